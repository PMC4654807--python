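"""Two-group differential expression with the study's thresholds.

Intensity platforms are tested with a moderated (empirical-Bayes) unpaired
t-test: per-gene variances are shrunk toward a common prior variance s0^2
with prior degrees of freedom d0, both estimated by moment matching on the
observed sample variances under the scaled-inverse-chi-square hierarchy.
Counts are normalized with median-of-ratios size factors, variance-stabilized
as log2(normalized + 1), and tested on the stabilized scale (the reported
fold change is therefore a "modified" log2 fold change).

A feature is differentially expressed when BH-adjusted p < 0.05 and
|log2FC| > 1 (both strict), optionally refined by present/absent calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import DegenerateInputError, ValidationError

DE_ALPHA = 0.05
DE_LFC = 1.0
D0_CAP = 1e6  # represents "infinite" shrinkage


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Per sample, the factor is the median over genes (restricted to genes with
    positive counts in every sample) of count / geometric-mean-across-samples.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise DegenerateInputError("no gene has positive counts in all samples")
    ref = arr[allpos]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def variance_stabilize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1): monotone, zero-preserving reference VST."""
    if (size_factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-inverse-chi-square variance prior.

    Under the hierarchy sigma_g^2 ~ s0^2 * d0 / chi2_d0 and
    s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_df / df, the marginal of s^2 / s0^2 is
    F(df, d0). Matching the squared coefficient of variation of s^2 to that of
    the F distribution gives d0; the mean then gives s0^2. d0 is capped to
    represent full shrinkage when the observed spread is at or below the
    chi-square-only expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m <= 0:
        raise DegenerateInputError("non-positive mean sample variance")
    c = v / (m * m)
    denom = c * df - 2.0
    if denom <= 0:
        d0 = D0_CAP
    else:
        d0 = (2.0 * df - 4.0 + 4.0 * c * df) / denom
        d0 = min(max(d0, 1e-8), D0_CAP)
    s0_2 = m * (d0 - 2.0) / d0 if d0 > 2 else m
    return d0, s0_2


def moderated_t_test(
    matrix: ExpressionMatrix,
    comparison: tuple[str, str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated unpaired t-test between two sample groups.

    Returns a DE table (one row per feature) with log2fc = mean(test) -
    mean(reference), the moderated t statistic, and its two-sided p-value on
    df + d0 degrees of freedom. ``d0_override`` pins the prior df (0 recovers
    the ordinary equal-variance t-test; ``np.inf`` full shrinkage).
    """
    ref, test = comparison
    ref_vals = matrix.values[matrix.samples_in_group(ref)].to_numpy(dtype=float)
    test_vals = matrix.values[matrix.samples_in_group(test)].to_numpy(dtype=float)
    n1, n2 = ref_vals.shape[1], test_vals.shape[1]
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(
            f"comparison {ref} vs {test}: need >=2 replicates per group (got {n1}, {n2})"
        )
    df = n1 + n2 - 2
    lfc = test_vals.mean(axis=1) - ref_vals.mean(axis=1)
    ss = ((ref_vals - ref_vals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (test_vals - test_vals.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df

    if d0_override is None:
        d0, s0_2 = estimate_variance_prior(s2, df)
    else:
        d0 = float(d0_override)
        s0_2 = float(np.mean(s2)) if np.isinf(d0) else estimate_variance_prior(s2, df)[1]
    if np.isinf(d0) or d0 >= D0_CAP:
        post_var = np.full_like(s2, s0_2)
        total_df = D0_CAP
    elif d0 == 0:
        post_var = s2
        total_df = float(df)
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = df + d0
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2.0 * scipy.stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "comparison": f"{ref}_vs_{test}",
            "log2fc": lfc,
            "t": t,
            "pvalue": pvalue,
            "platform": matrix.platform,
        }
    ).set_index("feature_id")


def count_de_test(
    counts: ExpressionMatrix,
    comparison: tuple[str, str],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Count-platform DE: moderated t on variance-stabilized values.

    The returned log2fc is on the stabilized scale. Size factors absorb global
    depth differences, so scaling every count of a sample leaves results
    invariant.
    """
    if counts.platform_kind != "count":
        raise ValidationError("count_de_test requires a count platform")
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(counts.values)
    vst = variance_stabilize(counts.values, size_factors)
    return moderated_t_test(counts.with_values(vst, platform_kind="intensity"), comparison)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_de_filter(
    table: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    alpha: float = DE_ALPHA,
    lfc: float = DE_LFC,
    refinement: str = "either",
) -> pd.DataFrame:
    """Apply the DE thresholds (adj p < alpha, |log2fc| > lfc, both strict)
    and, when presence calls are supplied, the presence refinement.

    Refinement rules: ``either`` keeps a call if the feature is present in at
    least one of the two compared groups, ``both`` requires both, ``test``
    only the test group, ``none`` disables refinement.
    """
    if refinement not in ("either", "both", "test", "none"):
        raise ValidationError(f"unknown refinement rule {refinement!r}")
    out = table.copy()
    if "adj_pvalue" not in out.columns:
        out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    is_de = (out["adj_pvalue"] < alpha) & (out["log2fc"].abs() > lfc)
    if presence is not None and refinement != "none":
        ref_grp, test_grp = out["comparison"].iloc[0].split("_vs_")
        pres = presence.reindex(out.index).fillna(False)
        if refinement == "either":
            ok = pres[ref_grp] | pres[test_grp]
        elif refinement == "both":
            ok = pres[ref_grp] & pres[test_grp]
        else:
            ok = pres[test_grp]
        is_de &= ok
    out["is_de"] = is_de
    return out
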