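"""Present/absent expression calls.

Array- and sequencing-style platforms produce a bimodal distribution of
log-scale expression: a low-mean component of background/unexpressed features
and a high-mean component of genuinely expressed ones. A two-component
Gaussian mixture is fitted to the pooled ("chip-wide") values by EM, and a
feature is called *present* in a sample subtype only if every replicate of
that subtype is more likely to come from the high-mean component. Illumina
style arrays instead provide per-probe detection p-values, and presence
requires detection p < alpha in all replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import DegenerateInputError, ValidationError

SD_FLOOR = 1e-3  # log2-scale variance floor; prevents component collapse


@dataclass
class MixtureFit:
    """Ordered two-component 1-D Gaussian mixture (mean_low < mean_high)."""

    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    weight_low: float
    weight_high: float
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    converged: bool = True

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def component_densities(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            _normal_pdf(x, self.mean_low, self.sd_low),
            _normal_pdf(x, self.mean_high, self.sd_high),
        )

    def responsibility_high(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that each value came from the high component."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.component_densities(x)
        num = self.weight_high * hi
        den = self.weight_low * lo + num
        # where both densities underflow, decide by distance to the means
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), x > (self.mean_low + self.mean_high) / 2)
        return out

    def density_ratio_high(self, x: np.ndarray) -> np.ndarray:
        """Unweighted high-vs-low component density comparison (> 0.5 means high)."""
        lo, hi = self.component_densities(np.asarray(x, dtype=float))
        return (hi > lo).astype(float)


def _normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def mixture_loglik(x: np.ndarray, w_low, mu_low, sd_low, w_high, mu_high, sd_high) -> float:
    dens = w_low * _normal_pdf(x, mu_low, sd_low) + w_high * _normal_pdf(x, mu_high, sd_high)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_two_component_em(
    values: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
    sd_floor: float = SD_FLOOR,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM, best of ``n_starts`` restarts.

    Initialization for the first start splits responsibilities at the median;
    further starts jitter the split quantile. Convergence is declared when the
    relative log-likelihood improvement drops below ``tol``.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateInputError(f"need >=10 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero-variance input: mixture fit is degenerate")

    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for start in range(n_starts):
        q = 0.5 if start == 0 else float(rng.uniform(0.25, 0.75))
        fit = _em_single_run(x, split_quantile=q, tol=tol, max_iter=max_iter, sd_floor=sd_floor)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    if not best.converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning, stacklevel=2)
    return best


def _em_single_run(x, split_quantile, tol, max_iter, sd_floor) -> MixtureFit:
    cut = np.quantile(x, split_quantile)
    gamma = (x > cut).astype(float)  # responsibility of the high component
    # avoid empty components on ties at the cut
    if gamma.sum() == 0 or gamma.sum() == x.size:
        gamma = np.linspace(0.0, 1.0, x.size)[np.argsort(np.argsort(x))]

    trace: list[float] = []
    converged = False
    w_h = mu_l = mu_h = sd_l = sd_h = 0.0
    for _ in range(max_iter):
        # M step
        n_h = gamma.sum()
        n_l = x.size - n_h
        w_h = n_h / x.size
        mu_h = float(np.sum(gamma * x) / n_h)
        mu_l = float(np.sum((1 - gamma) * x) / n_l)
        sd_h = max(float(np.sqrt(np.sum(gamma * (x - mu_h) ** 2) / n_h)), sd_floor)
        sd_l = max(float(np.sqrt(np.sum((1 - gamma) * (x - mu_l) ** 2) / n_l)), sd_floor)
        # E step
        dens_l = (1 - w_h) * _normal_pdf(x, mu_l, sd_l)
        dens_h = w_h * _normal_pdf(x, mu_h, sd_h)
        total = np.maximum(dens_l + dens_h, 1e-300)
        gamma = dens_h / total
        ll = float(np.sum(np.log(total)))
        if trace and (ll - trace[-1]) <= tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

    if mu_l > mu_h:  # order components by mean
        mu_l, mu_h = mu_h, mu_l
        sd_l, sd_h = sd_h, sd_l
        w_h = 1 - w_h
    return MixtureFit(
        mean_low=mu_l,
        mean_high=mu_h,
        sd_low=sd_l,
        sd_high=sd_h,
        weight_low=1 - w_h,
        weight_high=w_h,
        loglik_trace=np.asarray(trace),
        converged=converged,
    )


def call_presence_mixture(
    matrix: ExpressionMatrix, fit: MixtureFit, rule: str = "posterior"
) -> pd.DataFrame:
    """Per-feature, per-group present/absent calls from a fitted mixture.

    A feature is present in a group iff *every* replicate of the group is
    assigned to the high-mean component. ``rule='posterior'`` compares the
    posterior responsibility (weighted densities) to 0.5; ``rule='density'``
    compares the unweighted component densities.
    """
    if rule not in ("posterior", "density"):
        raise ValidationError(f"unknown presence rule {rule!r}")
    vals = matrix.values.to_numpy(dtype=float)
    if rule == "posterior":
        high = fit.responsibility_high(vals) > 0.5
    else:
        lo, hi = fit.component_densities(vals)
        high = hi > lo
    high_df = pd.DataFrame(high, index=matrix.values.index, columns=matrix.values.columns)
    calls = {}
    for group in matrix.groups:
        calls[group] = high_df[matrix.samples_in_group(group)].all(axis=1)
    return pd.DataFrame(calls)


def call_presence_detection(
    detection_p: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Detection-p presence rule: p < alpha (strict) in all replicates of a group."""
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    arr = detection_p.to_numpy(dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValidationError("detection p-values must lie in [0, 1]")
    below = detection_p < alpha
    calls = {}
    for group in design["group"].unique():
        samples = design.loc[design["group"] == group, "sample"].astype(str).tolist()
        calls[group] = below[samples].all(axis=1)
    return pd.DataFrame(calls)


def collapse_duplicates_by_iqr(
    matrix: ExpressionMatrix, feature_to_gene: dict[str, str] | pd.Series
) -> ExpressionMatrix:
    """Collapse duplicate probes per gene, retaining the probe with the highest
    inter-quartile range across all samples (ties broken by the
    lexicographically smallest probe id). Unmapped probes are dropped.
    """
    mapping = pd.Series(feature_to_gene)
    if mapping.empty:
        raise ValidationError("feature-to-gene mapping is empty")
    mapped = matrix.values.index.intersection(mapping.index)
    vals = matrix.values.loc[mapped].sort_index()  # sort => deterministic tie-break
    q75 = vals.quantile(0.75, axis=1)
    q25 = vals.quantile(0.25, axis=1)
    iqr = q75 - q25
    frame = pd.DataFrame({"gene": mapping.loc[vals.index].to_numpy(), "iqr": iqr})
    keep = frame.groupby("gene", sort=True)["iqr"].idxmax()  # first occurrence wins ties
    collapsed = vals.loc[keep.to_numpy()]
    collapsed.index = keep.index
    return matrix.with_values(collapsed)
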