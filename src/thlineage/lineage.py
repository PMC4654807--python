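"""Cross-platform DE consensus and Th1/Th2 lineage-specificity calls.

A feature gets a *consensus* DE call for a comparison when it is
differentially expressed on at least two platforms with the same fold-change
direction. A feature is *Th1-specific* when it is DE in Thp vs Th1 but not in
Thp vs Th0 (the activation control) and not in Thp vs Th2 — and symmetrically
for Th2. The same classification applied to the sequencing platform alone
("seqonly") yields the novel-gene and lncRNA lists.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

COMPARISONS = ("Thp_vs_Th0", "Thp_vs_Th1", "Thp_vs_Th2")


def _signed_de(table: pd.DataFrame) -> pd.Series:
    """+1/-1 for DE up/down, 0 for not DE."""
    sign = np.sign(table["log2fc"]).astype(int)
    return sign.where(table["is_de"], 0)


def build_consensus(
    tables: Mapping[str, Mapping[str, pd.DataFrame]], min_platforms: int = 2
) -> pd.DataFrame:
    """Combine per-platform DE tables into consensus calls per comparison.

    ``tables[platform][comparison]`` is a DE table indexed by feature_id with
    ``is_de`` and ``log2fc`` columns. A feature absent from a platform's table
    contributes no vote for it. Output is indexed by the union of feature ids
    with, per comparison, ``de_<comparison>`` (bool) and ``sign_<comparison>``
    (+1/-1/0). Consensus requires >= ``min_platforms`` platforms DE with the
    same sign (and no opposite-sign quorum).
    """
    if len(tables) < 2:
        raise ValidationError("consensus requires >=2 platforms")
    features: pd.Index = pd.Index([], dtype=object)
    for per_platform in tables.values():
        for tab in per_platform.values():
            features = features.union(tab.index)
    features = features.sort_values()

    out = pd.DataFrame(index=features)
    for comparison in COMPARISONS:
        votes = []
        for platform, per_platform in tables.items():
            if comparison not in per_platform:
                import warnings

                warnings.warn(
                    f"platform {platform!r} has no table for {comparison}; no vote",
                    stacklevel=2,
                )
                continue
            votes.append(_signed_de(per_platform[comparison]).reindex(features))
        if not votes:
            out[f"de_{comparison}"] = False
            out[f"sign_{comparison}"] = 0
            continue
        mat = pd.concat(votes, axis=1)
        n_up = (mat == 1).sum(axis=1)
        n_down = (mat == -1).sum(axis=1)
        up = (n_up >= min_platforms) & (n_down < min_platforms)
        down = (n_down >= min_platforms) & (n_up < min_platforms)
        out[f"de_{comparison}"] = up | down
        out[f"sign_{comparison}"] = np.where(up, 1, np.where(down, -1, 0))
    return out


def single_platform_status(per_comparison: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """DE status frame for one platform, same schema as ``build_consensus``."""
    features: pd.Index = pd.Index([], dtype=object)
    for tab in per_comparison.values():
        features = features.union(tab.index)
    features = features.sort_values()
    out = pd.DataFrame(index=features)
    for comparison in COMPARISONS:
        if comparison not in per_comparison:
            raise ValidationError(f"missing comparison {comparison}")
        sign = _signed_de(per_comparison[comparison]).reindex(features).fillna(0).astype(int)
        out[f"de_{comparison}"] = sign != 0
        out[f"sign_{comparison}"] = sign
    return out


def classify_lineage(status: pd.DataFrame, evidence_mode: str = "consensus") -> pd.DataFrame:
    """Label each feature Th1-specific, Th2-specific or none.

    ``status`` must carry ``de_<comparison>`` booleans for all three Thp
    comparisons (as produced by :func:`build_consensus` or
    :func:`single_platform_status`).
    """
    missing = [c for c in COMPARISONS if f"de_{c}" not in status.columns]
    if missing:
        raise ValidationError(f"missing DE status for comparisons: {missing}")
    de0 = status["de_Thp_vs_Th0"].fillna(False).astype(bool)
    de1 = status["de_Thp_vs_Th1"].fillna(False).astype(bool)
    de2 = status["de_Thp_vs_Th2"].fillna(False).astype(bool)
    th1 = de1 & ~de2 & ~de0
    th2 = de2 & ~de1 & ~de0
    label = np.where(th1, "Th1-specific", np.where(th2, "Th2-specific", "none"))
    sign = np.where(
        th1, status["sign_Thp_vs_Th1"], np.where(th2, status["sign_Thp_vs_Th2"], 0)
    ).astype(int)
    direction = np.where(sign > 0, "up", np.where(sign < 0, "down", ""))
    return pd.DataFrame(
        {"label": label, "direction": direction, "evidence_mode": evidence_mode},
        index=status.index,
    )


def lineage_sets(assignment: pd.DataFrame) -> dict[str, set[str]]:
    """Convenience: {'Th1': ids, 'Th2': ids} from a classification frame."""
    return {
        "Th1": set(assignment.index[assignment["label"] == "Th1-specific"]),
        "Th2": set(assignment.index[assignment["label"] == "Th2-specific"]),
    }
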