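"""Core in-memory containers shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("Thp", "Th0", "Th1", "Th2")


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with its sample design.

    ``values`` holds log2 intensities for array-like platforms, raw counts or
    variance-stabilized values for sequencing platforms (``platform_kind``
    distinguishes them). ``design`` maps each sample column to a T-helper
    subtype (Thp/Th0/Th1/Th2) and replicate index.
    """

    values: pd.DataFrame
    design: pd.DataFrame  # columns: sample, group, replicate
    platform_kind: str  # "intensity" | "count"
    platform: str = "platform"

    def __post_init__(self) -> None:
        if self.platform_kind not in ("intensity", "count"):
            raise ValidationError(f"unknown platform_kind {self.platform_kind!r}")
        design_samples = list(self.design["sample"].astype(str))
        cols = list(map(str, self.values.columns))
        if set(design_samples) != set(cols):
            raise ValidationError(
                f"{self.platform}: design samples do not match matrix columns"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.platform}: non-finite expression values")
        if (self.design.groupby("group").size() < 1).any():
            raise ValidationError(f"{self.platform}: empty sample group")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        seen = self.design["group"].unique().tolist()
        return [g for g in GROUPS if g in seen] + [g for g in seen if g not in GROUPS]

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.design.loc[self.design["group"] == group, "sample"]
        if sel.empty:
            raise ValidationError(f"{self.platform}: no samples in group {group!r}")
        return sel.astype(str).tolist()

    def with_values(self, values: pd.DataFrame, platform_kind: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            design=self.design,
            platform_kind=platform_kind or self.platform_kind,
            platform=self.platform,
        )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, used only for evaluation."""

    th1_genes: set[str] = field(default_factory=set)
    th2_genes: set[str] = field(default_factory=set)
    th1_lncrnas: set[str] = field(default_factory=set)
    th2_lncrnas: set[str] = field(default_factory=set)
    expressed_features: dict[str, set[str]] = field(default_factory=dict)
    vicinity_pairs: set[tuple[str, str]] = field(default_factory=set)
    enriched_mark_regions: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    trait_gene_map: dict[str, set[str]] = field(default_factory=dict)
    effect_signs: dict[str, int] = field(default_factory=dict)
    planted_go_term: str | None = None
    planted_go_lncrna: str | None = None

    def to_dict(self) -> dict:
        return {
            "th1_genes": sorted(self.th1_genes),
            "th2_genes": sorted(self.th2_genes),
            "th1_lncrnas": sorted(self.th1_lncrnas),
            "th2_lncrnas": sorted(self.th2_lncrnas),
            "expressed_features": {g: sorted(v) for g, v in self.expressed_features.items()},
            "vicinity_pairs": sorted(map(list, self.vicinity_pairs)),
            "enriched_mark_regions": self.enriched_mark_regions,
            "trait_gene_map": {t: sorted(v) for t, v in self.trait_gene_map.items()},
            "effect_signs": self.effect_signs,
            "planted_go_term": self.planted_go_term,
            "planted_go_lncrna": self.planted_go_lncrna,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            th1_genes=set(d["th1_genes"]),
            th2_genes=set(d["th2_genes"]),
            th1_lncrnas=set(d["th1_lncrnas"]),
            th2_lncrnas=set(d["th2_lncrnas"]),
            expressed_features={g: set(v) for g, v in d["expressed_features"].items()},
            vicinity_pairs={tuple(p) for p in d["vicinity_pairs"]},
            enriched_mark_regions=[tuple(r) for r in d["enriched_mark_regions"]],
            trait_gene_map={t: set(v) for t, v in d["trait_gene_map"].items()},
            effect_signs={k: int(v) for k, v in d.get("effect_signs", {}).items()},
            planted_go_term=d.get("planted_go_term"),
            planted_go_lncrna=d.get("planted_go_lncrna"),
        )
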