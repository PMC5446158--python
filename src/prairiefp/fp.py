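"""Flowering potential (FP): trait-weighted relative cover by month.

For a plot and month, FP is the summed relative cover of the species
whose published flowering interval includes that month — each species'
relative cover times a 0/1 monthly flowering weight, summed over the
plot. Subset profiles (exotic/native provenance, or a functional group)
use the same relative covers with weights additionally zeroed outside
the subset; nothing is re-normalized within a subset, so provenance
subsets partition total FP and functional-group subsets sum to it when
every taxon is herbaceous and classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cover import KEY_COLS, PlotComposition
from .traits import MONTHS, SpeciesTrait, TraitCatalog, is_flowering

PROVENANCE_SUBSETS = ("exotic", "native")
FUNCTIONAL_SUBSETS = ("C3_graminoid", "C4_graminoid", "forb", "legume")


@dataclass(frozen=True)
class SubsetSpec:
    """Which slice of the community an FP profile covers."""

    kind: str = "total"
    value: str = ""

    def __post_init__(self) -> None:
        if self.kind == "total":
            if self.value:
                raise ValueError("total subset takes no value")
        elif self.kind == "provenance":
            if self.value not in PROVENANCE_SUBSETS:
                raise ValueError(f"provenance subset must be one of {PROVENANCE_SUBSETS}")
        elif self.kind == "functional_group":
            if self.value not in FUNCTIONAL_SUBSETS:
                raise ValueError(
                    f"functional_group subset must be one of {FUNCTIONAL_SUBSETS}"
                )
        else:
            raise ValueError(f"unknown subset kind {self.kind!r}")

    @classmethod
    def total(cls) -> "SubsetSpec":
        return cls("total")

    @classmethod
    def from_label(cls, label: str) -> "SubsetSpec":
        if label == "total":
            return cls.total()
        if label in PROVENANCE_SUBSETS:
            return cls("provenance", label)
        if label in FUNCTIONAL_SUBSETS:
            return cls("functional_group", label)
        raise ValueError(f"unknown subset label {label!r}")

    @property
    def label(self) -> str:
        return self.value or "total"

    def matches(self, trait: SpeciesTrait) -> bool:
        if self.kind == "total":
            return True
        if self.kind == "provenance":
            return trait.provenance == self.value
        return trait.functional_group == self.value


TOTAL = SubsetSpec.total()

#: The seven profiles analyzed by default: whole community, provenance, groups.
DEFAULT_SUBSETS = ("total",) + PROVENANCE_SUBSETS + FUNCTIONAL_SUBSETS


def monthly_fp(
    composition: PlotComposition,
    catalog: TraitCatalog,
    month: int,
    subset: SubsetSpec = TOTAL,
) -> float:
    """FP of one plot for one month: sum of rel_cover x 0/1 flowering weight.

    Every taxon in the composition must carry a trait record; exclusions
    are applied upstream.
    """
    total = 0.0
    for taxon, rel in composition.rel_cover.items():
        trait = catalog[taxon]  # KeyError -> "no trait record" from the catalog
        if subset.matches(trait):
            total += rel * is_flowering(trait, month)
    return total


@dataclass
class FPMatrix:
    """Plot x month FP values (proportion scale) for one community subset."""

    subset: SubsetSpec
    frame: pd.DataFrame  # KEY_COLS + one column per month 1..12

    def __post_init__(self) -> None:
        vals = self.frame[list(MONTHS)].to_numpy()
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-9):
            raise ValueError("FP values must lie in [0, 1]")

    @property
    def n_plots(self) -> int:
        return len(self.frame)

    def to_long(self, percent: bool = True) -> pd.DataFrame:
        """Tidy long table: one row per plot x month, FP on the percent scale."""
        long = self.frame.melt(
            id_vars=KEY_COLS, value_vars=list(MONTHS),
            var_name="month", value_name="fp",
        )
        long["month"] = long["month"].astype(int)
        long.insert(len(KEY_COLS), "subset_kind", self.subset.kind)
        long.insert(len(KEY_COLS) + 1, "subset_value", self.subset.value)
        scale = 100.0 if percent else 1.0
        long["fp_pct" if percent else "fp"] = long.pop("fp") * scale
        return long.sort_values(KEY_COLS + ["month"]).reset_index(drop=True)


def fp_matrix(
    rel_long: pd.DataFrame, catalog: TraitCatalog, subset: SubsetSpec = TOTAL
) -> FPMatrix:
    """Compute FP for every plot and all 12 months.

    `rel_long` is a relativized long cover table (KEY_COLS + taxon +
    rel_cover). Months outside the growing season are retained; species
    flowering then still contribute (the flowering-volume curve spans
    January-December).
    """
    missing = sorted(set(rel_long["taxon"].unique()) - set(catalog.taxa))
    if missing:
        raise KeyError(f"taxa without trait records (exclude upstream): {missing[:5]}")

    flowering = catalog.flowering_table()  # taxon x month 0/1
    in_subset = pd.Series(
        {t.taxon: float(subset.matches(t)) for t in catalog}, name="in_subset"
    )
    weights = flowering.mul(in_subset, axis=0).loc[rel_long["taxon"]]
    contrib = weights.to_numpy() * rel_long["rel_cover"].to_numpy()[:, None]
    contrib_df = pd.concat(
        [rel_long[KEY_COLS].reset_index(drop=True),
         pd.DataFrame(contrib, columns=list(MONTHS))],
        axis=1,
    )
    wide = contrib_df.groupby(KEY_COLS, sort=True, as_index=False)[list(MONTHS)].sum()
    return FPMatrix(subset=subset, frame=wide)


def group_profiles(matrix: FPMatrix, months=tuple(range(5, 11))) -> pd.DataFrame:
    """Mean +/- SE FP (percent scale) per ecoregion x month x N group.

    Plots are pooled into N_added (N, NP, NK+u, NPK+u) and N_free
    (control, P, K+u, PK+u). SE is NaN when a cell has a single plot;
    cells with no plots appear with n = 0.
    """
    months = sorted(months)
    if any(m not in MONTHS for m in months):
        raise ValueError("months must be a subset of 1..12")
    long = matrix.frame.melt(
        id_vars=KEY_COLS, value_vars=months, var_name="month", value_name="fp"
    )
    long["month"] = long["month"].astype(int)
    long["group"] = np.where(long["trt_N"], "N_added", "N_free")

    stats = (
        long.groupby(["ecoregion", "month", "group"], sort=True)["fp"]
        .agg(mean_fp_pct=lambda v: 100.0 * v.mean(),
             se_fp_pct=lambda v: 100.0 * v.std(ddof=1) / np.sqrt(len(v))
             if len(v) >= 2 else np.nan,
             n="size")
        .reset_index()
    )
    grid = pd.MultiIndex.from_product(
        [sorted(long["ecoregion"].unique()), months, ["N_added", "N_free"]],
        names=["ecoregion", "month", "group"],
    ).to_frame(index=False)
    out = grid.merge(stats, how="left", on=["ecoregion", "month", "group"])
    out["n"] = out["n"].fillna(0).astype(int)
    return out
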