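"""Plot-level percent-cover surveys: loading, exclusions, relative cover.

Cover is scored per species to the nearest percent at peak biomass; plant
canopies overlap, so plot totals can exceed 100%. Absolute cover is
converted to relative cover by dividing each species' cover by the plot
total. Exclusions (genus-only taxa, tree seedlings, taxa without a trait
record) are applied before relativization, so relative covers sum to one
over the analyzable community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TraitCatalog

logger = logging.getLogger(__name__)

ECOREGIONS = ("tallgrass", "mixedgrass", "shortgrass")

#: Columns that identify one experimental plot and its treatment.
KEY_COLS = ["site", "ecoregion", "block", "plot", "trt_N", "trt_P", "trt_K"]
PLOT_COLS = ["site", "block", "plot"]
COVER_COLUMNS = KEY_COLS + ["taxon", "cover_pct"]

_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False, "t": True, "f": False,
}


@dataclass(frozen=True)
class CoverObservation:
    """One (plot, taxon, percent cover) survey record."""

    site: str
    ecoregion: str
    block: str
    plot: str
    trt_N: bool
    trt_P: bool
    trt_K: bool
    taxon: str
    cover_pct: float


@dataclass
class PlotComposition:
    """Relative-cover composition of a single plot (sums to one)."""

    site: str
    ecoregion: str
    block: str
    plot: str
    trt_N: bool
    trt_P: bool
    trt_K: bool
    rel_cover: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.rel_cover.values())
        if self.rel_cover and abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative covers sum to {total}, expected 1")


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    text = series.astype(str).str.strip().str.lower()
    bad = ~text.isin(_BOOL_MAP)
    if bad.any():
        rows = (series.index[bad] + 2).tolist()  # +2: header + 0-based index
        raise ValueError(f"column {name!r}: unparseable boolean values at rows {rows}")
    return text.map(_BOOL_MAP)


def load_cover(path) -> pd.DataFrame:
    """Load and validate a cover survey CSV.

    Returns a DataFrame with columns ``site, ecoregion, block, plot,
    trt_N, trt_P, trt_K, taxon, cover_pct`` (treatments as booleans).
    Rows with non-numeric cover or cover outside (0, 100] reject the
    file with their row numbers; so do duplicate (site, block, plot,
    taxon) records and unknown ecoregion labels.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cover CSV missing required columns: {missing}")
    df = df[COVER_COLUMNS].copy()
    for col in ("trt_N", "trt_P", "trt_K"):
        df[col] = _parse_bool(df[col], col)

    cover = pd.to_numeric(df["cover_pct"], errors="coerce")
    bad = cover.isna() | (cover <= 0) | (cover > 100)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValueError(
            f"cover_pct must be numeric and in (0, 100]; offending rows {rows}"
        )
    df["cover_pct"] = cover.astype(float)

    unknown_eco = sorted(set(df["ecoregion"]) - set(ECOREGIONS))
    if unknown_eco:
        raise ValueError(f"unknown ecoregion labels {unknown_eco}; expected {ECOREGIONS}")

    dup = df.duplicated(subset=PLOT_COLS + ["taxon"])
    if dup.any():
        dupes = df.loc[dup, PLOT_COLS + ["taxon"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (site, block, plot, taxon) records: {dupes[:5]}")

    n_plots = df[PLOT_COLS].drop_duplicates().shape[0]
    logger.info("cover survey: %d rows across %d plots", len(df), n_plots)
    return df


@dataclass
class ExclusionReport:
    """Which taxa were removed before analysis, and how much cover they held."""

    by_taxon: pd.DataFrame  # taxon, reason, n_rows, total_cover
    by_plot: pd.DataFrame   # site, block, plot, excluded_cover

    @property
    def empty(self) -> bool:
        return self.by_taxon.empty

    def to_csv(self, path) -> None:
        self.by_taxon.to_csv(path, index=False)


def _exclusion_reason(taxon: str, catalog: TraitCatalog) -> str | None:
    if taxon not in catalog:
        return "no trait record"
    lifeform = catalog[taxon].lifeform
    if lifeform == "genus_only_placeholder":
        return "genus-only"
    if lifeform == "tree_seedling":
        return "tree seedling"
    return None


def apply_exclusions(
    cover: pd.DataFrame, catalog: TraitCatalog
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop observations of non-analyzable taxa (idempotent).

    Removes genus-only placeholders, tree seedlings, and taxa absent
    from the trait catalog, reporting each excluded taxon with its
    reason plus the excluded cover per plot.
    """
    reasons = {t: _exclusion_reason(t, catalog) for t in cover["taxon"].unique()}
    excluded_mask = cover["taxon"].map(reasons).notna()
    excluded = cover[excluded_mask]
    included = cover[~excluded_mask].reset_index(drop=True)

    if excluded.empty:
        by_taxon = pd.DataFrame(columns=["taxon", "reason", "n_rows", "total_cover"])
        by_plot = pd.DataFrame(columns=PLOT_COLS + ["excluded_cover"])
    else:
        by_taxon = (
            excluded.groupby("taxon", sort=True)
            .agg(n_rows=("cover_pct", "size"), total_cover=("cover_pct", "sum"))
            .reset_index()
        )
        by_taxon.insert(1, "reason", by_taxon["taxon"].map(reasons))
        by_plot = (
            excluded.groupby(PLOT_COLS, sort=True)["cover_pct"]
            .sum()
            .rename("excluded_cover")
            .reset_index()
        )
        for taxon, reason in sorted(
            (t, r) for t, r in reasons.items() if r is not None
        ):
            logger.warning("excluding taxon %r: %s", taxon, reason)
    if included.empty:
        logger.warning("all cover observations excluded")
    return included, ExclusionReport(by_taxon=by_taxon, by_plot=by_plot)


def relativize(plot_obs: pd.DataFrame) -> PlotComposition:
    """Convert one plot's absolute covers to relative cover (sums to one)."""
    if plot_obs.empty:
        raise ValueError("plot has no vegetated cover after exclusions")
    keys = plot_obs[KEY_COLS].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("relativize expects observations from exactly one plot")
    total = plot_obs["cover_pct"].sum()
    rel = dict(zip(plot_obs["taxon"], plot_obs["cover_pct"] / total))
    key = keys.iloc[0]
    return PlotComposition(
        site=key["site"], ecoregion=key["ecoregion"], block=key["block"],
        plot=key["plot"], trt_N=bool(key["trt_N"]), trt_P=bool(key["trt_P"]),
        trt_K=bool(key["trt_K"]), rel_cover=rel,
    )


def relativize_all(cover: pd.DataFrame) -> pd.DataFrame:
    """Vectorized relativization: adds a ``rel_cover`` column per plot."""
    if cover.empty:
        raise ValueError("no cover observations to relativize")
    out = cover.copy()
    totals = out.groupby(PLOT_COLS)["cover_pct"].transform("sum")
    out["rel_cover"] = out["cover_pct"] / totals
    return out


def iter_compositions(rel_long: pd.DataFrame):
    """Yield a PlotComposition for each plot of a relativized long table."""
    for _, grp in rel_long.groupby(PLOT_COLS, sort=True):
        key = grp.iloc[0]
        yield PlotComposition(
            site=key["site"], ecoregion=key["ecoregion"], block=key["block"],
            plot=key["plot"], trt_N=bool(key["trt_N"]), trt_P=bool(key["trt_P"]),
            trt_K=bool(key["trt_K"]),
            rel_cover=dict(zip(grp["taxon"], grp["rel_cover"])),
        )
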