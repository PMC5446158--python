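"""Synthetic factorial NPK cover datasets with known effect structure.

Emulates a distributed grassland nutrient-addition experiment: three
prairie ecoregions (tall-, mixed-, short-grass), a few sites per
ecoregion, three blocks per site, and the 8-level factorial of N, P and
K(+micronutrient) treatments within every block. Species pools carry
flowering windows concentrated in the growing season (C4 graminoids
skewed late, C3 graminoids and exotics skewed early), long-tailed
baseline abundances, provenance and functional-group labels, and a few
genus-only placeholder taxa to exercise the exclusion rules.

Treatment effects are multiplicative on *expected absolute cover*
(early-flowering exotics and C3 graminoids boosted under added N,
late-flowering C4 graminoids suppressed, in configured ecoregions
only), so the compositional trade-off — boosted groups displacing the
rest in relative cover — emerges from relativization rather than being
hard-coded. The analytic expectation of the induced N effect on FP by
ecoregion and month (the noise-free limit) is returned as
SyntheticTruth for recovery tests. All randomness flows from a single
seeded generator, so a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .cover import COVER_COLUMNS, ECOREGIONS
from .traits import MONTHS, SpeciesTrait, TraitCatalog

_DEFAULT_SITES = {"tallgrass": 3, "mixedgrass": 2, "shortgrass": 3}
_PAPER_SCALE_SITES = {"tallgrass": 6, "mixedgrass": 2, "shortgrass": 3}
_DEFAULT_GROUP_MIX = {
    "C3_graminoid": 0.20, "C4_graminoid": 0.20, "forb": 0.40,
    "legume": 0.10, "woody": 0.05, "other": 0.05,
}

EARLY_MONTHS = frozenset({5, 6})   # boosted groups flower here under added N
LATE_MONTHS = frozenset({9, 10})   # suppressed C4 flowering


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the reduced-scale study design."""

    seed: int = 0
    n_sites_per_ecoregion: dict = field(default_factory=lambda: dict(_DEFAULT_SITES))
    n_blocks: int = 3
    species_pool_size: int = 40          # per ecoregion
    exotic_fraction: float = 0.3
    unknown_provenance_fraction: float = 0.0
    group_mix: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_MIX))
    window_length_range: tuple = (1, 4)
    window_start_early: tuple = (4, 5)   # cool-season C3 graminoids / exotics
    window_length_early: tuple = (2, 4)
    window_start_mid: tuple = (5, 8)     # forbs, legumes, woody, other
    window_start_late: tuple = (8, 9)    # warm-season C4 graminoids
    window_length_late: tuple = (3, 4)   # long Aug-Oct style windows
    baseline_concentration: float = 0.8  # lognormal sigma of baseline weights
    effect_N_early_exotic: float = 1.8
    effect_N_early_C3: float = 1.6
    effect_N_late_C4: float = 0.6
    effect_ecoregions: tuple = ("tallgrass",)
    noise_sd: float = 0.25               # log-scale per-observation noise
    total_cover_range: tuple = (80.0, 160.0)
    n_genus_placeholders: int = 3        # per ecoregion, to exercise exclusions

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.species_pool_size < 1:
            raise ValueError("counts must be >= 1")
        if any(n < 1 for n in self.n_sites_per_ecoregion.values()):
            raise ValueError("need at least one site per ecoregion")
        for frac in (self.exotic_fraction, self.unknown_provenance_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for mult in (self.effect_N_early_exotic, self.effect_N_early_C3,
                     self.effect_N_late_C4):
            if mult <= 0:
                raise ValueError("effect multipliers must be > 0")

    @classmethod
    def paper_scale(cls, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """Full-scale preset: 11 sites (6 tall-, 2 mixed-, 3 short-grass)."""
        return cls(seed=seed, n_sites_per_ecoregion=dict(_PAPER_SCALE_SITES), **kwargs)

    def null(self) -> "SyntheticConfig":
        """Copy with every treatment effect switched off."""
        return replace(
            self, effect_N_early_exotic=1.0, effect_N_early_C3=1.0,
            effect_N_late_C4=1.0,
        )


@dataclass
class SyntheticTruth:
    """Analytic expected N_added - N_free FP difference (proportion scale)."""

    expected_fp_diff: pd.DataFrame  # index ecoregion, columns months 1..12
    config: SyntheticConfig

    def diff(self, ecoregion: str, month: int) -> float:
        return float(self.expected_fp_diff.loc[ecoregion, month])

    @property
    def is_null(self) -> bool:
        return bool(np.allclose(self.expected_fp_diff.to_numpy(), 0.0))

    def to_json(self, path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "expected_fp_diff": {
                eco: {str(m): float(self.expected_fp_diff.loc[eco, m]) for m in MONTHS}
                for eco in self.expected_fp_diff.index
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Complete crossed plot table: every block holds the 8 NPK combinations."""
    rows = []
    for eco in ECOREGIONS:
        for s in range(1, config.n_sites_per_ecoregion.get(eco, 0) + 1):
            site = f"{eco[:4]}_{s:02d}"
            for b in range(1, config.n_blocks + 1):
                for plot, (n, p, k) in enumerate(
                    [(n, p, k) for n in (False, True) for p in (False, True)
                     for k in (False, True)],
                    start=1,
                ):
                    rows.append(
                        {"site": site, "ecoregion": eco, "block": str(b),
                         "plot": str(plot), "trt_N": n, "trt_P": p, "trt_K": k}
                    )
    return pd.DataFrame(rows)


def _sample_window(rng, config: SyntheticConfig, group: str, provenance: str):
    length_range = config.window_length_range
    if group == "C4_graminoid":
        lo, hi = config.window_start_late
        length_range = config.window_length_late
    elif group == "C3_graminoid" or provenance == "exotic":
        lo, hi = config.window_start_early
        length_range = config.window_length_early
    else:
        lo, hi = config.window_start_mid
    start = int(rng.integers(lo, hi + 1))
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return frozenset(m for m in range(start, start + length) if m <= 12)


def _n_multiplier(config: SyntheticConfig, months: frozenset,
                  group: str, provenance: str) -> float:
    if provenance == "exotic" and months & EARLY_MONTHS:
        return config.effect_N_early_exotic
    if group == "C3_graminoid" and months & EARLY_MONTHS:
        return config.effect_N_early_C3
    if group == "C4_graminoid" and months & LATE_MONTHS:
        return config.effect_N_late_C4
    return 1.0


def make_species_pool(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[TraitCatalog, pd.DataFrame]:
    """Per-ecoregion species pools with traits and baseline abundance weights.

    Returns the trait catalog plus a pool table (taxon, ecoregion,
    labels, base_weight, n_multiplier). Genus-only placeholders are
    appended with empty flowering windows; they are surveyed but
    excluded from analysis downstream.
    """
    groups = list(config.group_mix)
    probs = np.asarray([config.group_mix[g] for g in groups], dtype=float)
    probs = probs / probs.sum()

    traits: list[SpeciesTrait] = []
    rows = []
    for eco in ECOREGIONS:
        for i in range(1, config.species_pool_size + 1):
            group = groups[int(rng.choice(len(groups), p=probs))]
            u = rng.random()
            if u < config.exotic_fraction:
                provenance = "exotic"
            elif u < config.exotic_fraction + config.unknown_provenance_fraction:
                provenance = "unknown"
            else:
                provenance = "native"
            months = _sample_window(rng, config, group, provenance)
            base_w = float(rng.lognormal(0.0, config.baseline_concentration))
            taxon = f"{eco.capitalize()}ia species{i:03d}"
            traits.append(
                SpeciesTrait(
                    taxon=taxon, flowering_months=months, provenance=provenance,
                    functional_group=group, lifeform="herbaceous",
                    source="synthetic flora",
                )
            )
            rows.append(
                {"taxon": taxon, "ecoregion": eco, "functional_group": group,
                 "provenance": provenance, "lifeform": "herbaceous",
                 "base_weight": base_w,
                 "n_multiplier": _n_multiplier(config, months, group, provenance)}
            )
        for j in range(1, config.n_genus_placeholders + 1):
            taxon = f"{eco.capitalize()}ia sp{j} (genus only)"
            traits.append(
                SpeciesTrait(
                    taxon=taxon, flowering_months=frozenset(),
                    provenance="unknown", functional_group="other",
                    lifeform="genus_only_placeholder", source="synthetic flora",
                )
            )
            rows.append(
                {"taxon": taxon, "ecoregion": eco, "functional_group": "other",
                 "provenance": "unknown", "lifeform": "genus_only_placeholder",
                 "base_weight": float(rng.lognormal(-1.0, 0.5)),
                 "n_multiplier": 1.0}
            )
    return TraitCatalog(traits), pd.DataFrame(rows)


def _truth_from_pool(
    pool: pd.DataFrame, catalog: TraitCatalog, config: SyntheticConfig
) -> SyntheticTruth:
    """Noise-free expected FP difference over the analyzable community."""
    table = pd.DataFrame(0.0, index=list(ECOREGIONS), columns=list(MONTHS))
    for eco in ECOREGIONS:
        sub = pool[(pool["ecoregion"] == eco) & (pool["lifeform"] == "herbaceous")]
        w = sub["base_weight"].to_numpy()
        mult = (
            sub["n_multiplier"].to_numpy()
            if eco in config.effect_ecoregions
            else np.ones(len(sub))
        )
        p0 = w / w.sum()
        p1 = (w * mult) / (w * mult).sum()
        for m in MONTHS:
            flower = np.array(
                [m in catalog[t].flowering_months for t in sub["taxon"]], dtype=float
            )
            table.loc[eco, m] = float(((p1 - p0) * flower).sum())
    return SyntheticTruth(expected_fp_diff=table, config=config)


def simulate_cover(
    design: pd.DataFrame,
    pool: pd.DataFrame,
    catalog: TraitCatalog,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one survey: every pool species scored in every plot.

    Per plot, expected cover is baseline weight x N multiplier (in the
    configured effect ecoregions) x lognormal noise, scaled so the plot
    total lands in the configured 80-160% band (overlapping canopies).
    """
    frames = []
    for _, plot in design.sort_values(["ecoregion", "site", "block", "plot"]).iterrows():
        sub = pool[pool["ecoregion"] == plot["ecoregion"]]
        w = sub["base_weight"].to_numpy().copy()
        if plot["trt_N"] and plot["ecoregion"] in config.effect_ecoregions:
            w = w * sub["n_multiplier"].to_numpy()
        noise = rng.lognormal(0.0, config.noise_sd, size=len(w))
        w = w * noise
        total = rng.uniform(*config.total_cover_range)
        cover = w / w.sum() * total
        frames.append(
            pd.DataFrame(
                {"site": plot["site"], "ecoregion": plot["ecoregion"],
                 "block": plot["block"], "plot": plot["plot"],
                 "trt_N": plot["trt_N"], "trt_P": plot["trt_P"],
                 "trt_K": plot["trt_K"], "taxon": sub["taxon"].to_numpy(),
                 "cover_pct": cover}
            )
        )
    cover_df = pd.concat(frames, ignore_index=True)[COVER_COLUMNS]
    return cover_df, _truth_from_pool(pool, catalog, config)


@dataclass
class SyntheticDataset:
    """One generated experiment: design, traits, covers, and ground truth."""

    config: SyntheticConfig
    design: pd.DataFrame
    catalog: TraitCatalog
    pool: pd.DataFrame
    cover: pd.DataFrame
    truth: SyntheticTruth


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator from the configured seed."""
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    catalog, pool = make_species_pool(config, rng)
    cover, truth = simulate_cover(design, pool, catalog, config, rng)
    return SyntheticDataset(
        config=config, design=design, catalog=catalog, pool=pool,
        cover=cover, truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write cover CSV, trait CSV, and truth JSON; return their paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cover": out / "cover.csv",
        "traits": out / "traits.csv",
        "truth": out / "truth.json",
    }
    cover = dataset.cover.copy()
    for col in ("trt_N", "trt_P", "trt_K"):
        cover[col] = cover[col].astype(int)
    cover.to_csv(paths["cover"], index=False, float_format="%.6f")
    dataset.catalog.to_csv(paths["traits"])
    dataset.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
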