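"""End-to-end orchestration: simulate / FP / volume / mixed models.

Stages run in a fixed order — load or simulate covers, apply
exclusions, relativize, compute FP matrices per subset, fit the FP
mixed model and N-by-month contrasts for each subset, compute per-plot
flowering volumes and the volume model — writing one tidy CSV per
product plus a run-summary JSON (config, row counts, collected
warnings). Identical config and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import cover as cover_mod
from . import fp as fp_mod
from . import lmm as lmm_mod
from . import simulate as sim_mod
from . import volume as vol_mod
from .traits import load_trait_catalog

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Inputs, options, and output location for one run."""

    out_dir: str = "prairiefp_out"
    cover_csv: str | None = None
    trait_csv: str | None = None
    synthetic: sim_mod.SyntheticConfig | None = None
    months: tuple = lmm_mod.GROWING_SEASON
    subsets: tuple = fp_mod.DEFAULT_SUBSETS
    by_ecoregion: bool = False
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        months = sorted(self.months)
        if months != list(range(months[0], months[-1] + 1)) or not (
            1 <= months[0] and months[-1] <= 12
        ):
            raise ValueError("months must be a contiguous subset of 1..12")
        self.months = tuple(months)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for label in self.subsets:
            fp_mod.SubsetSpec.from_label(label)  # validates

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if synth is not None:
            synth = {k: tuple(v) if isinstance(v, list) else v for k, v in synth.items()}
            cfg.synthetic = sim_mod.SyntheticConfig(**synth)
        return cfg


def _config_fingerprint(config: PipelineConfig) -> str:
    payload = {
        "out_dir": config.out_dir, "cover_csv": config.cover_csv,
        "trait_csv": config.trait_csv, "months": list(config.months),
        "subsets": list(config.subsets), "by_ecoregion": config.by_ecoregion,
        "alpha": config.alpha, "seed": config.seed,
        "synthetic": sim_mod._config_dict(config.synthetic) if config.synthetic else None,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic dataset and write cover/trait/truth files."""
    if config.synthetic is None:
        raise PipelineError("simulate", "no synthetic config provided")
    synth = config.synthetic
    if config.seed is not None:
        synth = replace(synth, seed=config.seed)
    t0 = time.perf_counter()
    dataset = sim_mod.generate(synth)
    paths = sim_mod.write_dataset(dataset, config.out_dir)
    manifest = {
        "seed": synth.seed,
        "config": sim_mod._config_dict(synth),
        "n_plots": int(dataset.design.shape[0]),
        "n_taxa": len(dataset.catalog),
        "files": paths,
    }
    manifest_path = Path(config.out_dir) / "simulate_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(manifest_path)
    logger.info(
        "simulate: %d plots, %d taxa (%.2fs)",
        manifest["n_plots"], manifest["n_taxa"], time.perf_counter() - t0,
    )
    return paths


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return str(path)


@dataclass
class _Prepared:
    catalog: object
    cover: pd.DataFrame
    included: pd.DataFrame
    rel_long: pd.DataFrame
    matrices: dict
    paths: dict
    warnings: list


def _prepare(config: PipelineConfig, out: Path) -> _Prepared:
    """Shared front half: load/simulate, exclude, relativize, FP matrices."""
    warnings_log: list[str] = []
    paths: dict[str, str] = {}

    cover_csv, trait_csv = config.cover_csv, config.trait_csv
    if cover_csv is None or trait_csv is None:
        sim_paths = run_simulate(config)
        cover_csv, trait_csv = sim_paths["cover"], sim_paths["traits"]
        paths.update({f"sim_{k}": v for k, v in sim_paths.items()})

    stage = "load"
    try:
        catalog = load_trait_catalog(trait_csv)
        for taxon, reason in catalog.skipped:
            warnings_log.append(f"trait row skipped: {taxon} ({reason})")
        cover = cover_mod.load_cover(cover_csv)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "exclusions"
    try:
        included, report = cover_mod.apply_exclusions(cover, catalog)
        paths["exclusions"] = str(out / "exclusions.csv")
        report.to_csv(paths["exclusions"])
        for _, row in report.by_taxon.iterrows():
            warnings_log.append(f"excluded: {row['taxon']} ({row['reason']})")
        rel_long = cover_mod.relativize_all(included)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "fp"
    try:
        matrices = {
            label: fp_mod.fp_matrix(rel_long, catalog, fp_mod.SubsetSpec.from_label(label))
            for label in config.subsets
        }
        fp_long = pd.concat(
            [m.to_long() for m in matrices.values()], ignore_index=True
        )
        paths["fp_long"] = _write(fp_long, out / "fp_long.csv")
    except Exception as err:
        raise PipelineError(stage, err) from err
    return _Prepared(
        catalog=catalog, cover=cover, included=included, rel_long=rel_long,
        matrices=matrices, paths=paths, warnings=warnings_log,
    )


def run_fp(config: PipelineConfig) -> dict:
    """Stop after the FP stage: fp_long.csv + exclusion report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _prepare(config, out).paths


def _volume_stage(prep: _Prepared, out: Path) -> None:
    stage = "volume"
    try:
        total = prep.matrices.get("total") or fp_mod.fp_matrix(
            prep.rel_long, prep.catalog
        )
        volumes = vol_mod.plot_volumes(total)
        prep.paths["volume"] = _write(volumes, out / "volume.csv")
        _, vol_anova = lmm_mod.fit_volume_lmm(volumes)
        prep.paths["anova_volume"] = _write(vol_anova, out / "anova_volume.csv")
    except lmm_mod.FitError as err:
        raise PipelineError(stage, err) from err


def run_volume(config: PipelineConfig) -> dict:
    """FP stage plus per-plot flowering volumes and the volume model."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prep = _prepare(config, out)
    _volume_stage(prep, out)
    return prep.paths


def run_analyze(config: PipelineConfig) -> dict:
    """Run the analysis stages on (possibly simulated) inputs.

    Writes fp_long.csv, per-subset anova/contrast CSVs, volume.csv,
    anova_volume.csv, exclusions.csv, and run_summary.json; returns the
    path map. Any stage failure aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prep = _prepare(config, out)
    paths, warnings_log = prep.paths, prep.warnings

    for label, matrix in prep.matrices.items():
        stage = f"lmm[{label}]"
        try:
            sub_long = matrix.to_long()
            handle = lmm_mod.fit_fp_lmm(sub_long, months=config.months)
            paths[f"anova_{label}"] = _write(
                lmm_mod.anova_table(handle), out / f"anova_{label}.csv"
            )
            contrasts = lmm_mod.n_by_month_contrasts(
                handle, by_ecoregion=config.by_ecoregion
            )
            paths[f"contrasts_{label}"] = _write(
                contrasts, out / f"contrasts_{label}.csv"
            )
        except lmm_mod.FitError as err:
            raise PipelineError(stage, err) from err

    _volume_stage(prep, out)

    summary = {
        "config_hash": _config_fingerprint(config),
        "n_cover_rows": int(len(prep.cover)),
        "n_included_rows": int(len(prep.included)),
        "n_plots": int(prep.rel_long[cover_mod.PLOT_COLS].drop_duplicates().shape[0]),
        "subsets": list(config.subsets),
        "months": list(config.months),
        "by_ecoregion": config.by_ecoregion,
        "warnings": warnings_log,
        "files": paths,
    }
    paths["run_summary"] = str(out / "run_summary.json")
    with open(paths["run_summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("analyze: wrote %d files to %s", len(paths), out)
    return paths


def run_all(config: PipelineConfig) -> dict:
    """simulate (when configured) + analyze."""
    return run_analyze(config)
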