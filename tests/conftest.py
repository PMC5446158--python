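import logging

import pytest

from prairiefp import cover as cov
from prairiefp import fp as fpm
from prairiefp import lmm
from prairiefp import simulate as sim
from prairiefp.traits import SpeciesTrait, TraitCatalog

logging.getLogger("prairiefp").setLevel(logging.ERROR)


REDUCED_SITES = {"tallgrass": 1, "mixedgrass": 1, "shortgrass": 1}


def reduced_config(seed: int, null: bool = False) -> sim.SyntheticConfig:
    """Reduced-scale study design used by the simulation suites."""
    cfg = sim.SyntheticConfig(
        seed=seed, n_sites_per_ecoregion=dict(REDUCED_SITES), n_blocks=2
    )
    return cfg.null() if null else cfg


def simulate_fp_long(config: sim.SyntheticConfig):
    """Generator -> exclusions -> relativize -> total FP, as the pipeline does."""
    ds = sim.generate(config)
    included, _ = cov.apply_exclusions(ds.cover, ds.catalog)
    rel = cov.relativize_all(included)
    matrix = fpm.fp_matrix(rel, ds.catalog)
    return ds, matrix


def simulate_and_contrasts(seed: int, null: bool = False, by_ecoregion: bool = False):
    """One end-to-end replicate: simulated dataset -> fitted LMM -> N contrasts."""
    ds, matrix = simulate_fp_long(reduced_config(seed, null=null))
    handle = lmm.fit_fp_lmm(matrix.to_long())
    return ds, lmm.n_by_month_contrasts(handle, by_ecoregion=by_ecoregion)


@pytest.fixture(scope="session")
def worked_example_catalog() -> TraitCatalog:
    """The flora worked example: a June-August forb plus a May-only companion."""
    return TraitCatalog(
        [
            SpeciesTrait(
                taxon="Monarda fistulosa", flowering_months=frozenset({6, 7, 8}),
                provenance="native", functional_group="forb",
            ),
            SpeciesTrait(
                taxon="Companion vernalis", flowering_months=frozenset({5}),
                provenance="native", functional_group="forb",
            ),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset() -> sim.SyntheticDataset:
    """Reduced-scale generated experiment shared by read-only tests."""
    return sim.generate(reduced_config(0))


@pytest.fixture(scope="session")
def balanced_handle():
    """Fitted FP model on a complete balanced design (2 sites/ecoregion)."""
    cfg = sim.SyntheticConfig(
        seed=7,
        n_sites_per_ecoregion={"tallgrass": 2, "mixedgrass": 2, "shortgrass": 2},
        n_blocks=2,
    )
    _, matrix = simulate_fp_long(cfg)
    return lmm.fit_fp_lmm(matrix.to_long()), matrix
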