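import numpy as np
import pandas as pd
import pytest

from prairiefp import cover as cov
from prairiefp import simulate as sim
from prairiefp.cover import KEY_COLS, PlotComposition, relativize_all
from prairiefp.fp import SubsetSpec, fp_matrix, group_profiles, monthly_fp
from prairiefp.traits import MONTHS, SpeciesTrait, TraitCatalog, is_flowering


def brute_force_fp(rel_long, catalog, month, subset=SubsetSpec.total()):
    """Independent double loop over (species, month) per plot."""
    out = {}
    for key, grp in rel_long.groupby(KEY_COLS, sort=True):
        total = 0.0
        for _, row in grp.iterrows():
            trait = catalog[row["taxon"]]
            if subset.matches(trait) and is_flowering(trait, month):
                total += row["rel_cover"]
        out[key] = total
    return out


def _composition(rel_cover: dict) -> PlotComposition:
    return PlotComposition(
        site="chic", ecoregion="tallgrass", block="1", plot="61",
        trt_N=False, trt_P=False, trt_K=False, rel_cover=rel_cover,
    )


class TestMonthlyFP:
    def test_worked_example_contribution(self, worked_example_catalog):
        """A species with relative cover 0.117 flowering Jun-Aug adds exactly
        0.117 to the June, July and August FP and nothing to May."""
        comp = _composition({"Monarda fistulosa": 0.117, "Companion vernalis": 0.883})
        for month in (6, 7, 8):
            assert monthly_fp(comp, worked_example_catalog, month) == pytest.approx(
                0.117, abs=1e-15
            )
        assert monthly_fp(comp, worked_example_catalog, 5) == pytest.approx(
            0.883, abs=1e-15
        )  # May holds only the companion species' cover

    def test_single_species_full_cover(self):
        catalog = TraitCatalog(
            [SpeciesTrait(taxon="Solo species",
                          flowering_months=frozenset(range(5, 11)))]
        )
        comp = _composition({"Solo species": 1.0})
        for m in range(5, 11):
            assert monthly_fp(comp, catalog, m) == 1.0
        for m in (1, 4, 11, 12):
            assert monthly_fp(comp, catalog, m) == 0.0

    def test_missing_trait_record_raises(self, worked_example_catalog):
        comp = _composition({"Ghost species": 1.0})
        with pytest.raises(KeyError, match="Ghost species"):
            monthly_fp(comp, worked_example_catalog, 6)


@pytest.fixture(scope="module")
def rel_long(small_dataset):
    included, _ = cov.apply_exclusions(small_dataset.cover, small_dataset.catalog)
    return relativize_all(included)


class TestFPMatrix:
    def test_matches_brute_force_all_months(self, rel_long, small_dataset):
        catalog = small_dataset.catalog
        matrix = fp_matrix(rel_long, catalog)
        wide = matrix.frame.set_index(KEY_COLS)
        for month in MONTHS:
            oracle = brute_force_fp(rel_long, catalog, month)
            for key, expected in oracle.items():
                assert wide.loc[key, month] == pytest.approx(expected, abs=1e-12)

    def test_cell_count(self, rel_long, small_dataset):
        matrix = fp_matrix(rel_long, small_dataset.catalog)
        n_plots = rel_long[KEY_COLS].drop_duplicates().shape[0]
        assert matrix.frame[list(MONTHS)].size == n_plots * 12

    def test_provenance_partition(self, rel_long, small_dataset):
        catalog = small_dataset.catalog
        total = fp_matrix(rel_long, catalog).frame[list(MONTHS)].to_numpy()
        exotic = fp_matrix(rel_long, catalog, SubsetSpec("provenance", "exotic"))
        native = fp_matrix(rel_long, catalog, SubsetSpec("provenance", "native"))
        np.testing.assert_allclose(
            total,
            exotic.frame[list(MONTHS)].to_numpy() + native.frame[list(MONTHS)].to_numpy(),
            atol=1e-9,
        )

    def test_functional_groups_sum_to_total_when_herbaceous_only(self):
        cfg = sim.SyntheticConfig(
            seed=3,
            n_sites_per_ecoregion={"tallgrass": 1, "mixedgrass": 1, "shortgrass": 1},
            n_blocks=1,
            group_mix={"C3_graminoid": 0.3, "C4_graminoid": 0.3, "forb": 0.3,
                       "legume": 0.1, "woody": 0.0, "other": 0.0},
        )
        ds = sim.generate(cfg)
        included, _ = cov.apply_exclusions(ds.cover, ds.catalog)
        rel = relativize_all(included)
        total = fp_matrix(rel, ds.catalog).frame[list(MONTHS)].to_numpy()
        parts = sum(
            fp_matrix(rel, ds.catalog, SubsetSpec("functional_group", g))
            .frame[list(MONTHS)].to_numpy()
            for g in ("C3_graminoid", "C4_graminoid", "forb", "legume")
        )
        np.testing.assert_allclose(total, parts, atol=1e-9)

    def test_functional_groups_never_exceed_total(self, rel_long, small_dataset):
        catalog = small_dataset.catalog
        total = fp_matrix(rel_long, catalog).frame[list(MONTHS)].to_numpy()
        parts = sum(
            fp_matrix(rel_long, catalog, SubsetSpec("functional_group", g))
            .frame[list(MONTHS)].to_numpy()
            for g in ("C3_graminoid", "C4_graminoid", "forb", "legume")
        )
        assert (parts <= total + 1e-9).all()

    def test_all_forb_community_has_zero_graminoid_fp(self):
        catalog = TraitCatalog(
            [SpeciesTrait(taxon=f"Forbia species{i}",
                          flowering_months=frozenset({6, 7}),
                          functional_group="forb") for i in range(3)]
        )
        rows = [
            {"site": "s", "ecoregion": "tallgrass", "block": "1", "plot": "1",
             "trt_N": False, "trt_P": False, "trt_K": False,
             "taxon": f"Forbia species{i}", "cover_pct": 10.0 * (i + 1)}
            for i in range(3)
        ]
        rel = relativize_all(pd.DataFrame(rows))
        c3 = fp_matrix(rel, catalog, SubsetSpec("functional_group", "C3_graminoid"))
        assert (c3.frame[list(MONTHS)].to_numpy() == 0).all()

    def test_bounds(self, rel_long, small_dataset):
        for label in ("total", "exotic", "forb"):
            matrix = fp_matrix(rel_long, small_dataset.catalog,
                               SubsetSpec.from_label(label))
            vals = matrix.frame[list(MONTHS)].to_numpy()
            assert vals.min() >= 0 and vals.max() <= 1 + 1e-12

    def test_permutation_invariance(self, rel_long, small_dataset):
        shuffled = rel_long.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = fp_matrix(rel_long, small_dataset.catalog).frame
        b = fp_matrix(shuffled, small_dataset.catalog).frame
        pd.testing.assert_frame_equal(a, b)

    def test_enlarging_window_never_decreases_fp(self, rel_long, small_dataset):
        catalog = small_dataset.catalog
        base = fp_matrix(rel_long, catalog).frame[list(MONTHS)].to_numpy()
        taxon = rel_long["taxon"].iloc[0]
        widened = [
            SpeciesTrait(
                taxon=t.taxon,
                flowering_months=frozenset(MONTHS) if t.taxon == taxon
                else t.flowering_months,
                provenance=t.provenance, functional_group=t.functional_group,
                lifeform=t.lifeform, source=t.source,
            )
            for t in catalog
        ]
        bigger = fp_matrix(rel_long, TraitCatalog(widened)).frame[list(MONTHS)].to_numpy()
        assert (bigger >= base - 1e-12).all()


class TestGroupProfiles:
    def _matrix_16_plots(self, fp_value_n, fp_value_ctrl):
        rows = []
        for block in ("1", "2"):
            for plot, (n, p, k) in enumerate(
                [(n, p, k) for n in (False, True) for p in (False, True)
                 for k in (False, True)], start=1
            ):
                row = {"site": "konz", "ecoregion": "tallgrass", "block": block,
                       "plot": str(plot), "trt_N": n, "trt_P": p, "trt_K": k}
                for m in MONTHS:
                    row[m] = fp_value_n if n else fp_value_ctrl
                rows.append(row)
        from prairiefp.fp import FPMatrix, SubsetSpec

        return FPMatrix(subset=SubsetSpec.total(), frame=pd.DataFrame(rows))

    def test_hand_computed_group_means(self):
        matrix = self._matrix_16_plots(0.4, 0.25)
        prof = group_profiles(matrix, months=(6,))
        prof = prof.set_index("group")
        assert prof.loc["N_added", "mean_fp_pct"] == pytest.approx(40.0)
        assert prof.loc["N_free", "mean_fp_pct"] == pytest.approx(25.0)
        assert prof.loc["N_added", "se_fp_pct"] == pytest.approx(0.0)
        assert (prof["n"] == 8).all()

    def test_single_plot_group_has_missing_se(self):
        matrix = self._matrix_16_plots(0.4, 0.25)
        one = matrix.frame.iloc[[0]]
        from prairiefp.fp import FPMatrix, SubsetSpec

        prof = group_profiles(FPMatrix(SubsetSpec.total(), one), months=(6,))
        added = prof[prof["group"] == "N_added"].iloc[0]
        free = prof[prof["group"] == "N_free"].iloc[0]
        assert free["n"] == 1 and np.isnan(free["se_fp_pct"])
        assert added["n"] == 0  # empty group flagged, not dropped

    def test_profiles_match_plotwise_means_on_synthetic_data(self, rel_long,
                                                             small_dataset):
        matrix = fp_matrix(rel_long, small_dataset.catalog)
        prof = group_profiles(matrix, months=(5, 6))
        long = matrix.frame.melt(id_vars=KEY_COLS, value_vars=[5, 6],
                                 var_name="month", value_name="fp")
        long["group"] = np.where(long["trt_N"], "N_added", "N_free")
        expected = long.groupby(["ecoregion", "month", "group"])["fp"].mean() * 100
        for _, row in prof.iterrows():
            assert row["mean_fp_pct"] == pytest.approx(
                expected.loc[(row["ecoregion"], row["month"], row["group"])], abs=1e-9
            )


class TestSubsetSpec:
    @pytest.mark.parametrize("label", ["total", "exotic", "native", "forb",
                                       "C3_graminoid", "C4_graminoid", "legume"])
    def test_labels_roundtrip(self, label):
        assert SubsetSpec.from_label(label).label == label

    @pytest.mark.parametrize(
        ("kind", "value"),
        [("total", "exotic"), ("provenance", "forb"), ("functional_group", "exotic"),
         ("provenance", ""), ("flavor", "x")],
    )
    def test_invalid_specs_rejected(self, kind, value):
        with pytest.raises(ValueError):
            SubsetSpec(kind, value)
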