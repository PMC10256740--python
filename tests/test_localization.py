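"""Fractionation statistics, FISH distances, qPCR and isoform fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from granulekit.geometry import NeuriteGeometry
from granulekit.localization import (cell_p95, centrosomal_rna_fraction,
                                     clip_density_shift, isoform_fraction,
                                     localization_ratio, mislocalized_set,
                                     normalize_cyclic_loess,
                                     overlap_enrichment,
                                     qpcr_membrane_enrichment,
                                     spot_neurite_distance)
from granulekit.synthetic import (CountTableSpec, simulate_fractionation_counts,
                                  simulate_neurite_field, simulate_qpcr)


def _two_condition_samples():
    return pd.DataFrame({
        "sample": ["c_s", "c_n", "p_s", "p_n"],
        "compartment": ["soma", "neurite"] * 2,
        "condition": ["ctrl", "ctrl", "pert", "pert"],
    })


class TestCyclicLoess:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"a": rng.integers(1, 1000, 300)})
        counts["b"] = counts["a"]
        normed = normalize_cyclic_loess(counts)
        expected = np.log2(counts + 0.5)
        assert np.allclose(normed, expected, atol=1e-9)

    def test_constant_scaling_removed(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 5000, 500)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        normed = normalize_cyclic_loess(counts)
        m = normed["a"] - normed["b"]
        assert abs(m.mean()) < 0.05  # the ~1 log2 offset is gone

    def test_per_gene_average_preserved(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 2000, size=(400, 3)),
                              columns=list("abc"))
        normed = normalize_cyclic_loess(counts)
        raw_a = np.log2(counts + 0.5).mean(axis=1)
        assert np.allclose(normed.mean(axis=1), raw_a, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize_cyclic_loess(pd.DataFrame({"a": [1, 2, 3]}))


class TestLocalizationRatio:
    def _normed(self, soma, neurite):
        genes = [f"g{i}" for i in range(len(soma))]
        df = pd.DataFrame({"c_s": soma, "c_n": neurite,
                           "p_s": soma, "p_n": neurite},
                          index=genes, dtype=float)
        return df

    def test_equal_compartments_zero_ratio(self):
        normed = self._normed([5.0, 6.0], [5.0, 6.0])
        loc = localization_ratio(normed, _two_condition_samples())
        assert np.allclose(loc.table["L_ctrl"], 0.0)

    def test_fourfold_counts_give_log2_two(self):
        # neurite 800 vs soma 200 counts, equal libraries: L -> ~2
        counts = pd.DataFrame({"c_s": [200], "c_n": [800],
                               "p_s": [200], "p_n": [800]}, index=["g0"])
        normed = np.log2(counts + 0.5)
        loc = localization_ratio(normed, _two_condition_samples(),
                                 expression_threshold=0.0)
        assert loc.table.loc["g0", "L_ctrl"] == pytest.approx(2.0, abs=0.01)

    def test_shift_vs_self_is_zero(self):
        normed = self._normed([5.0, 7.0, 3.0], [6.0, 6.5, 3.5])
        loc = localization_ratio(normed, _two_condition_samples())
        assert np.allclose(loc.table["dL_pert"], 0.0)

    def test_expression_filter_flags_low_genes(self):
        normed = self._normed([0.2, 8.0], [0.3, 8.0])
        loc = localization_ratio(normed, _two_condition_samples(),
                                 expression_threshold=1.0)
        assert list(loc.table["passes_filter"]) == [False, True]

    def test_missing_compartment_rejected(self):
        normed = self._normed([5.0], [5.0])
        bad = _two_condition_samples()
        bad.loc[bad["sample"] == "c_s", "compartment"] = "neurite"
        with pytest.raises(ValueError, match="soma"):
            localization_ratio(normed, bad)


class TestClipDensityShift:
    def test_reference_bin_p_one_and_recovery(self):
        spec = CountTableSpec(n_genes=1200, effect_size=-0.5, seed=5)
        sim = simulate_fractionation_counts(spec)
        normed = np.log2(sim.counts + 0.5)  # balanced libraries by design
        loc = localization_ratio(normed, sim.samples, control="control",
                                 expression_threshold=-10)
        bins = clip_density_shift(loc, sim.clip, seed=0)
        assert bins.loc[0, "p_vs_zero"] == 1.0
        assert bins.iloc[-1]["median_dL"] == pytest.approx(-0.5, abs=0.15)
        assert bins.iloc[-1]["p_vs_zero"] < 0.005
        # unaffected bins stay near zero
        assert abs(bins.loc[0, "median_dL"]) < 0.1

    def test_null_simulation_flat(self):
        spec = CountTableSpec(n_genes=1200, effect_size=0.0, seed=6)
        sim = simulate_fractionation_counts(spec)
        normed = np.log2(sim.counts + 0.5)
        loc = localization_ratio(normed, sim.samples, control="control",
                                 expression_threshold=-10)
        bins = clip_density_shift(loc, sim.clip, seed=0)
        assert (bins["median_dL"].abs() < 0.1).all()
        assert (bins["p_vs_zero"].iloc[1:] > 0.005).all()


class TestMislocalizedSet:
    def _loc(self, dl):
        genes = [f"g{i}" for i in range(len(dl))]
        table = pd.DataFrame({"L_ctrl": 0.0, "L_pert": dl, "dL_pert": dl,
                              "passes_filter": True},
                             index=genes)
        from granulekit.localization import LocalizationTable
        return LocalizationTable(table, "ctrl", 1.0)

    def test_threshold_inclusion(self):
        loc = self._loc([-0.3, 0.3, -0.2])
        assert mislocalized_set(loc, delta_threshold=0.25) == {"g0"}

    def test_zero_threshold_matches_sign_oracle(self):
        rng = np.random.default_rng(3)
        dl = rng.normal(0, 1, 50)
        loc = self._loc(dl)
        got = mislocalized_set(loc, delta_threshold=0.0)
        expected = {f"g{i}" for i in range(50) if dl[i] <= 0}
        assert got == expected


class TestOverlapEnrichment:
    def test_fold_examples(self):
        universe = [f"g{i}" for i in range(1000)]
        a = set(universe[:100])
        b = set(universe[74:174])  # overlap 26
        res = overlap_enrichment(a, b, 1000)
        assert res.fold == pytest.approx(2.6)
        b10 = set(universe[90:190])  # overlap 10 = expected
        assert overlap_enrichment(a, b10, 1000).fold == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        # brute-force two-tailed Fisher p on an N=30 toy universe:
        # sum of P(K=k) over all k at most as probable as observed
        N, na, nb, k_obs = 30, 8, 10, 6
        a = set(range(na))
        b = set(range(na - k_obs, na - k_obs + nb))
        res = overlap_enrichment(a, b, N)
        pk = [stats.hypergeom.pmf(k, N, na, nb)
              for k in range(max(0, na + nb - N), min(na, nb) + 1)]
        p_obs = stats.hypergeom.pmf(k_obs, N, na, nb)
        expected = sum(p for p in pk if p <= p_obs * (1 + 1e-9))
        assert res.p == pytest.approx(expected, rel=1e-6)

    def test_random_sets_fold_one_on_average(self):
        rng = np.random.default_rng(4)
        folds = []
        for _ in range(1000):
            a = set(rng.choice(500, 60, replace=False))
            b = set(rng.choice(500, 60, replace=False))
            folds.append(overlap_enrichment(a, b, 500).fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), {"g1"}, 10)


class TestSpotDistances:
    @pytest.fixture
    def geometry(self):
        return NeuriteGeometry((0.0, 0.0), [
            np.array([[0.0, 0.0], [100.0, 0.0]]),
        ])

    def test_tip_midpoint_and_soma(self, geometry):
        spots = pd.DataFrame({"cell_id": 0,
                              "x_um": [100.0, 50.0, 0.0],
                              "y_um": [0.0, 0.5, 0.0]})
        d = spot_neurite_distance(spots, geometry)
        assert d["fraction"].tolist() == pytest.approx([1.0, 0.5, 0.0])

    def test_unassignable_spot_flagged(self, geometry):
        spots = pd.DataFrame({"cell_id": 0, "x_um": [50.0], "y_um": [30.0]})
        d = spot_neurite_distance(spots, geometry, max_assign_um=2.0)
        assert not d["assigned"].iloc[0]
        assert np.isnan(d["fraction"].iloc[0])

    def test_fraction_monotone_in_arclength(self, geometry):
        xs = np.linspace(0, 100, 25)
        spots = pd.DataFrame({"cell_id": 0, "x_um": xs, "y_um": 0.2})
        d = spot_neurite_distance(spots, geometry)
        assert (np.diff(d["fraction"]) >= 0).all()
        assert d["fraction"].between(0, 1).all()

    def test_round_trip_with_simulator(self, geometry):
        spots = simulate_neurite_field(geometry, 200, ("uniform",), seed=9)
        d = spot_neurite_distance(spots, geometry)
        assert np.allclose(d["fraction"], spots["true_fraction"], atol=1e-9)


class TestCellP95:
    def test_constant_distances(self):
        d = pd.DataFrame({"cell_id": 0, "fraction": np.full(200, 0.3)})
        out = cell_p95(d, min_spots=150)
        assert out.loc[0, "p95"] == pytest.approx(0.3)

    def test_uniform_order_statistic(self):
        rng = np.random.default_rng(10)
        d = pd.DataFrame({"cell_id": 0, "fraction": rng.uniform(0, 1, 10_000)})
        out = cell_p95(d, min_spots=150)
        assert out.loc[0, "p95"] == pytest.approx(0.95, abs=0.01)

    def test_low_count_cell_excluded(self):
        d = pd.DataFrame({
            "cell_id": [0] * 100 + [1] * 200,
            "fraction": np.concatenate([np.full(100, 0.5), np.full(200, 0.5)]),
        })
        out = cell_p95(d, min_spots=150)
        assert out["cell_id"].tolist() == [1]

    def test_depletion_lowers_p95(self):
        """Spots pushed toward the soma lower the per-cell p95 — the
        direction of a distal-transport defect."""
        geom = NeuriteGeometry((0, 0), [np.array([[0.0, 0.0], [100.0, 0.0]])])
        p95s = []
        for a_param in (1.0, 0.5, 0.25):  # increasing depletion of distal spots
            spots = simulate_neurite_field(geom, 400, ("beta", a_param, 1.0),
                                           seed=11)
            d = spot_neurite_distance(spots, geom)
            p95s.append(cell_p95(d, min_spots=150).loc[0, "p95"])
        assert p95s[0] > p95s[1] > p95s[2]


class TestCentrosomalFraction:
    def _masks(self):
        cell = np.zeros((50, 50), bool)
        cell[5:45, 5:45] = True
        centro = np.zeros((50, 50), bool)
        centro[20:25, 20:25] = True
        return cell, centro

    def test_all_inside_centrosome(self):
        cell, centro = self._masks()
        spots = pd.DataFrame({"x_um": [21.0, 22.0], "y_um": [21.0, 22.0]})
        assert centrosomal_rna_fraction(spots, centro, cell) == 1.0

    def test_none_inside(self):
        cell, centro = self._masks()
        spots = pd.DataFrame({"x_um": [10.0, 40.0], "y_um": [10.0, 40.0]})
        assert centrosomal_rna_fraction(spots, centro, cell) == 0.0

    def test_partial_fraction(self):
        cell, centro = self._masks()
        xs = [21.0] * 20 + [10.0] * 80
        spots = pd.DataFrame({"x_um": xs, "y_um": xs})
        assert centrosomal_rna_fraction(spots, centro, cell) == pytest.approx(0.2)

    def test_no_spots_in_cell_rejected(self):
        cell, centro = self._masks()
        spots = pd.DataFrame({"x_um": [1.0], "y_um": [1.0]})
        with pytest.raises(ValueError):
            centrosomal_rna_fraction(spots, centro, cell)


class TestQpcrEnrichment:
    def test_all_equal_ct_unity(self):
        t = simulate_qpcr(1.0, 0.0, 3, seed=0)
        fold, pct = qpcr_membrane_enrichment(t)
        assert fold == pytest.approx(1.0)
        assert pct == pytest.approx(0.0)

    def test_one_cycle_gives_twofold(self):
        t = simulate_qpcr(2.0, 0.0, 2, seed=0)
        assert qpcr_membrane_enrichment(t)[0] == pytest.approx(2.0)

    def test_sixty_percent_round_trip(self):
        t = simulate_qpcr(1.6, 0.0, 5, seed=0)
        fold, pct = qpcr_membrane_enrichment(t)
        assert fold == pytest.approx(1.6)
        assert pct == pytest.approx(60.0)

    def test_missing_combination_rejected(self):
        t = simulate_qpcr(1.5, 0.0, 2, seed=0)
        broken = t[~((t.gene == "target") & (t.fraction == "membrane")
                     & (t.replicate == 1))]
        with pytest.raises(ValueError):
            qpcr_membrane_enrichment(broken)


class TestIsoformFraction:
    @pytest.mark.parametrize("alpha,beta,expected",
                             [(3.0, 1.0, 0.75), (0.0, 5.0, 0.0), (2.0, 2.0, 0.5)])
    def test_examples(self, alpha, beta, expected):
        assert isoform_fraction(alpha, beta) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            isoform_fraction(0.0, 0.0)
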