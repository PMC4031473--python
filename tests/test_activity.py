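"""Distance-based activator/repressor inference and regulatory potential."""

import math

import numpy as np
import pytest

import chipexpr as ce
from chipexpr.activity import ecdf_at
from chipexpr.core import ValidationError

from conftest import make_gene, make_peak


class TestNearestPeakDistance:
    def test_min_over_summits(self):
        gene = make_gene("G", tx_start=10_000, tx_end=12_000)
        peaks = [make_peak(start=7_800, end=8_200, summit=8_000),
                 make_peak(start=13_300, end=13_700, summit=13_500)]
        assert ce.nearest_peak_distance([gene], peaks)["G"] == 2000

    def test_no_peak_on_chromosome_is_infinite(self):
        gene = make_gene("G", chrom="chr5", tx_start=10_000, tx_end=12_000)
        peaks = [make_peak(chrom="chr1")]
        assert math.isinf(ce.nearest_peak_distance([gene], peaks)["G"])

    def test_summit_at_tss_is_zero(self):
        gene = make_gene("G", tx_start=10_000, tx_end=12_000)
        peak = make_peak(start=9_800, end=10_200, summit=10_000)
        assert ce.nearest_peak_distance([gene], [peak])["G"] == 0


class TestEcdf:
    def test_step_values(self):
        x, f, n_inf = ce.ecdf([0.0, 10.0, 20.0])
        assert f[list(x).index(10.0)] == pytest.approx(2 / 3)
        assert f[-1] == 1.0
        assert n_inf == 0
        # F(x) = 1 for any x >= max
        assert ecdf_at(np.array([0.0, 10.0, 20.0]), np.array([25.0]))[0] == 1.0

    def test_infinite_sentinels_excluded_but_counted(self):
        x, f, n_inf = ce.ecdf([1.0, math.inf, 2.0, math.inf])
        assert n_inf == 2
        assert len(x) == 2 and f[-1] == 1.0

    def test_below_minimum_is_zero(self):
        x, _, _ = ce.ecdf([5.0, 6.0])
        assert ecdf_at(np.array([5.0, 6.0]), np.array([-1.0]))[0] == 0.0

    def test_all_infinite_rejected(self):
        with pytest.raises(ValidationError):
            ce.ecdf([math.inf, math.inf])


class TestKsOneSided:
    def test_worked_example(self):
        call = ce.ks_one_sided([0, 0, 0, 0], [10, 20, 30, 40])
        assert call.d_plus == 1.0
        assert call.p == pytest.approx(math.exp(-4.0), rel=1e-9)

    def test_identical_samples(self):
        call = ce.ks_one_sided([1, 2, 3], [1, 2, 3])
        assert call.d_plus == 0.0 and call.p == 1.0

    def test_farther_set_gives_zero_d_plus(self):
        call = ce.ks_one_sided([100], [1, 2, 3])
        assert call.d_plus == 0.0 and call.p == 1.0

    def test_d_plus_matches_brute_force_sup(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.uniform(0, 50, size=int(rng.integers(2, 15)))
            b = rng.uniform(0, 50, size=int(rng.integers(2, 15)))
            call = ce.ks_one_sided(a, b)
            grid = np.concatenate([a, b])
            sup = max(
                (a <= x).mean() - (b <= x).mean() for x in grid
            )
            assert call.d_plus == pytest.approx(max(0.0, sup), abs=1e-12)
            assert 0.0 <= call.d_plus <= 1.0

    def test_infinite_distances_reported_not_imputed(self):
        call = ce.ks_one_sided([1.0, math.inf], [5.0, 6.0, math.inf])
        assert call.n_set == 1 and call.n_set_infinite == 1
        assert call.n_background == 2 and call.n_background_infinite == 1

    def test_permutation_method_deterministic(self):
        a = [1.0, 2.0, 3.0]
        b = [4.0, 5.0, 6.0, 7.0]
        p1 = ce.ks_one_sided(a, b, method="permutation",
                             n_permutations=500, rng_seed=3).p
        p2 = ce.ks_one_sided(a, b, method="permutation",
                             n_permutations=500, rng_seed=3).p
        assert p1 == p2

    def test_empty_finite_sample_rejected(self):
        with pytest.raises(ValidationError):
            ce.ks_one_sided([math.inf], [1.0])


class TestRegulatoryPotential:
    def test_peak_at_tss(self):
        gene = make_gene("G", tx_start=50_000, tx_end=60_000)
        peak = make_peak(start=49_800, end=50_200, summit=50_000)
        rp = ce.regulatory_potential(gene, [peak], 100_000, 100_000)
        assert rp == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_peak_at_decay_distance(self):
        gene = make_gene("G", tx_start=200_000, tx_end=210_000)
        peak = make_peak(start=99_800, end=100_200, summit=100_000)
        rp = ce.regulatory_potential(gene, [peak], 100_000, 100_000)
        assert rp == pytest.approx(math.exp(-4.5), rel=1e-9)

    def test_no_peaks_within_horizon(self):
        gene = make_gene("G", tx_start=500_000, tx_end=510_000)
        peak = make_peak(start=0, end=400, summit=200)
        assert ce.regulatory_potential(gene, [peak], 100_000, 100_000) == 0.0

    def test_strictly_decreasing_and_additive(self):
        gene = make_gene("G", tx_start=50_000, tx_end=60_000)
        near = make_peak(start=49_000, end=49_400, summit=49_200)
        far = make_peak(start=40_000, end=40_400, summit=40_200)
        rp_near = ce.regulatory_potential(gene, [near], 100_000, 100_000)
        rp_far = ce.regulatory_potential(gene, [far], 100_000, 100_000)
        rp_both = ce.regulatory_potential(gene, [near, far], 100_000, 100_000)
        assert rp_near > rp_far > 0
        assert rp_both == pytest.approx(rp_near + rp_far, rel=1e-12)


class TestSelectTopRegulated:
    def de(self, rows):
        return [ce.DEResult(g, 0, 0, delta, 0, p, p, "ns")
                for g, p, delta in rows]

    def test_toy_rank_product(self):
        results = self.de([("g1", 1e-5, -2.0), ("g2", 1e-3, -1.0),
                           ("g3", 1e-4, 1.0)])
        rp = {"g1": 1.0, "g2": 1.0, "g3": 1.0}
        active, repressive, shortfall = ce.select_top_regulated(results, rp, 1)
        assert active == ["g1"]
        assert repressive == ["g3"]
        assert shortfall == {}

    def test_shortfall_reported(self):
        results = self.de([("g1", 1e-5, -2.0)])
        active, repressive, shortfall = ce.select_top_regulated(results, {}, 5)
        assert active == ["g1"] and repressive == []
        assert shortfall == {"active": 4, "repressive": 5}

    def test_zero_rp_reduces_to_de_rank(self):
        results = self.de([("b", 1e-3, -1.0), ("a", 1e-5, -1.0),
                           ("c", 1e-4, -1.0)])
        active, _, _ = ce.select_top_regulated(results, {}, 3)
        assert active == ["a", "c", "b"]

    def test_input_order_invariant(self):
        rows = [("g%d" % i, p, -1.0) for i, p in
                enumerate([0.5, 1e-4, 0.02, 1e-4, 0.3])]
        rp = {f"g{i}": float(i) for i in range(5)}
        a1, _, _ = ce.select_top_regulated(self.de(rows), rp, 3)
        a2, _, _ = ce.select_top_regulated(self.de(rows[::-1]), rp, 3)
        assert a1 == a2

    def test_rp_breaks_de_ties(self):
        results = self.de([("low_rp", 1e-4, -1.0), ("high_rp", 1e-4, -1.0)])
        rp = {"low_rp": 0.1, "high_rp": 5.0}
        active, _, _ = ce.select_top_regulated(results, rp, 2)
        assert active[0] == "high_rp"


class TestCallFactorDirection:
    def test_planted_activator_only(self):
        cfg = ce.SyntheticConfig(seed=21, repressor_effect=0.0)
        ds = ce.generate(cfg, include_genome=False, include_coverage=False)
        results = ce.run_de(ds.expression, 0.001)
        dec, inc = ce.de_sets(results, 0.001, use_adjusted=False)
        dist = ce.nearest_peak_distance(ds.genes, ds.peaks["TF_A"])
        calls = ce.call_factor_direction(dec, inc, dist, alpha=0.01)
        assert calls["labels"] == ["activator evidence"]

    def test_planted_dual_role(self):
        ds = ce.generate(ce.SyntheticConfig(seed=22),
                         include_genome=False, include_coverage=False)
        results = ce.run_de(ds.expression, 0.001)
        dec, inc = ce.de_sets(results, 0.001, use_adjusted=False)
        dist = ce.nearest_peak_distance(ds.genes, ds.peaks["TF_A"])
        calls = ce.call_factor_direction(dec, inc, dist, alpha=0.01)
        assert set(calls["labels"]) == {"activator evidence",
                                        "repressor evidence"}
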