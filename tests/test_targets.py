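"""TSS-window target assignment and peak location classification."""

import numpy as np
import pytest

import chipexpr as ce
from chipexpr.core import ConfigurationError
from chipexpr.targets import classify_peak_locations, signed_distance

from conftest import make_gene, make_peak


class TestTss:
    def test_plus_strand(self):
        assert make_gene(strand="+", tx_start=1000, tx_end=5000).tss == 1000

    def test_minus_strand(self):
        assert make_gene(strand="-", tx_start=1000, tx_end=5000).tss == 4999

    def test_shared_start_opposite_strands(self):
        g1 = make_gene("A", strand="+", tx_start=1000, tx_end=5000)
        g2 = make_gene("B", strand="-", tx_start=1000, tx_end=5000)
        assert g1.tss != g2.tss


class TestAssignTargets:
    def test_signed_distance_and_membership(self):
        gene = make_gene("G", tx_start=10_000, tx_end=20_000, strand="+")
        peak = make_peak(start=8_050, end=8_450, summit=8_250)
        tmap = ce.assign_targets([peak], [gene], 3000)
        assert tmap.target_genes == {"G"}
        assert tmap.assignments["G"] == [(0, -1750)]

    def test_boundary_is_inclusive(self):
        gene = make_gene("G", tx_start=10_000, tx_end=20_000, strand="+")
        at = make_peak(start=12_900, end=13_100, summit=13_000)
        beyond = make_peak(start=12_901, end=13_101, summit=13_001)
        assert ce.assign_targets([at], [gene], 3000).target_genes == {"G"}
        assert ce.assign_targets([beyond], [gene], 3000).target_genes == set()

    def test_no_peaks_empty_map(self):
        genes = [make_gene(f"G{i}", tx_start=1000 * (i + 1),
                           tx_end=1000 * (i + 1) + 500) for i in range(5)]
        assert ce.assign_targets([], genes, 3000).target_genes == set()

    def test_toy_four_genes(self):
        # TSSs at 1k/10k/20k/30k vs summits 1.5k/22k/50k, window 3 kb:
        # brute force over all pairs leaves gene1 (|1.5k-1k|=500) and
        # gene3 (|22k-20k|=2000)
        genes = [make_gene(f"gene{i + 1}", tx_start=t, tx_end=t + 500)
                 for i, t in enumerate([1000, 10_000, 20_000, 30_000])]
        peaks = [make_peak(start=s - 100, end=s + 100, summit=s, name=f"p{s}")
                 for s in [1500, 22_000, 50_000]]
        tmap = ce.assign_targets(peaks, genes, 3000)
        assert tmap.target_genes == {"gene1", "gene3"}

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ConfigurationError):
            ce.assign_targets([make_peak()], [], 3000)

    def test_minus_strand_sign_flip(self):
        gene = make_gene("G", strand="-", tx_start=5_000, tx_end=10_000)
        peak = make_peak(start=9_800, end=10_200, summit=9_999)  # TSS at 9999
        tmap = ce.assign_targets([peak], [gene], 3000)
        assert tmap.assignments["G"] == [(0, 0)]
        upstream = make_peak(start=10_500, end=10_900, summit=10_700)
        tmap = ce.assign_targets([upstream], [gene], 3000)
        assert tmap.assignments["G"] == [(0, -701)]

    def test_multi_transcript_min_distance(self):
        t1 = make_gene("G", tx_start=10_000, tx_end=20_000)
        t2 = make_gene("G", tx_start=12_000, tx_end=20_000)
        peak = make_peak(start=11_800, end=12_200, summit=12_000)
        tmap = ce.assign_targets([peak], [t1, t2], 3000)
        assert tmap.distance("G") == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        genes = [make_gene(f"G{i}", strand=rng.choice(["+", "-"]),
                           tx_start=int(s), tx_end=int(s) + 2000)
                 for i, s in enumerate(rng.integers(0, 500_000, size=100))]
        peaks = [make_peak(start=int(s), end=int(s) + 400, summit=int(s) + 200,
                           name=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 500_000, size=100))]
        window = 3000
        tmap = ce.assign_targets(peaks, genes, window)
        expected = {}
        for g in genes:
            for i, p in enumerate(peaks):
                if p.chrom == g.chrom and abs(p.summit - g.tss) <= window:
                    expected.setdefault(g.gene_id, set()).add(
                        (i, signed_distance(p.summit, g)))
        assert tmap.target_genes == set(expected)
        for gid in expected:
            assert set(tmap.assignments[gid]) == expected[gid]

    def test_translation_invariance(self):
        genes = [make_gene("G", tx_start=10_000, tx_end=15_000)]
        peaks = [make_peak(start=9_000, end=9_400, summit=9_200)]
        shift = 123_456
        genes2 = [make_gene("G", tx_start=10_000 + shift, tx_end=15_000 + shift)]
        peaks2 = [make_peak(start=9_000 + shift, end=9_400 + shift,
                            summit=9_200 + shift)]
        t1 = ce.assign_targets(peaks, genes, 3000)
        t2 = ce.assign_targets(peaks2, genes2, 3000)
        assert t1.assignments == t2.assignments

    def test_window_monotonicity(self):
        rng = np.random.default_rng(3)
        genes = [make_gene(f"G{i}", tx_start=int(s), tx_end=int(s) + 1000)
                 for i, s in enumerate(rng.integers(0, 100_000, size=30))]
        peaks = [make_peak(start=int(s), end=int(s) + 200, summit=int(s) + 100)
                 for s in rng.integers(0, 100_000, size=30)]
        small = ce.assign_targets(peaks, genes, 1000).target_genes
        large = ce.assign_targets(peaks, genes, 5000).target_genes
        assert small <= large


class TestClassifyLocations:
    def gene(self):
        return make_gene("G", tx_start=10_000, tx_end=40_000,
                         cds_start=15_000, cds_end=35_000,
                         exon_starts=(10_000, 20_000, 34_000),
                         exon_ends=(16_000, 21_000, 40_000))

    def test_upstream_promoter(self):
        peak = make_peak(start=9_400, end=9_600, summit=9_500)
        dist = classify_peak_locations([peak], [self.gene()], 3000)
        assert dist["promoter"] == (1, 1.0)

    def test_intron_far_from_tss(self):
        peak = make_peak(start=25_000, end=25_200, summit=25_100)
        dist = classify_peak_locations([peak], [self.gene()], 3000)
        assert dist["intron"][0] == 1

    def test_coding_exon(self):
        peak = make_peak(start=20_400, end=20_600, summit=20_500)
        dist = classify_peak_locations([peak], [self.gene()], 3000)
        assert dist["coding exon"][0] == 1

    def test_three_prime_utr(self):
        peak = make_peak(start=36_000, end=36_200, summit=36_100)
        dist = classify_peak_locations([peak], [self.gene()], 3000)
        assert dist["3'UTR"][0] == 1

    def test_chromosome_without_genes_is_intergenic(self):
        peak = make_peak(chrom="chr9", start=500, end=700, summit=600)
        dist = classify_peak_locations([peak], [self.gene()], 3000)
        assert dist["intergenic"][0] == 1

    def test_fractions_sum_to_one(self, small_dataset):
        dist = classify_peak_locations(small_dataset.peaks["TF_A"],
                                       small_dataset.genes, 3000)
        assert sum(f for _, f in dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(n for n, _ in dist.values()) == len(small_dataset.peaks["TF_A"])


class TestExpressedGenes:
    def test_threshold_inclusion(self, small_dataset):
        expr = small_dataset.expression
        everything = ce.expressed_genes(expr, float("-inf"))
        assert everything == set(expr.row_ids)
        assert ce.expressed_genes(expr, expr.values.max() + 1) == set()

    def test_mean_of_control_only(self):
        expr = ce.ExpressionMatrix(
            ["g1"], ["c1", "c2", "k1", "k2"],
            np.array([[5.0, 6.0, 0.0, 0.0]]),
            {"c1": "control", "c2": "control",
             "k1": "knockdown", "k2": "knockdown"},
        )
        assert ce.expressed_genes(expr, 4.0) == {"g1"}
        assert ce.expressed_genes(expr, 5.6) == set()

    def test_unannotated_ids_warn_but_retained(self):
        expr = ce.ExpressionMatrix(
            ["novel"], ["c1", "c2"], np.array([[9.0, 9.0]]),
            {"c1": "control", "c2": "control"},
        )
        with pytest.warns(UserWarning):
            kept = ce.expressed_genes(expr, 0.0, annotated_ids={"G1"})
        assert kept == {"novel"}
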