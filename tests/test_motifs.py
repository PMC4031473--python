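"""PWM scoring, window scanning and Fisher-exact motif enrichment."""

import math

import numpy as np
import pytest

import chipexpr as ce
from chipexpr.core import ValidationError
from chipexpr.motifs import PWM, reverse_complement
from chipexpr.synthetic import PLANTED_MOTIF

from conftest import make_peak


def consensus_pwm(seq="AC"):
    rows = []
    for ch in seq:
        row = [0.0] * 4
        row["ACGT".index(ch)] = 1.0
        rows.append(row)
    return PWM("test", np.array(rows))


def fisher_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher exact p by enumeration over tables
    with the observed margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)
                / math.comb(n, col1))

    return sum(prob(x) for x in range(a, min(row1, col1) + 1)
               if col1 - x <= row2)


class TestPWM:
    def test_consensus_scores_max_bits(self):
        pwm = consensus_pwm("AC")
        assert ce.logodds_score("AC", pwm, 0, "+") == pytest.approx(4.0)
        assert pwm.max_score == pytest.approx(4.0)

    def test_background_pwm_scores_zero(self):
        pwm = PWM("bg", np.full((3, 4), 0.25))
        assert ce.logodds_score("ACG", pwm, 0, "+") == 0.0
        assert ce.logodds_score("TTT", pwm, 0, "+") == 0.0

    def test_reverse_strand_symmetry(self):
        pwm = PWM.from_consensus("m", "ACGTT")
        site = "ACGTT"
        fwd = ce.logodds_score(site, pwm, 0, "+")
        rev = ce.logodds_score(reverse_complement(site), pwm, 0, "-")
        assert fwd == pytest.approx(rev)

    def test_n_contributes_zero(self):
        pwm = consensus_pwm("AC")
        assert ce.logodds_score("AN", pwm, 0, "+") == pytest.approx(2.0)

    def test_offset_out_of_range(self):
        with pytest.raises(ValidationError):
            ce.logodds_score("AC", consensus_pwm("AC"), 1, "+")

    def test_jaspar_roundtrip(self, tmp_path):
        text = ">toy\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        path = tmp_path / "toy.jaspar"
        path.write_text(text)
        pwm = ce.read_jaspar(str(path), pseudocount=0.0)
        assert len(pwm) == 2
        assert pwm.matrix[0, 0] == 1.0

    def test_builtin_pwms_load(self):
        rest = ce.load_builtin_pwm("rest_nrse")
        e2f1 = ce.load_builtin_pwm("e2f1")
        assert len(rest) == len(PLANTED_MOTIF)
        assert len(e2f1) == 8
        # the planted consensus is that matrix's best hit
        score = ce.logodds_score(PLANTED_MOTIF, rest, 0, "+")
        assert score == pytest.approx(rest.max_score)


class TestSummitWindows:
    def test_centred(self):
        (w,) = ce.summit_windows([make_peak(start=900, end=1100,
                                            summit=1000)], 600)
        assert (w.start, w.end) == (700, 1300)

    def test_truncated_at_bounds(self):
        (w,) = ce.summit_windows([make_peak(start=50, end=250, summit=100)],
                                 600, {"chr1": 10_000})
        assert (w.start, w.end) == (0, 400)

    def test_shared_summits_both_emitted(self):
        peaks = [make_peak(start=900, end=1100, summit=1000, name="a"),
                 make_peak(start=950, end=1050, summit=1000, name="b")]
        windows = ce.summit_windows(peaks, 600)
        assert windows[0] == windows[1]

    def test_odd_width_rejected(self):
        with pytest.raises(ValidationError):
            ce.summit_windows([make_peak()], 601)


class TestScanWindows:
    def genome(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        # plant consensus at 500
        seq = seq[:500] + PLANTED_MOTIF + seq[500 + len(PLANTED_MOTIF):]
        return {"chr1": seq}

    def test_planted_consensus_found(self):
        genome = self.genome()
        pwm = ce.load_builtin_pwm("rest_nrse")
        windows = [ce.GenomicInterval("chr1", 300, 900)]
        hits, flags = ce.scan_windows(windows, genome, pwm, pwm.max_score)
        assert flags["chr1:300-900"]
        assert any(h.offset == 200 and h.strand == "+" for h in hits)

    def test_reverse_strand_hit(self):
        pwm = ce.load_builtin_pwm("rest_nrse")
        rc = reverse_complement(PLANTED_MOTIF)
        genome = {"chr1": "A" * 40 + rc + "A" * 40}
        windows = [ce.GenomicInterval("chr1", 0, len(genome["chr1"]))]
        hits, flags = ce.scan_windows(windows, genome, pwm, pwm.max_score)
        assert any(h.strand == "-" and h.offset == 40 for h in hits)

    def test_all_n_window_no_hits(self):
        genome = {"chr1": "N" * 100}
        pwm = consensus_pwm("AC")
        hits, flags = ce.scan_windows(
            [ce.GenomicInterval("chr1", 0, 100)], genome, pwm, 0.1)
        assert hits == [] and flags["chr1:0-100"] is False

    def test_infinite_threshold_no_hits(self):
        hits, flags = ce.scan_windows(
            [ce.GenomicInterval("chr1", 0, 50)], {"chr1": "ACGT" * 25},
            consensus_pwm("AC"), float("inf"))
        assert hits == []

    def test_window_beyond_sequence_rejected(self):
        with pytest.raises(ValidationError):
            ce.scan_windows([ce.GenomicInterval("chr1", 0, 200)],
                            {"chr1": "ACGT"}, consensus_pwm("AC"), 0.0)


class TestEnrichment:
    def build(self, fg_hit, fg_total, bg_hit, bg_total):
        """Windows of 30 bp; 'hit' windows contain the AC consensus."""
        pwm = consensus_pwm("ACGTAC")
        seqs = []
        windows = []
        pos = 0
        flags = [True] * fg_hit + [False] * (fg_total - fg_hit) + \
            [True] * bg_hit + [False] * (bg_total - bg_hit)
        for flag in flags:
            block = ("TTTT" + "ACGTAC" + "TTTT" * 5) if flag else "T" * 30
            seqs.append(block[:30])
            windows.append(ce.GenomicInterval("chr1", pos, pos + 30))
            pos += 30
        genome = {"chr1": "".join(seqs)}
        fg = windows[:fg_total]
        bg = windows[fg_total:]
        return fg, bg, genome, pwm

    def test_enriched_foreground(self):
        fg, bg, genome, pwm = self.build(8, 10, 2, 10)
        res = ce.motif_enrichment_test(fg, bg, genome, pwm)
        assert res["fg_hits"] == 8 and res["bg_hits"] == 2
        assert res["p_value"] < 0.05
        assert res["p_value"] == pytest.approx(fisher_oracle(8, 2, 2, 8),
                                               rel=1e-9)

    def test_equal_rates_not_significant(self):
        fg, bg, genome, pwm = self.build(5, 10, 5, 10)
        res = ce.motif_enrichment_test(fg, bg, genome, pwm)
        assert res["p_value"] >= 0.5

    def test_haldane_correction_keeps_or_finite(self):
        fg, bg, genome, pwm = self.build(6, 10, 0, 10)
        res = ce.motif_enrichment_test(fg, bg, genome, pwm)
        assert math.isfinite(res["odds_ratio"]) and res["odds_ratio"] > 0

    def test_matches_enumeration_for_small_margins(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            fg_total = int(rng.integers(1, 21))
            bg_total = int(rng.integers(1, 21))
            fg_hit = int(rng.integers(0, fg_total + 1))
            bg_hit = int(rng.integers(0, bg_total + 1))
            fg, bg, genome, pwm = self.build(fg_hit, fg_total,
                                             bg_hit, bg_total)
            res = ce.motif_enrichment_test(fg, bg, genome, pwm)
            oracle = fisher_oracle(fg_hit, fg_total - fg_hit,
                                   bg_hit, bg_total - bg_hit)
            assert res["p_value"] == pytest.approx(oracle, rel=1e-8)

    def test_strand_symmetry_of_enrichment(self):
        fg, bg, genome, pwm = self.build(7, 10, 1, 10)
        res = ce.motif_enrichment_test(fg, bg, genome, pwm)
        L = len(genome["chr1"])
        rc_genome = {"chr1": reverse_complement(genome["chr1"])}
        rc = lambda w: ce.GenomicInterval(w.chrom, L - w.end, L - w.start)
        res_rc = ce.motif_enrichment_test([rc(w) for w in fg],
                                          [rc(w) for w in bg],
                                          rc_genome, pwm)
        assert res_rc["fg_hits"] == res["fg_hits"]
        assert res_rc["p_value"] == pytest.approx(res["p_value"], rel=1e-12)


def test_random_background_windows_seeded():
    lengths = {"chr1": 5000, "chr2": 3000}
    w1 = ce.random_background_windows(lengths, 600, 20, seed=4)
    w2 = ce.random_background_windows(lengths, 600, 20, seed=4)
    assert w1 == w2
    assert all(len(w) == 600 for w in w1)
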