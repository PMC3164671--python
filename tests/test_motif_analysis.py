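import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_revcomp, naive_scan

from striatarget import motif_analysis as ma
from striatarget.io_formats import PWMRecord
from striatarget.motif_analysis import (
    BackgroundModel,
    build_log_odds,
    canonical_kmer,
    discover_kmers,
    expand_pattern,
    fraction_containing,
    revcomp,
    sample_background,
    scan_sequence,
    zscore_p,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


def random_pwm(rng, L=6, lo=1, hi=20):
    counts = rng.integers(lo, hi, size=(L, 4)).astype(float)
    rec = PWMRecord("R", "rand", counts, "N" * L)
    return build_log_odds(rec)


class TestRevcomp:
    @given(seq=DNA)
    @settings(max_examples=80, deadline=None)
    def test_involution_and_oracle(self, seq):
        assert revcomp(revcomp(seq)) == seq
        assert revcomp(seq) == naive_revcomp(seq)

    @given(seq=st.text(alphabet="ACGT", min_size=4, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_canonical_stable(self, seq):
        assert canonical_kmer(seq) == canonical_kmer(revcomp(seq))
        assert canonical_kmer(seq) in (seq, revcomp(seq))


class TestBuildLogOdds:
    def test_uniform_counts_give_zero_weights(self):
        rec = PWMRecord("U", "", np.ones((6, 4)), "NNNNNN")
        pwm = build_log_odds(rec)
        np.testing.assert_allclose(pwm.weights, 0.0, atol=1e-12)

    def test_consensus_achieves_max_score(self, rng):
        counts = np.full((6, 4), 0.0)
        consensus = "TGTGGT"
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, b in enumerate(consensus):
            counts[i, idx[b]] = 10
        pwm = build_log_odds(PWMRecord("C", "", counts, consensus))
        hits = scan_sequence(consensus, pwm, both_strands=False)
        assert hits[0][2] == pytest.approx(pwm.max_score())

    def test_hand_computed_cell(self, rng):
        counts = rng.integers(1, 30, size=(6, 4)).astype(float)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pc = 0.25
        pwm = build_log_odds(PWMRecord("H", "", counts, "NNNNNN"), bg, pc)
        i, b = 3, 2
        want = math.log2(
            (counts[i, b] + pc * bg[b]) / (counts[i].sum() + pc) / bg[b]
        )
        assert pwm.weights[i, b] == pytest.approx(want, abs=1e-12)

    def test_zero_row_rejected(self):
        counts = np.ones((6, 4))
        counts[2] = 0
        with pytest.raises(ValueError, match="zero count row"):
            build_log_odds(PWMRecord("Z", "", counts, "NNNNNN"))


class TestScan:
    def test_matches_naive_oracle(self, rng):
        pwm = random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        got = scan_sequence(seq, pwm)
        want = naive_scan(seq, pwm.weights)
        assert len(got) == len(want)
        for (o1, s1, sc1), (o2, s2, sc2) in zip(got, want):
            assert (o1, s1) == (o2, s2)
            assert sc1 == pytest.approx(sc2, abs=1e-9)

    def test_n_windows_dropped(self, rng):
        pwm = random_pwm(rng)
        seq = "ACGTAN" + "ACGTAC" * 5
        got = scan_sequence(seq, pwm)
        assert all(
            "N" not in seq[o : o + pwm.length].upper() for o, _, _ in got
        )
        assert got == [
            (o, s, pytest.approx(sc, abs=1e-9)) for o, s, sc in naive_scan(seq, pwm.weights)
        ]

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        fwd = sorted(round(sc, 9) for _, _, sc in scan_sequence(seq, pwm))
        rev = sorted(round(sc, 9) for _, _, sc in scan_sequence(revcomp(seq), pwm))
        assert fwd == rev

    def test_too_short_sequence(self, rng):
        with pytest.raises(ValueError, match="sequence length"):
            scan_sequence("ACG", random_pwm(rng))


class TestBackground:
    def _genome(self, rng, n=50_000, masked=0.2):
        seq = rng.choice(list("ACGT"), size=n)
        lower = rng.random(n) < masked
        return "".join(b.lower() if m else b for b, m in zip(seq, lower))

    def test_deterministic_under_seed(self, rng):
        pwm = random_pwm(rng)
        genome = self._genome(rng)
        a = sample_background(pwm, genome, n=20_000, seed=5)
        b = sample_background(pwm, genome, n=20_000, seed=5)
        assert a == b

    def test_mean_stable_across_seeds(self, rng):
        pwm = random_pwm(rng)
        genome = self._genome(rng)
        a = sample_background(pwm, genome, n=100_000, seed=1)
        b = sample_background(pwm, genome, n=10_000, seed=2)
        assert abs(a.mean - b.mean) < 4 * a.sd / math.sqrt(10_000)

    def test_degenerate_background_rejected(self, rng):
        rec = PWMRecord("U", "", np.ones((6, 4)), "NNNNNN")
        pwm = build_log_odds(rec)  # all-zero weights
        genome = self._genome(rng)
        with pytest.raises(ValueError, match="degenerate background"):
            sample_background(pwm, genome, n=5_000, seed=1)

    def test_too_few_valid_positions(self, rng):
        pwm = random_pwm(rng)
        with pytest.raises(ValueError, match="< 1000"):
            sample_background(pwm, "ACGT" * 100, n=5_000, seed=1)


class TestZscore:
    def _bg(self):
        return BackgroundModel("M", mean=2.0, sd=1.5, n_samples=10_000, seed=0)

    def test_score_at_mean(self):
        z, p = zscore_p(2.0, self._bg())
        assert (z, p) == (0.0, 0.5)

    def test_threshold_quantile(self):
        # z = 3.0902 is the 0.999 normal quantile: p rounds to 0.0010
        _, p = zscore_p(2.0 + 1.5 * 3.0902, self._bg())
        assert round(p, 4) == 0.0010

    def test_p_strictly_decreasing_in_score(self):
        bg = self._bg()
        ps = [zscore_p(s, bg)[1] for s in np.linspace(-3, 8, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_two_sided_flag(self):
        _, p1 = zscore_p(5.0, self._bg())
        _, p2 = zscore_p(5.0, self._bg(), two_sided=True)
        assert p2 == pytest.approx(2 * p1)


class TestExpandPattern:
    def test_slash_alternative(self):
        assert expand_pattern("AGG/TTCA") == {"AGGTCA", "AGTTCA"}

    def test_bracket_class(self):
        assert expand_pattern("AG[AT]GTG") == {"AGAGTG", "AGTGTG"}

    def test_plain(self):
        assert expand_pattern("GGATCA") == {"GGATCA"}

    def test_malformed(self):
        with pytest.raises(ValueError):
            expand_pattern("AG[AT GTG")
        with pytest.raises(ValueError):
            expand_pattern("/AGT")


class TestFractionContaining:
    COUP = {"AGGTCA", "AGTTCA", "TGTACT"}

    def test_hit_on_plus(self):
        assert fraction_containing(["AGGTCANNN"], self.COUP) == 1.0

    def test_no_hits(self):
        assert fraction_containing(["CCCCCCCC"], self.COUP) == 0.0

    def test_empty_seqs_error(self):
        with pytest.raises(ValueError):
            fraction_containing([], self.COUP)

    def test_planted_fraction_matches_naive(self, rng):
        seqs = []
        for i in range(100):
            s = list(rng.choice(list("ACGT"), size=80))
            if i < 32:
                kmer = list(rng.choice(sorted(self.COUP)))
                if rng.random() < 0.5:
                    kmer = list(naive_revcomp("".join(kmer)))
                pos = int(rng.integers(0, 75))
                s[pos : pos + 6] = kmer
            seqs.append("".join(s))
        got = fraction_containing(seqs, self.COUP)
        search = self.COUP | {naive_revcomp(k) for k in self.COUP}
        want = sum(any(k in s for k in search) for s in seqs) / len(seqs)
        assert got == want
        assert got >= 0.32

    def test_monotone_in_kmer_set(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(40)]
        f1 = fraction_containing(seqs, {"AGGTCA"})
        f2 = fraction_containing(seqs, {"AGGTCA", "TGTACT"})
        assert 0.0 <= f1 <= f2 <= 1.0


class TestDiscoverKmers:
    def test_ubiquitous_kmer_ranks_first(self, rng):
        seqs = []
        for _ in range(30):
            s = "".join(rng.choice(list("ACGT"), size=50))
            seqs.append(s[:20] + "ACCACA" + s[26:])
        motifs = discover_kmers(seqs, 6, 25)
        assert motifs[0].kmer == "ACCACA"
        assert motifs[0].support == 30
        assert motifs[0].rank == 1

    def test_support_matches_naive_count(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(20)]
        motifs = discover_kmers(seqs, 4, 2)
        for m in motifs:
            keys = {m.kmer, naive_revcomp(m.kmer)}
            want = sum(
                any(
                    s[i : i + 4] in keys
                    for i in range(len(s) - 3)
                )
                for s in seqs
            )
            assert m.support == want

    def test_invariant_under_reverse_complementing_inputs(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(25)]
        flipped = [revcomp(s) if rng.random() < 0.5 else s for s in seqs]
        a = discover_kmers(seqs, 6, 2)
        b = discover_kmers(flipped, 6, 2)
        assert {(m.kmer, m.support) for m in a} == {(m.kmer, m.support) for m in b}

    def test_all_too_short(self):
        with pytest.raises(ValueError, match="shorter than k"):
            discover_kmers(["ACG", "TTA"], 6, 2)

    def test_parameter_bounds(self):
        with pytest.raises(ValueError):
            discover_kmers(["ACGTACGT"], 3, 2)
        with pytest.raises(ValueError):
            discover_kmers(["ACGTACGT"], 6, 1)


class TestScanCalibration:
    def test_null_rate_near_nominal(self, rng):
        """Windows drawn from the background itself score p < 0.001 at the
        nominal rate, within 3-sigma binomial.

        Holds in the regime where the score distribution is near-normal
        (weak, longer matrices); strong short motifs have discrete bounded
        tails and the normal approximation is not expected there.
        """
        from striatarget import synthetic_data as sd

        cfg = sd.SimConfig(
            genome_length=300_000, n_genes=2, n_peaks=2, seed=13,
            repeat_fraction=0.1, frac_peaks_within_10kb=0.0,
            frac_peaks_within_1kb=0.0,
        )
        from striatarget.pipeline import _genome_base_freqs

        genome, _ = sd.generate_genome(cfg)
        seq = genome[cfg.chrom]
        L = 14
        counts = rng.integers(90, 111, size=(L, 4)).astype(float)
        pwm = build_log_odds(
            PWMRecord("CAL", "", counts, "N" * L), _genome_base_freqs(genome)
        )
        bg = sample_background(pwm, genome, n=500_000, seed=3)
        starts = ma.valid_window_starts(seq, L)
        pos = rng.choice(starts, size=30_000, replace=True)
        enc = ma.encode(seq)
        col = np.arange(L)
        scores = pwm.weights[col, enc[pos[:, None] + col]].sum(axis=1)
        from scipy.stats import norm

        frac = float((norm.sf((scores - bg.mean) / bg.sd) < 0.001).mean())
        tol = 3 * math.sqrt(0.001 * 0.999 / 30_000)
        assert abs(frac - 0.001) <= tol
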