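import itertools

import numpy as np
import pytest

from cistromere.genome import Genome
from cistromere.intervals import GenomicInterval, PeakSet
from cistromere.motifs import (
    BASES,
    DensityProfile,
    PositionWeightMatrix,
    canonical_are_pwm,
    compare_fractions,
    differential_density,
    fraction_with_motif,
    load_motif,
    motif_density_profile,
    motif_enrichment,
    peak_has_motif,
    scan,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def indicator_pwm(word, eps=1e-9):
    """Near-deterministic PWM for a fixed word (score 2 bits per match)."""
    probs = np.full((len(word), 4), eps / 3)
    for i, b in enumerate(word):
        probs[i, BASES.index(b)] = 1 - eps
    probs /= probs.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(probs, name=word)


class TestPWMValidation:
    def test_row_sum_enforced(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError):
            PositionWeightMatrix(bad)

    def test_min_length(self):
        with pytest.raises(ValueError):
            PositionWeightMatrix(np.full((3, 4), 0.25))

    def test_from_counts_normalizes(self):
        counts = np.array([[10, 0, 0, 0]] * 5, dtype=float)
        pwm = PositionWeightMatrix.from_counts(counts, pseudocount=0.25)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_zero_count_column_uniform(self):
        counts = np.zeros((5, 4))
        counts[1:] = [10, 0, 0, 0]
        pwm = PositionWeightMatrix.from_counts(counts, pseudocount=0.25)
        assert np.allclose(pwm.probs[0], 0.25)


class TestLoadMotif:
    def test_jaspar_format(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0  5  1 ]\n"
            "C [ 0  10  5  1 ]\n"
            "G [ 0   0  0  8 ]\n"
            "T [ 0   0  0  0 ]\n"
        )
        pwm = load_motif(path)
        assert pwm.name == "TEST"
        assert pwm.length == 4
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_ragged_matrix_rejected(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 1 2 3 4\nC 1 2 3\nG 1 2 3 4\nT 1 2 3 4\n")
        with pytest.raises(ValueError, match="ragged"):
            load_motif(path)

    def test_negative_counts_rejected(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 1 2 3 4\nC 1 2 3 4\nG 1 2 3 4\nT 1 2 -3 4\n")
        with pytest.raises(ValueError):
            load_motif(path)

    def test_palindromic_pfm_equals_own_rc(self):
        pwm = canonical_are_pwm()
        rc = pwm.reverse_complement()
        assert np.allclose(pwm.probs, rc.probs)
        assert np.allclose(pwm.log_odds, rc.log_odds)


class TestScan:
    def test_indicator_hit(self):
        pwm = indicator_pwm("ACGT")
        hits = scan(pwm, "AACGTT", threshold=0.0)
        # ACGT is palindromic: the one real site, strand tie broken to '+'
        assert len(hits) == 1
        assert hits[0].position == 1
        assert hits[0].strand == "+"

    def test_strand_symmetry(self):
        pwm = indicator_pwm("ACGGT")
        seq = "TTACGGTTT"
        hits_f = scan(pwm, seq, threshold=0.0)
        hits_r = scan(pwm, revcomp(seq), threshold=0.0)
        assert len(hits_f) == len(hits_r) == 1
        assert hits_f[0].strand == "+"
        assert hits_r[0].strand == "-"
        assert hits_f[0].score == pytest.approx(hits_r[0].score)

    def test_short_sequence_empty(self, are_pwm):
        assert scan(are_pwm, "ACGT") == []

    def test_n_windows_excluded(self):
        pwm = indicator_pwm("ACGT")
        assert scan(pwm, "ACGN", threshold=-100.0) == []

    def test_exhaustive_oracle_small(self, rng, are_pwm, are_threshold):
        """Scan matches a brute-force all-offset scorer (subset; the full
        1,000-sequence version is an acceptance criterion)."""
        lo_f = are_pwm.log_odds
        lo_r = are_pwm.reverse_complement().log_odds
        L = are_pwm.length
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            expected = []
            for pos in range(len(seq) - L + 1):
                window = seq[pos:pos + L]
                sf = sum(lo_f[j, BASES.index(window[j])] for j in range(L))
                sr = sum(lo_r[j, BASES.index(window[j])] for j in range(L))
                best, strand = (sf, "+") if sf >= sr else (sr, "-")
                if best >= are_threshold - 6:
                    expected.append((pos, strand, best))
            got = scan(are_pwm, seq, threshold=are_threshold - 6)
            assert [(h.position, h.strand) for h in got] == [
                (p, s) for p, s, _ in expected
            ]
            assert np.allclose(
                [h.score for h in got], [sc for _, _, sc in expected]
            )


class TestPeakHasMotif:
    def test_planted_site_at_center(self, poly_t_genome, are_pwm):
        consensus = are_pwm.consensus()
        peak = GenomicInterval("chr1", 5000, 5200)
        center = 5100
        poly_t_genome.set_sequence(
            "chr1", center - are_pwm.length // 2, consensus
        )
        assert peak_has_motif(peak, poly_t_genome, are_pwm)

    def test_site_outside_window(self, poly_t_genome, are_pwm):
        peak = GenomicInterval("chr1", 5000, 5200)
        poly_t_genome.set_sequence("chr1", 5100 + 300, are_pwm.consensus())
        assert not peak_has_motif(peak, poly_t_genome, are_pwm, window=100)
        assert peak_has_motif(peak, poly_t_genome, are_pwm, window=700)

    def test_missing_chromosome(self, poly_t_genome, are_pwm):
        with pytest.raises(KeyError):
            peak_has_motif(
                GenomicInterval("chrX", 0, 100), poly_t_genome, are_pwm
            )


class TestFractionWithMotif:
    def test_counts_match_per_peak_calls(self, poly_t_genome, are_pwm):
        peaks = []
        for i in range(10):
            start = 1000 + i * 500
            peaks.append(GenomicInterval("chr1", start, start + 200))
        for iv in peaks[:7]:
            center = (iv.start + iv.end) // 2
            poly_t_genome.set_sequence(
                "chr1", center - are_pwm.length // 2, are_pwm.consensus()
            )
        ps = PeakSet(peaks)
        frac = fraction_with_motif(ps, poly_t_genome, are_pwm)
        assert frac == 0.7
        recount = np.mean(
            [peak_has_motif(iv, poly_t_genome, are_pwm) for iv in ps]
        )
        assert frac == recount

    def test_empty_set_errors(self, poly_t_genome, are_pwm):
        with pytest.raises(ValueError):
            fraction_with_motif(PeakSet([]), poly_t_genome, are_pwm)


class TestCompareFractions:
    def test_identical_paired_p_one(self):
        res = compare_fractions([0.5, 0.4, 0.3], [0.5, 0.4, 0.3], paired=True)
        assert res["pvalue"] == 1.0

    def test_unpaired_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: all 20 label assignments enumerated."""
        res = compare_fractions([1, 2, 3], [4, 5, 6])
        pooled = [1, 2, 3, 4, 5, 6]
        u_obs = sum(a > b for a in [1, 2, 3] for b in [4, 5, 6])
        u_obs = max(u_obs, 9 - u_obs)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u = sum(x > y for x in a for y in b)
            u = max(u, 9 - u)
            total += 1
            if u >= u_obs:
                count += 1
        assert res["pvalue"] == pytest.approx(count / total)
        assert res["pvalue"] == pytest.approx(0.1)

    def test_paired_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            compare_fractions([1, 2], [1, 2, 3], paired=True)

    def test_eight_concordant_pairs(self):
        normal = [0.5 + 0.01 * i for i in range(8)]
        tumor = [v - 0.2 for v in normal]
        res = compare_fractions(normal, tumor, paired=True)
        assert res["pvalue"] == pytest.approx(2 / 2**8, abs=1e-12)


class TestDensityProfile:
    def test_hit_at_every_center(self, poly_t_genome, are_pwm):
        peaks = []
        for i in range(5):
            start = 2000 + i * 3000
            iv = GenomicInterval("chr1", start, start + 200)
            center = (start + start + 200) // 2
            # plant so the hit *start* is exactly at the center offset 0
            poly_t_genome.set_sequence("chr1", center, are_pwm.consensus())
            peaks.append(iv)
        prof = motif_density_profile(
            PeakSet(peaks), poly_t_genome, are_pwm, window=2400, bin_size=10
        )
        central = prof.window // (2 * prof.bin_size)
        assert prof.values[central] == pytest.approx(1 / 10)
        mask = np.ones(prof.n_bins, dtype=bool)
        mask[central] = False
        assert np.all(prof.values[mask] == 0)

    def test_no_hits_all_zero(self, poly_t_genome, are_pwm):
        ps = PeakSet([GenomicInterval("chr1", 5000, 5200)])
        prof = motif_density_profile(ps, poly_t_genome, are_pwm)
        assert np.all(prof.values == 0)

    def test_bin_must_divide_window(self, poly_t_genome, are_pwm):
        ps = PeakSet([GenomicInterval("chr1", 5000, 5200)])
        with pytest.raises(ValueError):
            motif_density_profile(
                ps, poly_t_genome, are_pwm, window=2400, bin_size=7
            )

    def test_integrates_to_hits_per_peak(self, poly_t_genome, are_pwm):
        """sum(value * bin_size) equals mean hits per peak in the window."""
        peaks = []
        n_sites = 0
        for i in range(4):
            start = 2000 + i * 4000
            peaks.append(GenomicInterval("chr1", start, start + 200))
            for off in (-400, 0, 350)[: i + 1]:
                poly_t_genome.set_sequence(
                    "chr1", start + 100 + off, are_pwm.consensus()
                )
                n_sites += 1
        prof = motif_density_profile(
            PeakSet(peaks), poly_t_genome, are_pwm, window=2400, bin_size=10
        )
        assert prof.values.sum() * prof.bin_size == pytest.approx(n_sites / 4)


class TestDifferentialDensity:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return DensityProfile(values, window=len(values) * 10, bin_size=10,
                              n_peaks=10)

    def test_identity_zero(self):
        a = self._profile(np.linspace(0, 1, 20))
        assert np.all(differential_density(a, a).values == 0)

    def test_center_enrichment_sign(self):
        center_peaked = np.zeros(21)
        center_peaked[8:13] = [0.1, 0.3, 0.5, 0.3, 0.1]
        a = self._profile(center_peaked)
        b = self._profile(np.full(21, 0.05))
        diff = differential_density(a, b)
        assert diff.values[10] > 0
        assert diff.values[0] < 0  # flat background above zero out of center

    def test_geometry_mismatch(self):
        a = self._profile(np.zeros(20))
        b = DensityProfile(np.zeros(10), window=200, bin_size=20, n_peaks=10)
        with pytest.raises(ValueError):
            differential_density(a, b)

    def test_smoothing_preserves_mean_on_quadratics(self):
        """A local quadratic fit reproduces quadratic inputs exactly."""
        x = np.arange(30, dtype=float)
        quad = 0.02 * x**2 - 0.3 * x + 1.0
        a = self._profile(quad)
        b = self._profile(np.zeros(30))
        smoothed = differential_density(a, b, smooth=True)
        assert np.allclose(smoothed.values, quad, atol=1e-9)
        assert smoothed.values.mean() == pytest.approx(quad.mean(), abs=1e-9)
        assert smoothed.metadata["smoothing"].startswith("savgol")


class TestMotifEnrichment:
    def _planted_sets(self, genome, pwm, n_fg_pos, n_fg, n_bg_pos, n_bg):
        fg, bg = [], []
        pos = 1000
        for i in range(n_fg):
            iv = GenomicInterval("chr1", pos, pos + 100)
            if i < n_fg_pos:
                genome.set_sequence(
                    "chr1", pos + 50 - pwm.length // 2, pwm.consensus()
                )
            fg.append(iv)
            pos += 150
        for i in range(n_bg):
            iv = GenomicInterval("chr1", pos, pos + 100)
            if i < n_bg_pos:
                genome.set_sequence(
                    "chr1", pos + 50 - pwm.length // 2, pwm.consensus()
                )
            bg.append(iv)
            pos += 150
        return PeakSet(fg), PeakSet(bg)

    def test_odds_ratio_and_significance(self, are_pwm):
        genome = Genome({"chr1": "T" * 40000})
        fg, bg = self._planted_sets(genome, are_pwm, 90, 100, 10, 100)
        res = motif_enrichment(fg, bg, genome, are_pwm)
        assert res["odds_ratio"] == pytest.approx(81.0)
        assert res["pvalue"] <= 1e-20
        assert res["significant"]

    def test_equal_fractions_not_significant(self, are_pwm):
        genome = Genome({"chr1": "T" * 10000})
        fg, bg = self._planted_sets(genome, are_pwm, 5, 10, 5, 10)
        res = motif_enrichment(fg, bg, genome, are_pwm)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert not res["significant"]

    def test_empty_sets_error(self, poly_t_genome, are_pwm):
        ps = PeakSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            motif_enrichment(PeakSet([]), ps, poly_t_genome, are_pwm)


class TestScanRCInvariance:
    def test_simultaneous_reverse_complement(self, rng, are_pwm):
        """Scores are invariant under reverse-complementing both the PWM
        and the sequence."""
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            thr = -20.0
            hits = scan(are_pwm, seq, thr)
            hits_rc = scan(are_pwm.reverse_complement(), revcomp(seq), thr)
            assert sorted(round(h.score, 9) for h in hits) == sorted(
                round(h.score, 9) for h in hits_rc
            )
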