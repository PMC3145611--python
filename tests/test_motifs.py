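"""Berg-von Hippel scanning, regex scanning, and matched backgrounds."""

import math

import numpy as np
import pytest

from peakatlas.formats import PWM, fetch_sequences, reverse_complement
from peakatlas.intervals import GenomicInterval, PeakSet
from peakatlas.motifs import (
    BackgroundConfig,
    MotifScanConfig,
    bvh_weights,
    dinucleotide_frequencies,
    make_background,
    scan_pwm,
    scan_regex,
)


def seqs_of(*strings, chrom="chr1"):
    out = []
    pos = 0
    for i, s in enumerate(strings):
        out.append(
            (GenomicInterval(chrom, pos, pos + len(s), id=f"p{i}"), s)
        )
        pos += len(s) + 10
    return out


class TestBvhWeights:
    def test_single_base_column_arithmetic(self):
        """Column A=4,C=0,G=0,T=0, pc=0.5: w[A]=0, w[C]=ln(0.5/4.5)."""
        pwm = PWM("m", np.array([[4.0], [0.0], [0.0], [0.0]]))
        w = bvh_weights(pwm, 0.5)
        assert w[0, 0] == 0.0
        assert w[1, 0] == pytest.approx(math.log(0.5 / 4.5))

    def test_uniform_column_all_zero(self):
        pwm = PWM("m", np.full((4, 3), 2.0))
        assert (bvh_weights(pwm) == 0).all()

    def test_max_weight_zero_every_column(self):
        rng = np.random.default_rng(1)
        pwm = PWM("m", rng.integers(0, 20, size=(4, 8)) + 1)
        w = bvh_weights(pwm)
        assert np.allclose(w.max(axis=0), 0.0)
        assert (w <= 0).all()

    def test_affinity_decreases_with_substitutions(self, truth_pwm):
        """Each extra mismatch from the consensus lowers the affinity."""
        cons = truth_pwm.consensus()
        cfg = MotifScanConfig(tau=1e-9, both_strands=False)
        prev = None
        seq = cons
        for i in range(3):
            mutated = seq[:i] + ("A" if seq[i] != "A" else "C") + seq[i + 1 :]
            _, hits = scan_pwm(seqs_of(mutated), truth_pwm, cfg)
            aff = max(h.affinity for h in hits)
            if prev is not None:
                assert aff < prev
            prev = aff
            seq = mutated


class TestScanPwm:
    def test_consensus_affinity_one(self, truth_pwm):
        cons = truth_pwm.consensus()
        peaks, hits = scan_pwm(seqs_of(cons), truth_pwm, MotifScanConfig(tau=1.0))
        assert len(peaks) == 1
        assert hits[0].offset == 0
        assert hits[0].affinity == pytest.approx(1.0)

    def test_reverse_complement_hit_on_minus(self, truth_pwm):
        rc = reverse_complement(truth_pwm.consensus())
        _, hits = scan_pwm(seqs_of(rc), truth_pwm)
        assert any(h.strand == "-" for h in hits)

    def test_tau_one_returns_exactly_consensus(self, truth_pwm):
        cons = truth_pwm.consensus()
        near = cons[:-1] + ("A" if cons[-1] != "A" else "C")
        peaks, hits = scan_pwm(
            seqs_of("TT" + cons + "GG", near), truth_pwm, MotifScanConfig(tau=1.0)
        )
        assert [iv.id for iv in peaks] == ["p0"]
        assert all(h.affinity == pytest.approx(1.0) for h in hits)

    def test_n_windows_rejected(self, truth_pwm):
        cons = truth_pwm.consensus()
        damaged = cons[:3] + "N" + cons[4:]
        peaks, _ = scan_pwm(seqs_of(damaged), truth_pwm, MotifScanConfig(tau=0.001))
        assert len(peaks) == 0

    def test_short_sequence_skipped_with_warning(self, truth_pwm):
        with pytest.warns(UserWarning, match="shorter"):
            peaks, _ = scan_pwm(seqs_of("ACG"), truth_pwm)
        assert len(peaks) == 0

    def test_matches_naive_oracle_on_random_sequences(self):
        """Hit set equals an exhaustive per-window recomputation."""
        rng = np.random.default_rng(5)
        pwm = PWM("m", rng.integers(0, 10, size=(4, 6)).astype(float) + 0.5)
        w = bvh_weights(pwm, 0.5)
        seqs = seqs_of(
            *(
                "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
                for _ in range(100)
            )
        )
        cfg = MotifScanConfig(tau=0.5)
        _, hits = scan_pwm(seqs, pwm, cfg)
        got = {(h.peak_id, h.offset, h.strand) for h in hits}
        want = set()
        for iv, seq in seqs:
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for off in range(len(s) - 6 + 1):
                    score = sum(w["ACGT".index(c), i] for i, c in enumerate(s[off:off+6]))
                    if math.exp(score) >= 0.5:
                        fwd_off = off if strand == "+" else len(seq) - 6 - off
                        want.add((iv.id, fwd_off, strand))
        assert got == want

    def test_strand_symmetry_of_counts(self, truth_pwm):
        rng = np.random.default_rng(9)
        raw = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
            for _ in range(30)
        ]
        cfg = MotifScanConfig(tau=0.3)
        _, fwd_hits = scan_pwm(seqs_of(*raw), truth_pwm, cfg)
        _, rc_hits = scan_pwm(
            seqs_of(*(reverse_complement(s) for s in raw)), truth_pwm, cfg
        )
        assert len(fwd_hits) == len(rc_hits)


class TestScanRegex:
    def test_class_pattern_matches(self):
        peaks, hits = scan_regex(seqs_of("ACGC"), "[AT]CG[CT]")
        fwd = [h for h in hits if h.strand == "+"]
        assert len(peaks) == 1 and fwd[0].offset == 0

    def test_absent_pattern_excludes_peak(self):
        peaks, _ = scan_regex(seqs_of("GGGGGG"), "TCCAAT")
        assert len(peaks) == 0

    def test_invalid_pattern_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            scan_regex(seqs_of("ACGT"), "[AT")

    def test_overlapping_matches_all_reported(self):
        _, hits = scan_regex(seqs_of("AAAA"), "AA")
        assert len([h for h in hits if h.strand == "+"]) == 3

    def test_match_counts_equal_naive_oracle(self):
        rng = np.random.default_rng(3)
        raw = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
               for _ in range(50)]
        pattern = "TCCAAT"
        _, hits = scan_regex(seqs_of(*raw), pattern)
        want = 0
        for s in raw:
            for t in (s, reverse_complement(s)):
                want += sum(
                    1 for i in range(len(t) - 5) if t[i : i + 6] == pattern
                )
        assert len(hits) == want


class TestBackgrounds:
    def test_1mm_homopolymer_is_deterministic(self):
        bg = make_background(
            seqs_of("AAAAAAAA"), None, {"chr1": 1000}, BackgroundConfig(mode="1MM")
        )
        assert bg[0][1] == "AAAAAAAA"

    @pytest.mark.parametrize("mode", ["random", "adjacent", "1MM"])
    def test_lengths_conserved_elementwise(self, fixture, chrom_sizes, mode):
        peaks = PeakSet(
            [GenomicInterval("chr1", 1000 + i * 2000, 1000 + i * 2000 + 150 + i)
             for i in range(10)]
        )
        seqs = fetch_sequences(str(fixture.genome_fa), peaks)
        bg = make_background(
            seqs, str(fixture.genome_fa), chrom_sizes,
            BackgroundConfig(mode=mode, seed=4),
        )
        assert [len(s) for _, s in bg] == [iv.length for iv in peaks]

    def test_adjacent_flanks_the_peaks(self, fixture, chrom_sizes):
        peaks = PeakSet([GenomicInterval("chr1", 5_000, 5_400),
                         GenomicInterval("chr1", 9_000, 9_400)])
        seqs = fetch_sequences(str(fixture.genome_fa), peaks)
        bg = make_background(
            seqs, str(fixture.genome_fa), chrom_sizes,
            BackgroundConfig(mode="adjacent"),
        )
        assert bg[0][0].end == 5_000  # left flank
        assert bg[1][0].start == 9_400  # right flank (alternating)

    def test_1mm_preserves_dinucleotide_frequencies(self, fixture):
        """Pooled background dinucleotide frequencies track the input's
        within 0.02 on GC-rich peaks."""
        rng = np.random.default_rng(12)
        gc_rich = [
            "".join(rng.choice(list("ACGT"), p=[0.1, 0.4, 0.4, 0.1]))
            for _ in range(50 * 300)
        ]
        seqs = seqs_of(*(
            "".join(gc_rich[i * 300 : (i + 1) * 300]) for i in range(50)
        ))
        bg = make_background(seqs, None, {}, BackgroundConfig(mode="1MM", seed=7))
        f_in = dinucleotide_frequencies([s for _, s in seqs])
        f_bg = dinucleotide_frequencies([s for _, s in bg])
        for dinuc in f_in:
            assert abs(f_in[dinuc] - f_bg.get(dinuc, 0.0)) <= 0.02

    def test_1mm_seeded_reproducible(self, fixture, chrom_sizes):
        seqs = fetch_sequences(str(fixture.genome_fa), fixture.truth_peaks)
        a = make_background(seqs, None, {}, BackgroundConfig(mode="1MM", seed=3))
        b = make_background(seqs, None, {}, BackgroundConfig(mode="1MM", seed=3))
        assert [s for _, s in a] == [s for _, s in b]

    def test_cgi_matches_island_overlap_fraction(self, fixture, chrom_sizes):
        from peakatlas.formats import read_peaks
        from peakatlas.intervals import build_tree

        cpg = read_peaks(fixture.cpg_bed)
        seqs = fetch_sequences(str(fixture.genome_fa), fixture.truth_peaks)
        bg = make_background(
            seqs, str(fixture.genome_fa), chrom_sizes,
            BackgroundConfig(mode="CGI", seed=5, cpg_track=cpg),
        )
        tree = build_tree(cpg)
        frac_in = sum(
            1 for iv, _ in seqs if tree.any_overlap(iv)
        ) / len(seqs)
        frac_bg = sum(
            1 for iv, _ in bg if tree.any_overlap(iv)
        ) / len(bg)
        assert abs(frac_bg - frac_in) <= 0.05

    def test_cgi_without_track_rejected(self):
        with pytest.raises(ValueError, match="cpg_track"):
            make_background(seqs_of("ACGT"), None, {"chr1": 100},
                            BackgroundConfig(mode="CGI"))


class TestEmbeddedMotifRecovery:
    def test_planted_fraction_recovered(self, fixture, truth_pwm):
        """The fixture embeds the consensus in 80% of truth peaks; the
        scanner recovers that fraction within 0.1."""
        seqs = fetch_sequences(str(fixture.genome_fa), fixture.truth_peaks)
        peaks_with, _ = scan_pwm(seqs, truth_pwm, MotifScanConfig(tau=0.5))
        frac = len(peaks_with) / len(fixture.truth_peaks)
        assert abs(frac - fixture.spec.motif_fraction) <= 0.1
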