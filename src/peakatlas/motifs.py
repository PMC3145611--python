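"""Motif scanning in peak sequences and matched background generation.

PWM scanning uses the Berg-von Hippel weighting: each matrix column's
counts are converted to log-ratios against the column's most frequent
base (with a pseudocount), so the consensus sequence scores exactly 0 and
every other window scores below it. The relative affinity of a window is
exp(score), in (0, 1], and a window is a hit when its affinity reaches the
user threshold ``tau``. Consensus patterns may also be given as regular
expressions over IUPAC-free character classes (e.g. ``[AT]CG[CT]``) and
matched on both strands.

Background sequence generators for enrichment analyses:

random    uniform placement anywhere in the genome, same lengths;
adjacent  regions immediately flanking each peak (alternating sides);
CGI       random placement re-drawn until the batch matches the peaks'
          CpG-island overlap fraction within +/- 5 percentage points;
1MM       per-peak synthetic sequence from that peak's own first-order
          Markov (dinucleotide) frequencies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import PWM, reverse_complement
from .intervals import GenomicInterval, PeakSet, build_tree

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifScanConfig:
    tau: float = 0.5  # relative-affinity acceptance threshold
    pseudocount: float = 0.5
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError("tau must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class MotifHit:
    peak_id: str
    offset: int  # bp within the peak sequence
    strand: str
    score: float  # BvH log-ratio sum, <= 0
    affinity: float  # exp(score), in (0, 1]


@dataclass
class BackgroundConfig:
    mode: str = "random"  # random | adjacent | CGI | 1MM
    seed: int = 0
    cpg_track: Optional[PeakSet] = None  # required for CGI
    cgi_tolerance: float = 0.05
    max_batches: int = 1000


# ---------------------------------------------------------------------------
# Berg-von Hippel scanning
# ---------------------------------------------------------------------------


def bvh_weights(pwm: PWM, pseudocount: float = 0.5) -> np.ndarray:
    """4 x width log-ratio weights: w[b,i] = ln((n[b,i]+pc)/(n_max[i]+pc)).

    The most frequent base of each column gets weight 0; all weights <= 0.
    """
    counts = pwm.counts
    col_max = counts.max(axis=0)
    return np.log((counts + pseudocount) / (col_max + pseudocount))


def _scan_one(
    seq: str, weights: np.ndarray, tau: float, strand: str, peak_id: str
) -> List[MotifHit]:
    w = weights.shape[1]
    hits = []
    log_tau = np.log(tau)
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        score = 0.0
        ok = True
        for i, ch in enumerate(window):
            b = _BASE_IDX.get(ch)
            if b is None:  # windows containing N are rejected
                ok = False
                break
            score += weights[b, i]
        if ok and score >= log_tau - 1e-12:
            hits.append(
                MotifHit(peak_id, off, strand, score, float(np.exp(score)))
            )
    return hits


def scan_pwm(
    sequences: Sequence[Tuple[GenomicInterval, str]],
    pwm: PWM,
    cfg: Optional[MotifScanConfig] = None,
) -> Tuple[PeakSet, List[MotifHit]]:
    """Scan peak sequences for a PWM.

    Returns (the peaks with >= 1 accepted window, all hits). Reverse-strand
    hits are reported at the offset of the motif's leftmost base on the
    forward sequence.
    """
    cfg = cfg or MotifScanConfig()
    weights = bvh_weights(pwm, cfg.pseudocount)
    w = pwm.width
    hit_peaks: List[GenomicInterval] = []
    hits: List[MotifHit] = []
    for iv, seq in sequences:
        if len(seq) < w:
            warnings.warn(
                f"sequence for {iv.chrom}:{iv.start}-{iv.end} shorter than "
                f"motif width {w}; skipped",
                stacklevel=2,
            )
            continue
        pid = iv.id or f"{iv.chrom}:{iv.start}-{iv.end}"
        peak_hits = _scan_one(seq, weights, cfg.tau, "+", pid)
        if cfg.both_strands:
            rc_hits = _scan_one(reverse_complement(seq), weights, cfg.tau, "-", pid)
            for h in rc_hits:
                h.offset = len(seq) - w - h.offset  # leftmost base, forward coords
            peak_hits.extend(rc_hits)
        if peak_hits:
            hit_peaks.append(iv)
            hits.extend(peak_hits)
    return PeakSet(hit_peaks, source="motif_hits"), hits


def scan_regex(
    sequences: Sequence[Tuple[GenomicInterval, str]], pattern: str
) -> Tuple[PeakSet, List[MotifHit]]:
    """Scan with a consensus pattern (character classes over ACGT).

    Matches are case-insensitive, reported on both the forward strand and
    the reverse complement; overlapping occurrences are all reported.
    """
    try:
        rx = re.compile(f"(?=({pattern}))", re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid pattern at position {exc.pos}: {exc.msg}") from exc
    hit_peaks: List[GenomicInterval] = []
    hits: List[MotifHit] = []
    for iv, seq in sequences:
        pid = iv.id or f"{iv.chrom}:{iv.start}-{iv.end}"
        peak_hits = []
        for m in rx.finditer(seq):
            peak_hits.append(MotifHit(pid, m.start(), "+", 0.0, 1.0))
        rc = reverse_complement(seq)
        for m in rx.finditer(rc):
            mlen = len(m.group(1))
            peak_hits.append(
                MotifHit(pid, len(seq) - m.start() - mlen, "-", 0.0, 1.0)
            )
        if peak_hits:
            hit_peaks.append(iv)
            hits.extend(peak_hits)
    return PeakSet(hit_peaks, source="regex_hits"), hits


# ---------------------------------------------------------------------------
# Background generation
# ---------------------------------------------------------------------------


def _random_intervals(
    lengths: Sequence[int], chrom_sizes: Dict[str, int], rng: np.random.Generator
) -> List[GenomicInterval]:
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    out = []
    for L in lengths:
        slots = np.maximum(sizes - L + 1, 0)
        if slots.sum() == 0:
            raise ValueError(f"no chromosome can hold a {L} bp region")
        ci = rng.choice(len(chroms), p=slots / slots.sum())
        start = int(rng.integers(0, slots[ci]))
        out.append(GenomicInterval(chroms[ci], start, start + L, id=f"bg_{len(out)}"))
    return out


def _overlap_fraction(intervals: Sequence[GenomicInterval], track: PeakSet) -> float:
    if not intervals:
        return 0.0
    tree = build_tree(track)
    return sum(1 for iv in intervals if tree.any_overlap(iv)) / len(intervals)


def _markov_sequence(source: str, rng: np.random.Generator) -> str:
    """Generate a same-length sequence from the source's first-order Markov
    frequencies; starts from the source's first base, falls back to
    mononucleotide draws for unseen contexts."""
    src = [c for c in source if c in _BASE_IDX]
    if len(src) < 2:
        return source
    trans: Dict[str, List[str]] = {}
    for a, b in zip(src, src[1:]):
        trans.setdefault(a, []).append(b)
    mono = src
    cur = src[0]
    out = [cur]
    for _ in range(len(source) - 1):
        pool = trans.get(cur)
        if not pool:
            pool = mono
        cur = pool[int(rng.integers(0, len(pool)))]
        out.append(cur)
    return "".join(out)


def make_background(
    peaks_seqs: Sequence[Tuple[GenomicInterval, str]],
    genome,
    chrom_sizes: Dict[str, int],
    cfg: Optional[BackgroundConfig] = None,
) -> List[Tuple[GenomicInterval, str]]:
    """One background sequence per input peak, same length.

    ``genome`` is anything :func:`peakatlas.formats.fetch_sequences`
    accepts (a FASTA path or an open pyfaidx.Fasta); it is unused in 1MM
    mode, where sequences are synthesised rather than extracted.
    """
    from .formats import fetch_sequences

    def fetch_ordered(ivs):
        # fetch_sequences iterates grouped by chromosome; restore the
        # one-background-per-peak pairing by the interval ids
        fetched = {
            iv.id: (iv, seq) for iv, seq in fetch_sequences(genome, PeakSet(ivs))
        }
        return [fetched[iv.id] for iv in ivs]

    cfg = cfg or BackgroundConfig()
    rng = np.random.default_rng(cfg.seed)
    lengths = [iv.length for iv, _ in peaks_seqs]

    if cfg.mode == "1MM":
        out = []
        for i, (iv, seq) in enumerate(peaks_seqs):
            synth = _markov_sequence(seq.upper(), rng)
            out.append(
                (GenomicInterval(iv.chrom, iv.start, iv.end, id=f"1mm_{i}"), synth)
            )
        return out

    if cfg.mode == "random":
        return fetch_ordered(_random_intervals(lengths, chrom_sizes, rng))

    if cfg.mode == "adjacent":
        ivs = []
        for i, (iv, _) in enumerate(peaks_seqs):
            side_left = i % 2 == 0  # alternate sides to avoid directional bias
            size = chrom_sizes[iv.chrom]
            L = iv.length
            if side_left and iv.start - L < 0:
                side_left = False
            if not side_left and iv.end + L > size:
                side_left = True
            if side_left:
                s, e = iv.start - L, iv.start
            else:
                s, e = iv.end, iv.end + L
            if s < 0 or e > size:
                raise ValueError(
                    f"no room adjacent to {iv.chrom}:{iv.start}-{iv.end}"
                )
            ivs.append(GenomicInterval(iv.chrom, s, e, id=f"adj_{i}"))
        return fetch_ordered(ivs)

    if cfg.mode == "CGI":
        if cfg.cpg_track is None:
            raise ValueError("CGI mode requires a cpg_track")
        target = _overlap_fraction([iv for iv, _ in peaks_seqs], cfg.cpg_track)
        achieved = None
        for _ in range(cfg.max_batches):
            ivs = _random_intervals(lengths, chrom_sizes, rng)
            achieved = _overlap_fraction(ivs, cfg.cpg_track)
            if abs(achieved - target) <= cfg.cgi_tolerance:
                return fetch_ordered(ivs)
        raise RuntimeError(
            f"CGI resampling failed after {cfg.max_batches} batches: "
            f"target fraction {target:.3f}, last achieved {achieved:.3f}"
        )

    raise ValueError(f"unknown background mode {cfg.mode!r}")


def dinucleotide_frequencies(seqs: Sequence[str]) -> Dict[str, float]:
    """Pooled dinucleotide frequencies over a batch of sequences."""
    counts: Dict[str, int] = {}
    total = 0
    for seq in seqs:
        s = seq.upper()
        for a, b in zip(s, s[1:]):
            if a in _BASE_IDX and b in _BASE_IDX:
                counts[a + b] = counts.get(a + b, 0) + 1
                total += 1
    return {k: v / total for k, v in counts.items()} if total else {}
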