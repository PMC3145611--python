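"""Read-density peak calling.

Reads are extended to the expected fragment length in their 3' direction
and piled into per-base coverage. Bases at or above the coverage threshold
``t`` become candidates; candidate runs closer than ``max_gap`` bp are
merged; merged regions shorter than ``min_len`` are dropped. With a
control library, a region is kept only when its library-size-normalized
ChIP/control mean-coverage ratio reaches ``fold`` (one pseudocount read on
the control). Each reported peak carries its maximum ChIP coverage as the
score and the leftmost position of that maximum as the summit.

The thresholds here are deliberately simple and fully exposed; defaults
are t=15 reads, fold=2, max_gap=200 bp, min_len=100 bp, fragment
length 200 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .formats import ReadSet
from .intervals import GenomicInterval, PeakSet


@dataclass
class PeakCallConfig:
    t: float = 15.0  # per-base coverage threshold
    fold: float = 2.0  # min ChIP/control normalized ratio
    max_gap: int = 200  # merge candidate runs closer than this
    min_len: int = 100  # drop merged regions shorter than this
    fragment_length: int = 200

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.min_len <= 0 or self.max_gap < 0 or self.fragment_length <= 0:
            raise ValueError("invalid window parameters")


def coverage(
    reads: ReadSet,
    chrom_sizes: Dict[str, int],
    fragment_length: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Per-base coverage from fragment-extended reads.

    + reads extend rightward from their start, - reads leftward from their
    3' position (the read end); fragments are truncated at chromosome
    boundaries.
    """
    L = fragment_length if fragment_length is not None else reads.fragment_length
    out: Dict[str, np.ndarray] = {}
    warned = False
    for chrom, size in chrom_sizes.items():
        # difference array for O(reads + size) pileup
        diff = np.zeros(size + 1, dtype=np.float64)
        for r in reads.on(chrom):
            if r.strand == "-":
                s, e = r.end - L, r.end
            else:
                s, e = r.start, r.start + L
            if e > size or s < 0:
                if not warned:
                    warnings.warn(
                        f"fragments beyond {chrom} bounds truncated", stacklevel=2
                    )
                    warned = True
                s, e = max(0, s), min(size, e)
            if e > s:
                diff[s] += 1
                diff[e] -= 1
        out[chrom] = np.cumsum(diff[:-1])
    return out


def _candidate_regions(
    cov: np.ndarray, t: float, max_gap: int, min_len: int
) -> List[Tuple[int, int]]:
    above = cov >= t
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    # merge runs separated by < max_gap
    merged: List[Tuple[int, int]] = []
    cur_s, cur_e = int(run_starts[0]), int(run_ends[0])
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - cur_e < max_gap:
            cur_e = int(e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    merged.append((cur_s, cur_e))
    return [(s, e) for s, e in merged if e - s >= min_len]


def call_peaks(
    chip: ReadSet,
    control: Optional[ReadSet],
    chrom_sizes: Dict[str, int],
    cfg: Optional[PeakCallConfig] = None,
) -> PeakSet:
    """Call peaks from ChIP (and optionally control) reads.

    Returns a PeakSet whose intervals carry score = max ChIP coverage and,
    in ``extra``, the summit position (leftmost maximum).
    """
    cfg = cfg or PeakCallConfig()
    if chip.total_reads == 0:
        return PeakSet(source="peaks")
    chip_cov = coverage(chip, chrom_sizes, cfg.fragment_length)
    ctrl_cov = (
        coverage(control, chrom_sizes, cfg.fragment_length)
        if control is not None and control.total_reads > 0
        else None
    )
    chip_total = chip.total_reads
    ctrl_total = control.total_reads if control is not None else 0

    peaks: List[GenomicInterval] = []
    i = 0
    for chrom in sorted(chrom_sizes):
        cov = chip_cov.get(chrom)
        if cov is None:
            continue
        for s, e in _candidate_regions(cov, cfg.t, cfg.max_gap, cfg.min_len):
            region = cov[s:e]
            if ctrl_cov is not None:
                chip_rate = region.mean() / chip_total
                # +1 pseudocount read spread over the region on the control
                ctrl_mean = ctrl_cov[chrom][s:e].mean() + 1.0 / (e - s)
                ctrl_rate = ctrl_mean / max(ctrl_total, 1)
                if chip_rate / ctrl_rate < cfg.fold:
                    continue
            summit_off = int(region.argmax())  # argmax is leftmost on ties
            i += 1
            peaks.append(
                GenomicInterval(
                    chrom, s, e,
                    id=f"peak_{i}",
                    score=float(region.max()),
                    extra=(str(s + summit_off),),
                )
            )
    return PeakSet(peaks, source="peaks")


def peak_summit(iv: GenomicInterval) -> int:
    """Summit position of a called peak; midpoint when none was recorded."""
    if iv.extra:
        try:
            return int(iv.extra[0])
        except (TypeError, ValueError):
            pass
    return iv.midpoint
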