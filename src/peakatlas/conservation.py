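"""Evolutionary conservation of peaks.

Works on per-base score tracks (phastCons probabilities in [0, 1] or
phyloP scores) read from fixedStep wiggle or bedGraph. Two analyses:

* mean conservation per peak, with a strict ``> threshold`` filter
  (default 0.5) to keep putatively functional peaks;
* binned profiles around peak summits (default a 2 kb window in 10 bp
  bins, i.e. 200 bins), averaged over peaks and compared against profiles
  of randomly placed same-length regions.

Bases without a score follow ``missing_policy``: "zero" treats them as 0
(phastCons tracks are near-complete), "skip" excludes them from means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .detect import peak_summit
from .formats import ScoreTrack
from .intervals import GenomicInterval, PeakSet


@dataclass
class ProfileConfig:
    window: int = 2000  # total bp around the centre
    bin: int = 10
    threshold: float = 0.5
    missing_policy: str = "zero"  # zero | skip

    def __post_init__(self) -> None:
        if self.window % self.bin != 0:
            raise ValueError("window must be divisible by bin")
        if self.missing_policy not in ("zero", "skip"):
            raise ValueError("missing_policy must be 'zero' or 'skip'")

    @property
    def n_bins(self) -> int:
        return self.window // self.bin


@dataclass
class ConservationProfile:
    per_region: np.ndarray  # (regions, n_bins), NaN rows for truncated windows
    mean: np.ndarray  # per-bin mean over untruncated regions
    label: str
    n_used: int
    n_truncated: int


def _region_mean(
    track: ScoreTrack, chrom: str, start: int, end: int, policy: str
) -> float:
    vals = track.values(chrom, max(start, 0), end)
    if policy == "zero":
        vals = np.nan_to_num(vals, nan=0.0)
        return float(vals.mean()) if vals.size else 0.0
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def peak_mean_conservation(
    peaks: PeakSet,
    track: ScoreTrack,
    cfg: Optional[ProfileConfig] = None,
) -> Tuple[List[Tuple[GenomicInterval, float]], PeakSet]:
    """Mean score per peak and the peaks strictly above the threshold."""
    cfg = cfg or ProfileConfig()
    warned = set()
    means: List[Tuple[GenomicInterval, float]] = []
    passing: List[GenomicInterval] = []
    for iv in peaks:
        if iv.chrom not in track.runs and iv.chrom not in warned:
            warnings.warn(f"no scores on {iv.chrom}", stacklevel=2)
            warned.add(iv.chrom)
        m = _region_mean(track, iv.chrom, iv.start, iv.end, cfg.missing_policy)
        means.append((iv, m))
        if not np.isnan(m) and m > cfg.threshold:
            passing.append(iv)
    return means, PeakSet(passing, source="conserved")


def conservation_profile(
    regions: PeakSet,
    track: ScoreTrack,
    cfg: Optional[ProfileConfig] = None,
    center: str = "summit",
    chrom_sizes: Optional[Dict[str, int]] = None,
    label: str = "peaks",
) -> ConservationProfile:
    """Binned score profile around each region's centre.

    ``center`` is "summit" (recorded summit, midpoint when absent) or
    "midpoint". Windows running off a chromosome end are flagged and
    excluded from the group mean.
    """
    cfg = cfg or ProfileConfig()
    nb = cfg.n_bins
    rows = np.full((len(regions), nb), np.nan)
    truncated = 0
    for ri, iv in enumerate(regions):
        c = peak_summit(iv) if center == "summit" else iv.midpoint
        start = c - cfg.window // 2
        end = start + cfg.window
        size = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        if start < 0 or (size is not None and end > size):
            truncated += 1
            continue
        vals = track.values(iv.chrom, start, end)
        if cfg.missing_policy == "zero":
            vals = np.nan_to_num(vals, nan=0.0)
        binned = vals.reshape(nb, cfg.bin)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            rows[ri] = np.nanmean(binned, axis=1)
    used = ~np.isnan(rows).all(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows[used], axis=0) if used.any() else np.full(nb, np.nan)
    return ConservationProfile(
        per_region=rows, mean=mean, label=label,
        n_used=int(used.sum()), n_truncated=truncated,
    )


def random_regions_profile(
    regions: PeakSet,
    track: ScoreTrack,
    chrom_sizes: Dict[str, int],
    cfg: Optional[ProfileConfig] = None,
    seed: int = 0,
) -> ConservationProfile:
    """Profile of uniformly placed regions matching the input's number and
    lengths, for the peaks-vs-random comparison plot."""
    from .motifs import _random_intervals

    cfg = cfg or ProfileConfig()
    rng = np.random.default_rng(seed)
    lengths = [iv.length for iv in regions]
    rand = PeakSet(_random_intervals(lengths, chrom_sizes, rng), source="random")
    return conservation_profile(
        rand, track, cfg, center="midpoint", chrom_sizes=chrom_sizes,
        label="random",
    )


def write_profile_table(
    profiles: List[ConservationProfile], cfg: ProfileConfig, path
) -> None:
    """Plot-ready TSV: bin start offset from centre + one mean column per group."""
    offsets = np.arange(cfg.n_bins) * cfg.bin - cfg.window // 2
    with open(path, "w") as fh:
        fh.write("bin_start_offset\t" + "\t".join(p.label + "_mean" for p in profiles) + "\n")
        for i, off in enumerate(offsets):
            vals = "\t".join(f"{p.mean[i]:.6g}" for p in profiles)
            fh.write(f"{off}\t{vals}\n")
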