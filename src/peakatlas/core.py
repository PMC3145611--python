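"""Peak-list comparison and randomization-based overlap significance.

Set operations (overlap, unique, merge) run on interval trees. The
significance of an observed overlap between two peak lists is assessed by a
randomization null that regenerates the first list many times while
conserving the number of peaks, the per-chromosome multiset of peak
lengths, and the gene-part distribution (promoter / exonic / intronic /
downstream / intergenic): each randomized peak is placed uniformly within
the genomic territory of its own category on its own chromosome. The
empirical p-value counts randomizations whose overlap reaches the observed
count (with add-one smoothing so p is never 0), and the z-score is the
observed count's distance from the null mean in null standard deviations.

The Jaccard index between two peak files is computed on the connected
components of the merged peak set: components containing peaks from both
files, divided by all components — a symmetric quantity bounded by 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import (
    _COLLAPSE,
    CATEGORIES,
    COLLAPSED,
    AnnotationConfig,
    classify_peaks,
    genome_labels,
)
from .formats import GeneModel
from .intervals import GenomicInterval, IntervalTree, PeakSet, build_tree


@dataclass
class OverlapStats:
    observed: int
    n_rand: int
    rand_counts: List[int]
    p_value: float
    z_score: Optional[float]  # None when the null has zero spread
    seed: int

    @property
    def z_defined(self) -> bool:
        return self.z_score is not None


@dataclass
class JaccardResult:
    matrix: np.ndarray
    labels: List[str]


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------


def compare_intervals(a: PeakSet, b: PeakSet, mode: str = "overlap") -> PeakSet:
    """Compare two peak lists.

    overlap — peaks of ``a`` overlapping at least one peak of ``b``;
    unique — peaks of ``a`` overlapping none of ``b`` (the exact
    complement, so overlap + unique = a); merge — the union with
    transitively-overlapping intervals coalesced into spanning intervals.
    """
    if mode in ("overlap", "unique"):
        tree = build_tree(b)
        want = mode == "overlap"
        return PeakSet(
            (iv for iv in a if tree.any_overlap(iv) == want), source=mode
        )
    if mode == "merge":
        return merge_peaks(a, b)
    raise ValueError(f"unknown mode {mode!r}")


def merge_peaks(*sets: PeakSet) -> PeakSet:
    """Coalesce all intervals from the given sets into maximal spanning
    intervals; output intervals are pairwise non-overlapping and sorted."""
    pooled: Dict[str, List[GenomicInterval]] = {}
    for s in sets:
        for iv in s:
            pooled.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(pooled):
        ivs = sorted(pooled[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # strict overlap only; abutting stays split
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return PeakSet(merged, source="merge")


# ---------------------------------------------------------------------------
# Category-conserving randomization
# ---------------------------------------------------------------------------


class CategoryTerritories:
    """Per-chromosome runs of bases belonging to each collapsed gene-part
    category, precomputed once so repeated randomizations are cheap."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        chrom_sizes: Dict[str, int],
        cfg: Optional[AnnotationConfig] = None,
    ) -> None:
        self.cfg = cfg or AnnotationConfig()
        labels = genome_labels(genes, chrom_sizes, self.cfg)
        collapse_code = np.array(
            [COLLAPSED.index(_COLLAPSE[c]) for c in CATEGORIES], dtype=np.uint8
        )
        # runs[(chrom, collapsed category)] = (starts, lengths) arrays
        self.runs: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, arr in labels.items():
            coll = collapse_code[arr]
            # boundaries of constant-label runs
            change = np.flatnonzero(np.diff(coll)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(coll)]))
            cats = coll[starts]
            for ci, cat in enumerate(COLLAPSED):
                sel = cats == ci
                if sel.any():
                    self.runs[(chrom, cat)] = (starts[sel], ends[sel] - starts[sel])

    def place(
        self, chrom: str, length: int, category: str, rng: np.random.Generator
    ) -> Tuple[int, int, bool]:
        """Uniform placement of a ``length``-bp interval inside the
        category's territory on ``chrom``. Returns (start, end, exact):
        exact is False when no run fits the whole peak and placement falls
        back to requiring only the midpoint inside the territory."""
        key = (chrom, category)
        if key not in self.runs:
            raise ValueError(f"no {category} territory on {chrom}")
        starts, lengths = self.runs[key]
        fit = lengths >= length
        if fit.any():
            slots = lengths[fit] - length + 1
            probs = slots / slots.sum()
            i = rng.choice(len(slots), p=probs)
            run_start = starts[fit][i]
            offset = rng.integers(0, slots[i])
            return int(run_start + offset), int(run_start + offset + length), True
        # fallback: midpoint inside the territory
        probs = lengths / lengths.sum()
        i = rng.choice(len(lengths), p=probs)
        mid = int(starts[i] + rng.integers(0, lengths[i]))
        start = max(0, mid - length // 2)
        return start, start + length, False


def _peak_categories(
    peaks: PeakSet, genes: Sequence[GeneModel], cfg: Optional[AnnotationConfig]
) -> List[Tuple[GenomicInterval, str]]:
    result = classify_peaks(peaks, genes, cfg)
    return [(iv, _COLLAPSE[cat]) for iv, cat in result.primary]


def randomize_peaks(
    a: PeakSet,
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    seed: int = 0,
    cfg: Optional[AnnotationConfig] = None,
    territories: Optional[CategoryTerritories] = None,
    categories: Optional[List[Tuple[GenomicInterval, str]]] = None,
) -> PeakSet:
    """One randomized replicate of ``a`` conserving peak count, the
    per-chromosome length multiset, and the gene-part category of every
    peak. ``territories`` and ``categories`` may be precomputed by callers
    that randomize repeatedly."""
    for chrom in {iv.chrom for iv in a}:
        if chrom not in chrom_sizes:
            raise ValueError(f"chrom_sizes does not cover {chrom}")
    if territories is None:
        territories = CategoryTerritories(genes, chrom_sizes, cfg)
    if categories is None:
        categories = _peak_categories(a, genes, cfg)
    rng = np.random.default_rng(seed)
    out: List[GenomicInterval] = []
    fell_back = 0
    for iv, cat in categories:
        start, end, exact = territories.place(iv.chrom, iv.length, cat, rng)
        if not exact:
            fell_back += 1
        out.append(GenomicInterval(iv.chrom, start, end))
    if fell_back:
        warnings.warn(
            f"{fell_back} peaks placed by midpoint fallback "
            "(no territory run long enough)",
            stacklevel=2,
        )
    return PeakSet(out, source=f"randomized:{a.source}")


def overlap_significance(
    a: PeakSet,
    b: PeakSet,
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    n_rand: int = 100,
    seed: int = 0,
    cfg: Optional[AnnotationConfig] = None,
) -> OverlapStats:
    """Empirical significance of the overlap of ``a`` with ``b``.

    ``b`` is held fixed; ``a`` is randomized ``n_rand`` times under the
    category-conserving null. p = (1 + #{rand >= observed}) / (1 + n_rand);
    z = (observed - mean) / sd of the null counts (None when sd = 0).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    tree_b = build_tree(b)
    observed = sum(1 for iv in a if tree_b.any_overlap(iv))
    territories = CategoryTerritories(genes, chrom_sizes, cfg)
    categories = _peak_categories(a, genes, cfg)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_rand)
    rand_counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fallback warnings once is enough
        for i in range(n_rand):
            ra = randomize_peaks(
                a, genes, chrom_sizes, seed=int(child_seeds[i] % (2**31)),
                cfg=cfg, territories=territories, categories=categories,
            )
            rand_counts.append(sum(1 for iv in ra if tree_b.any_overlap(iv)))
    arr = np.asarray(rand_counts)
    p = (1 + int((arr >= observed).sum())) / (1 + n_rand)
    sd = arr.std(ddof=1) if n_rand > 1 else 0.0
    z = float((observed - arr.mean()) / sd) if sd > 0 else None
    return OverlapStats(
        observed=observed,
        n_rand=n_rand,
        rand_counts=rand_counts,
        p_value=p,
        z_score=z,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------


def _pair_jaccard(a: PeakSet, b: PeakSet) -> float:
    if len(a) == 0 and len(b) == 0:
        return 0.0
    components = merge_peaks(a, b)
    tree_a, tree_b = build_tree(a), build_tree(b)
    union = len(components)
    inter = sum(
        1
        for comp in components
        if tree_a.any_overlap(comp) and tree_b.any_overlap(comp)
    )
    return inter / union


def jaccard_index(sets: Sequence[PeakSet], labels: Optional[Sequence[str]] = None) -> JaccardResult:
    """Pairwise Jaccard similarity for a list of peak files.

    For each pair, merge both files into connected components; the index is
    the number of components containing peaks from both files divided by
    the total number of components.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    d = len(sets)
    if labels is None:
        labels = [s.source or f"set{i}" for i, s in enumerate(sets)]
    m = np.zeros((d, d))
    for i in range(d):
        m[i, i] = 1.0 if len(sets[i]) else 0.0
        for j in range(i + 1, d):
            m[i, j] = m[j, i] = _pair_jaccard(sets[i], sets[j])
    return JaccardResult(matrix=m, labels=list(labels))
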