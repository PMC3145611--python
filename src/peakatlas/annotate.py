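"""Peak-to-gene annotation.

Classifies ChIP-seq peaks into gene parts (promoter, exon, first intron,
intron, downstream, distal, other), computes the genome-wide expected
fraction of each category, summarises peaks per gene, finds closest genes
and distal peaks, compares gene lists, and annotates peaks against
arbitrary nongenic tracks (repeats, CpG islands, external peak sets).

Classification is against transcripts; when several labels apply, one
primary category is assigned by the fixed priority
promoter > exon > first_intron > intron > downstream > distal > other,
so the categories partition the peak set and observed fractions sum to 1.

Promoters are, by default, 4 kb windows centred on the TSS but never
extended past the downstream extremity of the transcript. The first intron
is the 5'-most intron in transcription order. Distal (intergenic) peaks
overlap no gene part and lie at least ``distal_min`` bp (default 2 kb)
from every transcript; peaks nearer than that but in no part fall in the
residual "other" category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats import GeneModel
from .intervals import GenomicInterval, IntervalTree, PeakSet

CATEGORIES = ("promoter", "exon", "first_intron", "intron", "downstream", "distal", "other")

# per-base label codes, ascending priority overwrites descending
_CODE = {c: i for i, c in enumerate(CATEGORIES)}

# collapse to the five randomization categories
COLLAPSED = ("promoter", "exonic", "intronic", "downstream", "intergenic")
_COLLAPSE = {
    "promoter": "promoter",
    "exon": "exonic",
    "first_intron": "intronic",
    "intron": "intronic",
    "downstream": "downstream",
    "distal": "intergenic",
    "other": "intergenic",
}


@dataclass
class AnnotationConfig:
    promoter_window: int = 4000  # total width centred on the TSS
    downstream_window: int = 2000  # width past the TES
    distal_min: int = 2000  # minimum gap from any transcript
    database: str = "custom"

    def __post_init__(self) -> None:
        if min(self.promoter_window, self.downstream_window) <= 0:
            raise ValueError("windows must be positive")
        if self.distal_min < 0:
            raise ValueError("distal_min must be >= 0")


@dataclass
class GeneLink:
    symbol: str
    category: str
    distance: int  # bp gap to the transcript; 0 when overlapping the part


@dataclass
class AnnotationResult:
    by_category: Dict[str, PeakSet]
    gene_links: List[Tuple[GenomicInterval, List[GeneLink]]]
    observed_fractions: Dict[str, float]
    primary: List[Tuple[GenomicInterval, str]]
    config: AnnotationConfig


def promoter_region(g: GeneModel, window: int) -> Tuple[int, int]:
    """Promoter window centred on the TSS, clipped at the transcript's
    downstream extremity and at position 0."""
    half = window // 2
    if g.strand == "+":
        start = max(0, g.tx_start - half)
        end = min(g.tx_start + half, g.tx_end)
    else:
        center = g.tx_end  # one past the TSS base
        start = max(0, center - half, g.tx_start)
        end = center + half
    return start, end


def downstream_region(g: GeneModel, window: int) -> Optional[Tuple[int, int]]:
    if g.strand == "+":
        return g.tx_end, g.tx_end + window
    start = g.tx_start - window
    if g.tx_start <= 0:
        return None
    return max(0, start), g.tx_start


def _part_trees(genes: Sequence[GeneModel], cfg: AnnotationConfig):
    """Interval trees of each gene part, tagged with gene symbols via id."""
    trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in
                                      ("promoter", "exon", "first_intron", "intron",
                                       "downstream", "transcript")}
    for g in genes:
        ps, pe = promoter_region(g, cfg.promoter_window)
        if pe > ps:
            trees["promoter"].insert(GenomicInterval(g.chrom, ps, pe, id=g.symbol))
        for es, ee in zip(g.exon_starts, g.exon_ends):
            if ee > es:
                trees["exon"].insert(GenomicInterval(g.chrom, es, ee, id=g.symbol))
        fi = g.first_intron()
        for s, e in g.introns():
            tree = "first_intron" if fi == (s, e) else "intron"
            trees[tree].insert(GenomicInterval(g.chrom, s, e, id=g.symbol))
        dr = downstream_region(g, cfg.downstream_window)
        if dr is not None and dr[1] > dr[0]:
            trees["downstream"].insert(GenomicInterval(g.chrom, dr[0], dr[1], id=g.symbol))
        trees["transcript"].insert(
            GenomicInterval(g.chrom, g.tx_start, g.tx_end, id=g.symbol)
        )
    return trees


def classify_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    cfg: Optional[AnnotationConfig] = None,
) -> AnnotationResult:
    """Assign one primary gene-part category per peak.

    Candidate labels are gathered against all transcripts, then the primary
    category is the highest-priority label; categories therefore partition
    the input and the observed fractions sum to 1 exactly.
    """
    cfg = cfg or AnnotationConfig()
    if not genes:
        raise ValueError("gene list is empty")
    trees = _part_trees(genes, cfg)
    gene_chroms = {g.chrom for g in genes}
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    by_cat: Dict[str, PeakSet] = {c: PeakSet(source=c) for c in CATEGORIES}
    links: List[Tuple[GenomicInterval, List[GeneLink]]] = []
    primary: List[Tuple[GenomicInterval, str]] = []
    warned_chroms = set()

    for iv in peaks:
        peak_links: List[GeneLink] = []
        if iv.chrom not in gene_chroms:
            if iv.chrom not in warned_chroms:
                warnings.warn(
                    f"no genes on {iv.chrom}; peaks there classified distal",
                    stacklevel=2,
                )
                warned_chroms.add(iv.chrom)
            cat = "distal"
        else:
            cat = None
            for part in ("promoter", "exon", "first_intron", "intron", "downstream"):
                hits = trees[part].query(iv)
                for h in hits:
                    peak_links.append(GeneLink(h.id, part, 0))
                if hits and cat is None:
                    cat = part
            if cat is None:
                # in no part: distal vs other by gap to the nearest transcript
                min_gap = min(
                    iv.distance_to(
                        GenomicInterval(g.chrom, g.tx_start, g.tx_end)
                    )
                    for g in genes_by_chrom[iv.chrom]
                )
                cat = "distal" if min_gap >= cfg.distal_min else "other"
                closest, _ = _closest_on_chrom(iv, genes_by_chrom[iv.chrom])
                for g in closest:
                    peak_links.append(
                        GeneLink(g.symbol, cat,
                                 iv.distance_to(GenomicInterval(g.chrom, g.tx_start, g.tx_end)))
                    )
        by_cat[cat].add(iv)
        primary.append((iv, cat))
        links.append((iv, peak_links))

    n = len(peaks)
    fractions = {c: (len(by_cat[c]) / n if n else 0.0) for c in CATEGORIES}
    return AnnotationResult(
        by_category=by_cat,
        gene_links=links,
        observed_fractions=fractions,
        primary=primary,
        config=cfg,
    )


def genome_labels(
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    cfg: Optional[AnnotationConfig] = None,
) -> Dict[str, np.ndarray]:
    """Per-base category labels (codes into CATEGORIES) per chromosome.

    Painted in ascending priority so higher-priority parts overwrite lower
    ones; the same priority order as :func:`classify_peaks`.
    """
    cfg = cfg or AnnotationConfig()
    labels = {
        chrom: np.full(size, _CODE["distal"], dtype=np.uint8)
        for chrom, size in chrom_sizes.items()
    }
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, arr in labels.items():
        size = len(arr)
        gs = genes_by_chrom.get(chrom, [])
        # "other": within distal_min of a transcript but in no part
        for g in gs:
            s = max(0, g.tx_start - cfg.distal_min)
            e = min(size, g.tx_end + cfg.distal_min)
            arr[s:e] = _CODE["other"]
        # then parts, lowest priority first
        for g in gs:
            dr = downstream_region(g, cfg.downstream_window)
            if dr is not None:
                arr[max(0, dr[0]) : min(size, dr[1])] = _CODE["downstream"]
        for g in gs:
            fi = g.first_intron()
            for s, e in g.introns():
                if (s, e) != fi:
                    arr[max(0, s) : min(size, e)] = _CODE["intron"]
        for g in gs:
            fi = g.first_intron()
            if fi is not None:
                arr[max(0, fi[0]) : min(size, fi[1])] = _CODE["first_intron"]
        for g in gs:
            for s, e in zip(g.exon_starts, g.exon_ends):
                arr[max(0, s) : min(size, e)] = _CODE["exon"]
        for g in gs:
            ps, pe = promoter_region(g, cfg.promoter_window)
            arr[max(0, ps) : min(size, pe)] = _CODE["promoter"]
    return labels


def expected_fractions(
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    cfg: Optional[AnnotationConfig] = None,
) -> Dict[str, float]:
    """Fraction of the genome in each category, by per-base labelling."""
    labels = genome_labels(genes, chrom_sizes, cfg)
    total = sum(chrom_sizes.values())
    counts = np.zeros(len(CATEGORIES), dtype=np.int64)
    for arr in labels.values():
        counts += np.bincount(arr, minlength=len(CATEGORIES))
    return {c: counts[_CODE[c]] / total for c in CATEGORIES}


def geneparts_matrix(result: AnnotationResult):
    """Gene x category matrix of peak counts (pandas DataFrame).

    Cell (g, c) counts the peaks linked to gene g in part c; a peak linked
    to several genes counts once per gene.
    """
    import pandas as pd

    cells: Dict[str, Dict[str, int]] = {}
    for iv, peak_links in result.gene_links:
        seen = set()
        for link in peak_links:
            key = (link.symbol, link.category)
            if key in seen:
                continue  # one peak counts once per (gene, part)
            seen.add(key)
            cells.setdefault(link.symbol, {c: 0 for c in CATEGORIES})
            cells[link.symbol][link.category] += 1
    if not cells:
        return pd.DataFrame(columns=list(CATEGORIES))
    df = pd.DataFrame.from_dict(cells, orient="index").fillna(0).astype(int)
    return df.reindex(columns=list(CATEGORIES), fill_value=0).sort_index()


def _closest_on_chrom(
    iv: GenomicInterval, genes: Sequence[GeneModel]
) -> Tuple[List[GeneModel], int]:
    best: List[GeneModel] = []
    best_d = None
    for g in genes:
        d = iv.distance_to(GenomicInterval(g.chrom, g.tx_start, g.tx_end))
        if best_d is None or d < best_d:
            best, best_d = [g], d
        elif d == best_d:
            best.append(g)
    return best, (best_d if best_d is not None else -1)


def find_closest_genes(
    peaks: PeakSet, genes: Sequence[GeneModel]
) -> List[Tuple[GenomicInterval, List[Tuple[GeneModel, int]]]]:
    """For every peak, all genes at the minimum gap distance (ties kept);
    distance 0 when the peak overlaps the transcript."""
    if not genes:
        raise ValueError("gene list is empty")
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for iv in peaks:
        gs = genes_by_chrom.get(iv.chrom, [])
        if not gs:
            out.append((iv, []))
            continue
        closest, d = _closest_on_chrom(iv, gs)
        out.append((iv, [(g, d) for g in closest]))
    return out


def find_distal_peaks(
    peaks: PeakSet, genes: Sequence[GeneModel], d: int
) -> PeakSet:
    """Peaks overlapping no transcript and at least ``d`` bp from every one."""
    if d < 0:
        raise ValueError("d must be >= 0")
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    keep = []
    for iv in peaks:
        gs = genes_by_chrom.get(iv.chrom, [])
        ok = True
        for g in gs:
            tx = GenomicInterval(g.chrom, g.tx_start, g.tx_end)
            if iv.overlaps(tx) or iv.distance_to(tx) < d:
                ok = False
                break
        if ok:
            keep.append(iv)
    return PeakSet(keep, source="distal")


def compare_genes(
    a: Iterable[str], b: Iterable[str]
) -> Tuple[List[str], List[str], List[str]]:
    """Case-sensitive set comparison of two gene lists:
    (common, only in a, only in b), each sorted."""
    sa, sb = set(a), set(b)
    return sorted(sa & sb), sorted(sa - sb), sorted(sb - sa)


def nongenic_annotate(
    peaks: PeakSet,
    tracks: Dict[str, PeakSet],
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    n_rand: int = 100,
    seed: int = 0,
    cfg: Optional[AnnotationConfig] = None,
):
    """Overlap the peaks with each named annotation track (repeats, CpG
    islands, external peak sets, ...) and score each overlap with the
    randomization test. Returns {track: (overlapping PeakSet, OverlapStats
    or None for an empty track)}."""
    from .core import compare_intervals, overlap_significance

    out = {}
    for name, track in tracks.items():
        if len(track) == 0:
            warnings.warn(f"track {name!r} is empty; significance skipped")
            out[name] = (PeakSet(source=name), None)
            continue
        hit = compare_intervals(peaks, track, mode="overlap")
        stats = overlap_significance(
            peaks, track, genes, chrom_sizes, n_rand=n_rand, seed=seed, cfg=cfg
        )
        out[name] = (hit, stats)
    return out
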