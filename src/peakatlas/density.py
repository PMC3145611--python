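"""Read-density matrices and clustering of density profiles.

A density matrix holds, per gene or peak, the mean per-base coverage of
fragment-extended reads in fixed-width bins across a window anchored at
the TSS, TES or peak summit (defaults: 4 kb window, 10 bp bins — 400
columns). Rows of minus-strand genes are flipped so column 0 is always
5'-most. RPKM normalization rescales a bin value by
10^9 / (bin_bp x total mapped reads), making values comparable across
libraries of different depth.

The read-count matrix summarises each peak across several datasets by its
maximum or average coverage. Rows of either matrix can be clustered with
the built-in self-organizing map, k-means, or average-linkage
hierarchical clustering; all are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .detect import coverage, peak_summit
from .formats import GeneModel, ReadSet
from .intervals import GenomicInterval, PeakSet


@dataclass
class DensityMatrix:
    values: pd.DataFrame  # rows: region ids, columns: bin index (5'->3')
    window: int
    bin: int
    anchor: str
    normalization: str
    truncated: List[str]  # region ids whose window left the chromosome


@dataclass
class ClusterAssignment:
    method: str
    labels: np.ndarray  # per-row cluster id
    row_ids: List[str]
    params: dict
    seed: Optional[int] = None

    def regions_in_cluster(self, cluster: int) -> List[str]:
        return [r for r, l in zip(self.row_ids, self.labels) if l == cluster]


def _anchors(
    anchor: str,
    regions: Union[Sequence[GeneModel], PeakSet],
) -> List[Tuple[str, str, int, str]]:
    """(row id, chrom, anchor position, strand) per region."""
    out = []
    if anchor in ("tss", "tes"):
        for g in regions:
            pos = g.tss if anchor == "tss" else g.tes
            out.append((g.name, g.chrom, pos, g.strand))
    elif anchor == "summit":
        for iv in regions:
            rid = iv.id or f"{iv.chrom}:{iv.start}-{iv.end}"
            out.append((rid, iv.chrom, peak_summit(iv), "+"))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return out


def density_matrix(
    anchor: str,
    regions: Union[Sequence[GeneModel], PeakSet],
    reads: ReadSet,
    chrom_sizes: Dict[str, int],
    window: int = 4000,
    bin: int = 10,
    normalize: str = "none",
) -> DensityMatrix:
    """Binned coverage matrix around TSS/TES/summit anchors.

    Bin value is the mean per-base extended-read coverage over the bin;
    windows that would leave the chromosome produce all-zero rows flagged
    in ``truncated``.
    """
    if window % bin != 0:
        raise ValueError("window must be divisible by bin")
    if normalize not in ("none", "rpkm"):
        raise ValueError(f"unknown normalization {normalize!r}")
    nb = window // bin
    cov = coverage(reads, chrom_sizes)
    anchors = _anchors(anchor, regions)
    mat = np.zeros((len(anchors), nb))
    truncated = []
    for ri, (rid, chrom, pos, strand) in enumerate(anchors):
        start = pos - window // 2
        end = start + window
        size = chrom_sizes.get(chrom, 0)
        if start < 0 or end > size or chrom not in cov:
            truncated.append(rid)
            continue
        row = cov[chrom][start:end].reshape(nb, bin).mean(axis=1)
        if strand == "-":
            row = row[::-1]  # column 0 is 5'-most
        mat[ri] = row
    if normalize == "rpkm":
        mat *= 1e9 / (bin * max(reads.total_reads, 1))
    df = pd.DataFrame(mat, index=[a[0] for a in anchors])
    return DensityMatrix(
        values=df, window=window, bin=bin, anchor=anchor,
        normalization=normalize, truncated=truncated,
    )


def read_count_matrix(
    peaks: PeakSet,
    datasets: Dict[str, ReadSet],
    chrom_sizes: Dict[str, int],
    stat: str = "max",
    normalize: str = "none",
) -> pd.DataFrame:
    """Per-peak max or average coverage across several read datasets.

    RPKM uses the peak length as the region size in the denominator.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if stat not in ("max", "avg"):
        raise ValueError(f"stat must be 'max' or 'avg', got {stat!r}")
    rows = [iv.id or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peaks]
    out = pd.DataFrame(0.0, index=rows, columns=list(datasets))
    for name, rs in datasets.items():
        if rs.total_reads == 0:
            import warnings

            warnings.warn(f"dataset {name!r} has no reads; zero column")
            continue
        cov = coverage(rs, chrom_sizes)
        for rid, iv in zip(rows, peaks):
            region = cov.get(iv.chrom, np.zeros(0))[iv.start : iv.end]
            if region.size == 0:
                continue
            v = float(region.max() if stat == "max" else region.mean())
            if normalize == "rpkm":
                v *= 1e9 / (iv.length * rs.total_reads)
            out.loc[rid, name] = v
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def som_cluster(
    matrix: pd.DataFrame,
    grid: Tuple[int, int] = (4, 4),
    epochs: int = 100,
    lr: Tuple[float, float] = (0.5, 0.01),
    seed: int = 0,
) -> ClusterAssignment:
    """Self-organizing map over matrix rows.

    Rectangular grid of prototype vectors; winner is the Euclidean-nearest
    node and its Gaussian neighbourhood is pulled toward the sample, with
    radius decaying linearly from max(grid)/2 to 0.5 and learning rate
    from lr[0] to lr[1]. Final cluster id = index of the nearest node.
    """
    gr, gc = grid
    if gr < 1 or gc < 1:
        raise ValueError("grid must be at least 1x1")
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("matrix is empty")
    rng = np.random.default_rng(seed)
    n_nodes = gr * gc
    # node coordinates on the grid, for neighbourhood distances
    coords = np.array([(i // gc, i % gc) for i in range(n_nodes)], dtype=float)
    # init prototypes from random rows with a little jitter
    init_rows = rng.integers(0, X.shape[0], size=n_nodes)
    W = X[init_rows] + rng.normal(0, 1e-6, size=(n_nodes, X.shape[1]))
    r0 = max(gr, gc) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = max(r0 * (1 - frac), 0.5)
        alpha = lr[0] + (lr[1] - lr[0]) * frac
        order = rng.permutation(X.shape[0])
        for ri in order:
            x = X[ri]
            winner = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            d2 = ((coords - coords[winner]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2 * radius**2))
            W += (alpha * h)[:, None] * (x - W)
    labels = np.array(
        [int(np.argmin(((W - x) ** 2).sum(axis=1))) for x in X]
    )
    return ClusterAssignment(
        method="som", labels=labels, row_ids=list(matrix.index),
        params={"grid": grid, "epochs": epochs, "lr": lr}, seed=seed,
    )


def kmeans_cluster(
    matrix: pd.DataFrame, k: int, seed: int = 0
) -> ClusterAssignment:
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix):
        raise ValueError("k exceeds number of rows")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(np.asarray(matrix, dtype=float))
    return ClusterAssignment(
        method="kmeans", labels=labels, row_ids=list(matrix.index),
        params={"k": k}, seed=seed,
    )


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int, linkage: str = "average"
) -> ClusterAssignment:
    if k <= 0:
        raise ValueError("k must be positive")
    from scipy.cluster.hierarchy import fcluster
    from scipy.cluster.hierarchy import linkage as scipy_linkage

    Z = scipy_linkage(np.asarray(matrix, dtype=float), method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return ClusterAssignment(
        method="hierarchical", labels=labels, row_ids=list(matrix.index),
        params={"k": k, "linkage": linkage},
    )


def summarize_density_in_geneparts(
    reads: ReadSet,
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    cfg=None,
) -> pd.DataFrame:
    """Mean per-base coverage in each gene-part category, plot-ready."""
    from .annotate import CATEGORIES, genome_labels

    labels = genome_labels(genes, chrom_sizes, cfg)
    cov = coverage(reads, chrom_sizes)
    sums = np.zeros(len(CATEGORIES))
    bases = np.zeros(len(CATEGORIES))
    for chrom, lab in labels.items():
        c = cov.get(chrom)
        if c is None:
            continue
        for ci in range(len(CATEGORIES)):
            mask = lab == ci
            bases[ci] += mask.sum()
            sums[ci] += c[mask].sum()
    with np.errstate(invalid="ignore"):
        means = np.where(bases > 0, sums / np.maximum(bases, 1), np.nan)
    return pd.DataFrame(
        {"category": list(CATEGORIES), "bases": bases.astype(int), "mean_coverage": means}
    )
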