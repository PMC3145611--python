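"""Pathway association of peak-linked genes.

A peak list is first reduced to the set of genes it is linked to (optionally
restricted to chosen gene-part categories, e.g. promoter peaks only). For a
named pathway, significance is the upper tail of the hypergeometric
distribution: with N genes in the universe, K of them in the pathway and n
of them peak-linked, the p-value is the probability of drawing at least the
observed k pathway genes when n genes are sampled without replacement,

    p = sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N, n).

Counting is gene-level: a gene with many peaks contributes once. The
multi-pathway scan applies the same test to every set in a collection and
adds Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd
from scipy.stats import hypergeom

from .annotate import CATEGORIES, AnnotationResult
from .formats import GeneSetCollection
from .intervals import PeakSet


@dataclass
class PathwayMatchResult:
    pathway: str
    N: int  # universe size
    K: int  # pathway genes in the universe
    n: int  # peak-linked genes in the universe
    k: int  # overlap
    p_value: float
    member_hits: Dict[str, PeakSet] = field(default_factory=dict)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def pathway_match(
    genes_of_peaks: Dict[str, PeakSet],
    pathway: str,
    gsc: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
) -> PathwayMatchResult:
    """Associate peak-linked genes with one named pathway.

    ``genes_of_peaks`` maps gene symbol -> peaks linked to it. Genes absent
    from the universe are ignored entirely. Raises with near-matches when
    the pathway name is unknown.
    """
    if pathway not in gsc.sets:
        near = [p for p in gsc.sets if pathway.lower() in p.lower()]
        hint = f"; did you mean one of {near[:5]}?" if near else ""
        raise KeyError(f"pathway {pathway!r} not in collection{hint}")
    uni: Set[str] = set(universe) if universe is not None else (
        set(gsc.universe) if gsc.universe else
        set(genes_of_peaks) | {g for m in gsc.sets.values() for g in m}
    )
    members = set(gsc.sets[pathway]) & uni
    linked = set(genes_of_peaks) & uni
    overlap = members & linked
    N, K, n, k = len(uni), len(members), len(linked), len(overlap)
    p = hypergeometric_tail(N, K, n, k)
    return PathwayMatchResult(
        pathway=pathway, N=N, K=K, n=n, k=k, p_value=p,
        member_hits={g: genes_of_peaks[g] for g in sorted(overlap)},
    )


def enriched_pathways(
    genes_of_peaks: Dict[str, PeakSet],
    gsc: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    min_set: int = 1,
    correction: Optional[str] = "BH",
) -> pd.DataFrame:
    """Hypergeometric enrichment over every set in the collection.

    Sets with fewer than ``min_set`` universe members are skipped. Returns
    a DataFrame (pathway, N, K, n, k, p, q) sorted by p; q is the BH
    step-up adjusted p-value (q = p when correction is None or only one
    set is tested).
    """
    if min_set < 1:
        raise ValueError("min_set must be >= 1")
    if not gsc.sets:
        raise ValueError("gene-set collection is empty")
    uni: Set[str] = set(universe) if universe is not None else (
        set(gsc.universe) if gsc.universe else
        set(genes_of_peaks) | {g for m in gsc.sets.values() for g in m}
    )
    rows = []
    for name in gsc.sets:
        res = pathway_match(genes_of_peaks, name, gsc, universe=uni)
        if res.K < min_set:
            continue
        rows.append((name, res.N, res.K, res.n, res.k, res.p_value))
    df = pd.DataFrame(rows, columns=["pathway", "N", "K", "n", "k", "p"])
    if df.empty:
        df["q"] = []
        return df
    if correction == "BH" and len(df) > 1:
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    elif correction in (None, "BH"):
        df["q"] = df["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df.sort_values(["p", "pathway"]).reset_index(drop=True)


def peak_category_filter(
    annotation: AnnotationResult, categories: Sequence[str]
) -> Dict[str, PeakSet]:
    """Gene -> peaks restricted to peaks of the chosen primary categories."""
    if not categories:
        raise ValueError("categories must be non-empty")
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    wanted = set(categories)
    primary = {id(iv): cat for iv, cat in annotation.primary}
    out: Dict[str, PeakSet] = {}
    for iv, links in annotation.gene_links:
        if primary[id(iv)] not in wanted:
            continue
        for link in links:
            out.setdefault(link.symbol, PeakSet(source="filtered")).add(iv)
    return out


def genes_of_peaks_from_annotation(annotation: AnnotationResult) -> Dict[str, PeakSet]:
    """All gene links regardless of category."""
    return peak_category_filter(annotation, CATEGORIES)


def write_membership_table(
    genes_by_group: Dict[str, Iterable[str]], path
) -> None:
    """Gene -> group membership table for external enrichment tools."""
    with open(path, "w") as fh:
        fh.write("gene\tgroup\n")
        for group, genes in genes_by_group.items():
            for g in sorted(set(genes)):
                fh.write(f"{g}\t{group}\n")
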