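"""Synthetic ChIP-seq study generator.

Produces a complete, self-consistent miniature dataset — genome FASTA,
refGene-style gene table, ChIP and control read files, conservation
track, CpG-island and repeat tracks, a PFM motif, gene sets, and
histone-mark / cofactor peak files — together with a ground-truth
manifest (truth.json) recording exactly what was planted where. Every
module of the toolkit can therefore be exercised end-to-end without any
downloads, and all outputs are byte-reproducible from the seed.

What is emulated: uniform Poisson background reads with uniform spike
reads inside truth peaks (fragment geometry consistent with the peak
caller), truth peaks split between gene promoters and intergenic
territory, a consensus motif embedded in a stated fraction of truth
peaks, a conservation track elevated over truth peaks, and an
enhancer-style configuration of marks (mark1 present / mark2 absent /
cofactor present on a known subset of the distal peaks).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotate import _CODE, AnnotationConfig, genome_labels
from .formats import (
    PWM,
    GeneModel,
    GeneSetCollection,
    write_chrom_sizes,
    write_gmt,
    write_pfm,
    write_refgene,
)
from .intervals import GenomicInterval, PeakSet


@dataclass
class FixtureSpec:
    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 160_000, "chr2": 100_000}
    )
    n_genes: int = 18
    gene_length: int = 4000
    n_truth_peaks: int = 30
    promoter_fraction: float = 0.5  # of truth peaks at promoters
    peak_length: int = 400
    fold: float = 10.0  # spike enrichment over background
    background_rate: float = 0.02  # background reads per bp
    read_length: int = 36
    fragment_length: int = 200
    motif_fraction: float = 0.8  # truth peaks carrying the motif
    motif_consensus: str = "TGACGTCATT"
    gc: float = 0.5
    cpg_gc: float = 0.75
    n_cpg_islands: int = 12
    cpg_island_length: int = 500
    n_repeats: int = 20
    repeat_length: int = 300
    cons_baseline: float = 0.1
    cons_peak_level: float = 0.8
    n_random_gene_sets: int = 8
    random_set_size: int = 6


@dataclass
class Fixture:
    spec: FixtureSpec
    outdir: Path
    genome_fa: Path
    genes_path: Path
    chip_bed: Path
    control_bed: Path
    cons_wig: Path
    cpg_bed: Path
    repeats_bed: Path
    motifs_pfm: Path
    genesets_gmt: Path
    chrom_sizes_path: Path
    mark1_bed: Path
    mark2_bed: Path
    cofactor_bed: Path
    truth: dict
    genes: List[GeneModel]
    truth_peaks: PeakSet


def _place_genes(spec: FixtureSpec) -> List[GeneModel]:
    """Regularly spaced, non-overlapping genes with 3 exons each,
    alternating strand; layout leaves intergenic territory between genes."""
    genes: List[GeneModel] = []
    chroms = sorted(spec.chrom_sizes)
    total = sum(spec.chrom_sizes.values())
    gi = 0
    for chrom in chroms:
        size = spec.chrom_sizes[chrom]
        n = max(1, round(spec.n_genes * size / total))
        slot = size // n
        if slot < spec.gene_length + 10_000:
            n = max(1, size // (spec.gene_length + 10_000))
            slot = size // n
        for j in range(n):
            if gi >= spec.n_genes:
                break
            start = j * slot + 4000
            end = start + spec.gene_length
            if end + 4000 > size:
                continue
            L = spec.gene_length
            exon_starts = [start, start + int(0.4 * L), start + int(0.8 * L)]
            exon_ends = [start + int(0.2 * L), start + int(0.55 * L), end]
            genes.append(
                GeneModel(
                    name=f"tx{gi:03d}",
                    symbol=f"GENE{gi:03d}",
                    chrom=chrom,
                    strand="+" if gi % 2 == 0 else "-",
                    tx_start=start,
                    tx_end=end,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
            gi += 1
    return genes


def _label_runs(arr: np.ndarray, code: int) -> List[Tuple[int, int]]:
    mask = arr == code
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _place_truth_peaks(
    spec: FixtureSpec, genes: List[GeneModel], rng: np.random.Generator
) -> List[dict]:
    """Truth peaks: a fraction centred on gene TSSs (promoter peaks), the
    rest placed wholly inside distal-labelled territory."""
    labels = genome_labels(genes, spec.chrom_sizes, AnnotationConfig())
    n_prom = int(round(spec.n_truth_peaks * spec.promoter_fraction))
    n_dist = spec.n_truth_peaks - n_prom
    peaks: List[dict] = []
    half = spec.peak_length // 2

    prom_genes = list(genes)
    rng.shuffle(prom_genes)
    for g in prom_genes[:n_prom]:
        center = g.tss
        start = center - half
        peaks.append(
            {"chrom": g.chrom, "start": int(start), "end": int(start + spec.peak_length),
             "kind": "promoter", "gene": g.symbol}
        )
    if len(peaks) < n_prom:
        raise ValueError("not enough genes for the requested promoter peaks")

    distal_runs = []
    for chrom, arr in labels.items():
        for s, e in _label_runs(arr, _CODE["distal"]):
            # keep a margin so spike fragments stay distal-ish and windows fit
            if e - s >= spec.peak_length + 2 * spec.fragment_length:
                distal_runs.append((chrom, s, e))
    if len(distal_runs) == 0:
        raise ValueError("no distal territory for truth peaks")
    placed = 0
    attempts = 0
    used: Dict[Tuple[str, int, int], bool] = {}
    while placed < n_dist:
        attempts += 1
        if attempts > 100 * n_dist:
            raise ValueError("could not place all distal truth peaks")
        chrom, s, e = distal_runs[int(rng.integers(0, len(distal_runs)))]
        lo = s + spec.fragment_length
        hi = e - spec.fragment_length - spec.peak_length
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        iv = (chrom, start, start + spec.peak_length)
        if any(
            c == chrom and start < pe and ps < iv[2]
            for c, ps, pe in (
                (p["chrom"], p["start"] - 500, p["end"] + 500) for p in peaks
            )
        ):
            continue
        peaks.append(
            {"chrom": chrom, "start": iv[1], "end": iv[2], "kind": "distal",
             "gene": None}
        )
        placed += 1
    for i, p in enumerate(peaks):
        p["id"] = f"truth_{i:03d}"
        if p["start"] < 0 or p["end"] > spec.chrom_sizes[p["chrom"]]:
            raise ValueError(f"truth peak {p['id']} off chromosome")
    return peaks


def _make_genome(
    spec: FixtureSpec,
    truth_peaks: List[dict],
    cpg_islands: List[Tuple[str, int, int]],
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """i.i.d. genome with configurable GC, GC-rich CpG islands, and the
    motif consensus written into a fraction of truth peaks."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p_bg = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    p_cpg = np.array(
        [(1 - spec.cpg_gc) / 2, spec.cpg_gc / 2, spec.cpg_gc / 2, (1 - spec.cpg_gc) / 2]
    )
    genome = {
        chrom: bases[rng.choice(4, size=size, p=p_bg)]
        for chrom, size in spec.chrom_sizes.items()
    }
    for chrom, s, e in cpg_islands:
        genome[chrom][s:e] = bases[rng.choice(4, size=e - s, p=p_cpg)]
    motif = np.frombuffer(spec.motif_consensus.encode(), dtype="S1")
    n_with = int(round(spec.motif_fraction * len(truth_peaks)))
    order = rng.permutation(len(truth_peaks))
    for idx in order[:n_with]:
        p = truth_peaks[idx]
        center = (p["start"] + p["end"]) // 2
        genome[p["chrom"]][center : center + len(motif)] = motif
        p["has_motif"] = True
    for idx in order[n_with:]:
        truth_peaks[idx]["has_motif"] = False
    return genome


def _write_fasta(genome: Dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _simulate_reads(
    spec: FixtureSpec,
    truth_peaks: Optional[List[dict]],
    rng: np.random.Generator,
) -> List[Tuple[str, int, int, str]]:
    """Background Poisson-uniform reads plus, when truth peaks are given,
    spike reads uniform within each truth peak at fold x background."""
    reads: List[Tuple[str, int, int, str]] = []
    rl = spec.read_length
    for chrom in sorted(spec.chrom_sizes):
        size = spec.chrom_sizes[chrom]
        n_bg = rng.poisson(spec.background_rate * size)
        starts = rng.integers(0, size - rl, size=n_bg)
        strands = rng.choice(["+", "-"], size=n_bg)
        for s, st in zip(starts, strands):
            reads.append((chrom, int(s), int(s) + rl, str(st)))
    if truth_peaks:
        for p in truth_peaks:
            lam = spec.background_rate * (p["end"] - p["start"]) * spec.fold
            n_spike = rng.poisson(lam)
            starts = rng.integers(p["start"], p["end"] - rl, size=n_spike)
            strands = rng.choice(["+", "-"], size=n_spike)
            for s, st in zip(starts, strands):
                reads.append((p["chrom"], int(s), int(s) + rl, str(st)))
    reads.sort()
    return reads


def _write_reads_bed(reads, path: Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e, st) in enumerate(reads):
            fh.write(f"{chrom}\t{s}\t{e}\tr{i}\t0\t{st}\n")


def _write_cons_wig(spec: FixtureSpec, truth_peaks: List[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(spec.chrom_sizes):
            size = spec.chrom_sizes[chrom]
            vec = np.full(size, spec.cons_baseline)
            for p in truth_peaks:
                if p["chrom"] == chrom:
                    vec[p["start"] : p["end"]] = spec.cons_peak_level
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:g}" for v in vec) + "\n")


def _random_intervals_bed(
    spec: FixtureSpec, n: int, length: int, rng: np.random.Generator
) -> List[Tuple[str, int, int]]:
    chroms = sorted(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for _ in range(n):
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, sizes[ci] - length))
        out.append((chroms[ci], start, start + length))
    return sorted(out)


def _write_bed(intervals, path: Path, prefix: str = "iv") -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            fh.write(f"{chrom}\t{s}\t{e}\t{prefix}_{i}\n")


def make_fixture(spec: FixtureSpec, outdir) -> Fixture:
    """Generate the full synthetic study under ``outdir``.

    Deterministic: identical spec (including seed) yields byte-identical
    files. Returns a :class:`Fixture` with paths, the in-memory gene
    models and truth peaks, and the truth manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = _place_genes(spec)
    truth_peaks = _place_truth_peaks(spec, genes, rng)
    cpg = _random_intervals_bed(
        spec, spec.n_cpg_islands, spec.cpg_island_length, rng
    )
    genome = _make_genome(spec, truth_peaks, cpg, rng)
    repeats = _random_intervals_bed(spec, spec.n_repeats, spec.repeat_length, rng)

    chip = _simulate_reads(spec, truth_peaks, rng)
    control = _simulate_reads(spec, None, rng)

    # enhancer-style marks over the distal truth peaks: mark1 (enhancer
    # mark) on a subset, mark2 (promoter mark) on a different subset,
    # cofactor on a subset of mark1-positives
    distal = [p for p in truth_peaks if p["kind"] == "distal"]
    order = rng.permutation(len(distal))
    n1 = int(round(0.7 * len(distal)))
    mark1_ids = {distal[i]["id"] for i in order[:n1]}
    mark2_ids = {
        p["id"] for p in distal if rng.random() < 0.3
    } | {p["id"] for p in truth_peaks if p["kind"] == "promoter"}
    cof_ids = {i for i in mark1_ids if rng.random() < 0.8}

    def mark_intervals(ids):
        out = []
        for p in truth_peaks:
            if p["id"] in ids:
                jitter = int(rng.integers(-50, 51))
                s = max(0, p["start"] + jitter)
                out.append((p["chrom"], s, s + (p["end"] - p["start"])))
        return sorted(out)

    mark1 = mark_intervals(mark1_ids)
    mark2 = mark_intervals(mark2_ids)
    cofactor = mark_intervals(cof_ids)

    # gene sets: one planted set = genes carrying promoter truth peaks,
    # plus random decoys
    symbols = [g.symbol for g in genes]
    planted = sorted({p["gene"] for p in truth_peaks if p["gene"]})
    sets = {"planted_truth_targets": planted}
    for i in range(spec.n_random_gene_sets):
        picks = rng.choice(symbols, size=min(spec.random_set_size, len(symbols)),
                           replace=False)
        sets[f"random_set_{i}"] = sorted(str(s) for s in picks)
    gsc = GeneSetCollection(sets=sets, universe=sorted(symbols))

    # motif PFM: hard consensus counts so only exact matches score high
    consensus = spec.motif_consensus
    counts = np.zeros((4, len(consensus)))
    for i, ch in enumerate(consensus):
        counts["ACGT".index(ch), i] = 18.0
    pwm = PWM(name="truth_motif", counts=counts)

    # --- write everything ---------------------------------------------
    paths = {
        "genome_fa": outdir / "genome.fa",
        "genes_path": outdir / "genes.refGene",
        "chip_bed": outdir / "chip.bed",
        "control_bed": outdir / "control.bed",
        "cons_wig": outdir / "cons.wig",
        "cpg_bed": outdir / "cpg.bed",
        "repeats_bed": outdir / "repeats.bed",
        "motifs_pfm": outdir / "motifs.pfm",
        "genesets_gmt": outdir / "genesets.gmt",
        "chrom_sizes_path": outdir / "chrom.sizes",
        "mark1_bed": outdir / "mark1.bed",
        "mark2_bed": outdir / "mark2.bed",
        "cofactor_bed": outdir / "cofactor.bed",
    }
    _write_fasta(genome, paths["genome_fa"])
    write_refgene(genes, paths["genes_path"])
    _write_reads_bed(chip, paths["chip_bed"])
    _write_reads_bed(control, paths["control_bed"])
    _write_cons_wig(spec, truth_peaks, paths["cons_wig"])
    _write_bed(cpg, paths["cpg_bed"], "cpg")
    _write_bed(repeats, paths["repeats_bed"], "rep")
    write_pfm([pwm], paths["motifs_pfm"])
    write_gmt(gsc, paths["genesets_gmt"])
    write_chrom_sizes(spec.chrom_sizes, paths["chrom_sizes_path"])
    _write_bed(mark1, paths["mark1_bed"], "mark1")
    _write_bed(mark2, paths["mark2_bed"], "mark2")
    _write_bed(cofactor, paths["cofactor_bed"], "cof")

    truth = {
        "seed": spec.seed,
        "chrom_sizes": spec.chrom_sizes,
        "truth_peaks": truth_peaks,
        "motif_consensus": consensus,
        "motif_fraction": spec.motif_fraction,
        "planted_gene_set": planted,
        "mark1_ids": sorted(mark1_ids),
        "mark2_ids": sorted(mark2_ids),
        "cofactor_ids": sorted(cof_ids),
        "enhancer_ids": sorted(
            (mark1_ids - mark2_ids) & cof_ids
        ),
        "universe": sorted(symbols),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    truth_ps = PeakSet(
        (
            GenomicInterval(p["chrom"], p["start"], p["end"], id=p["id"])
            for p in truth_peaks
        ),
        source="truth",
    )
    return Fixture(
        spec=spec, outdir=outdir, truth=truth, genes=genes,
        truth_peaks=truth_ps, **paths,
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
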