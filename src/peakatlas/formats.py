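"""Readers and writers for the external formats the toolkit touches.

Everything is normalised to one internal convention: 0-based, half-open
coordinates. SAM positions (1-based) are shifted by -1 on input; fixedStep
wiggle positions (1-based) are shifted on both input and output. All readers
and writers round-trip on coordinates, names and strands.

Formats handled here: BED3/BED6 peak and read files, SAM (via pysam),
refGene-style gene tables, indexed FASTA (via pyfaidx), fixedStep wiggle and
bedGraph score tracks, JASPAR-style PFM matrices, and GMT gene-set files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from pyfaidx import Fasta

from .intervals import GenomicInterval, PeakSet

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Read:
    start: int  # 0-based leftmost mapped position
    end: int  # half-open right edge of the mapped read
    strand: str  # "+" or "-"


class ReadSet:
    """Mapped reads grouped by chromosome, with a fragment-extension length.

    ChIP fragments are longer than the sequenced tag, so coverage
    computations extend each read to ``fragment_length`` bp in its 3'
    direction (default 200 bp).
    """

    def __init__(self, fragment_length: int = 200, source: str = "") -> None:
        if fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        self.fragment_length = fragment_length
        self.source = source
        self.reads: Dict[str, List[Read]] = {}
        self.skipped_unmapped = 0

    def add(self, chrom: str, start: int, end: int, strand: str = "+") -> None:
        self.reads.setdefault(chrom, []).append(Read(start, end, strand))

    @property
    def total_reads(self) -> int:
        return sum(len(v) for v in self.reads.values())

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self.reads)

    def on(self, chrom: str) -> List[Read]:
        return self.reads.get(chrom, [])


@dataclass
class GeneModel:
    """A transcript model: strand, span, and exon structure.

    TSS is ``tx_start`` on the + strand and ``tx_end - 1`` on the - strand;
    introns are the gaps between consecutive exons, numbered in
    transcription order (first intron is 5'-most).
    """

    name: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: List[int]
    exon_ends: List[int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon start/end lists differ in length")
        if self.tx_end <= self.tx_start:
            raise ValueError("tx_end must exceed tx_start")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def introns(self) -> List[Tuple[int, int]]:
        """Intron intervals in genomic order."""
        out = []
        for i in range(len(self.exon_starts) - 1):
            a, b = self.exon_ends[i], self.exon_starts[i + 1]
            if b > a:
                out.append((a, b))
        return out

    def first_intron(self) -> Optional[Tuple[int, int]]:
        """The 5'-most intron in transcription order, if any."""
        introns = self.introns()
        if not introns:
            return None
        return introns[0] if self.strand == "+" else introns[-1]


@dataclass
class PWM:
    """Position frequency matrix: per-column counts for A, C, G, T."""

    name: str
    counts: np.ndarray  # shape (4, width)

    BASES = "ACGT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("PWM must have width >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column needs a positive total")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join(self.BASES[i] for i in self.counts.argmax(axis=0))


class ScoreTrack:
    """Sparse per-base scores: non-overlapping runs of consecutive values."""

    def __init__(self) -> None:
        self.runs: Dict[str, List[Tuple[int, np.ndarray]]] = {}

    def add_run(self, chrom: str, start: int, scores: Sequence[float]) -> None:
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            return
        self.runs.setdefault(chrom, []).append((start, arr))

    def finalize(self) -> None:
        for chrom in self.runs:
            self.runs[chrom].sort(key=lambda r: r[0])
            prev_end = -1
            for start, arr in self.runs[chrom]:
                if start < prev_end:
                    raise ValueError(f"overlapping score runs on {chrom}")
                prev_end = start + len(arr)

    def values(
        self, chrom: str, start: int, end: int, missing: float = np.nan
    ) -> np.ndarray:
        """Dense score vector over [start, end); uncovered bases get ``missing``."""
        out = np.full(end - start, missing, dtype=float)
        for run_start, arr in self.runs.get(chrom, []):
            run_end = run_start + len(arr)
            lo = max(start, run_start)
            hi = min(end, run_end)
            if lo < hi:
                out[lo - start : hi - start] = arr[lo - run_start : hi - run_start]
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) plus an optional explicit universe."""

    sets: Dict[str, List[str]]
    universe: Optional[List[str]] = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


# ---------------------------------------------------------------------------
# Peak (BED) I/O
# ---------------------------------------------------------------------------


def read_peaks(path: os.PathLike | str, fmt: str = "bed") -> PeakSet:
    """Read a peak list from a BED3+ file.

    Coordinates are taken unchanged (BED is already 0-based half-open).
    Columns beyond the sixth are preserved opaquely on each interval.
    """
    if fmt != "bed":
        raise ValueError(f"unsupported peak format {fmt!r}")
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            intervals.append(
                GenomicInterval(
                    fields[0], start, end, id=name, score=score,
                    extra=tuple(fields[5:]),
                )
            )
    return PeakSet(intervals, source=str(path))


def write_peaks(peaks: PeakSet, path: os.PathLike | str) -> None:
    """Write a peak set as BED; emits as many columns as the data carries."""
    with open(path, "w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.score is not None or iv.extra:
                fields.append(iv.id if iv.id is not None else ".")
            if iv.score is not None or iv.extra:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            fields.extend(iv.extra)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Read I/O
# ---------------------------------------------------------------------------


def read_reads(
    path: os.PathLike | str, fmt: str = "bed", fragment_length: int = 200
) -> ReadSet:
    """Read mapped reads from a BED or SAM file.

    SAM positions are 1-based and converted to the internal 0-based
    convention; unmapped records are skipped and counted. BED reads lacking
    a strand column default to "+" with a warning.
    """
    rs = ReadSet(fragment_length=fragment_length, source=str(path))
    if fmt == "bed":
        warned = False
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
                start, end = int(fields[1]), int(fields[2])
                if len(fields) >= 6 and fields[5] in ("+", "-"):
                    strand = fields[5]
                else:
                    strand = "+"
                    if not warned:
                        warnings.warn(
                            f"{path}: reads without strand default to '+'",
                            stacklevel=2,
                        )
                        warned = True
                rs.add(fields[0], start, end, strand)
    elif fmt == "sam":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped:
                    rs.skipped_unmapped += 1
                    continue
                start = rec.reference_start  # pysam is already 0-based
                end = rec.reference_end
                if end is None:
                    end = start + (rec.query_length or 1)
                rs.add(
                    rec.reference_name, start, end, "-" if rec.is_reverse else "+"
                )
    else:
        raise ValueError(f"unknown read format {fmt!r}")
    return rs


def write_reads_bed(reads: ReadSet, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for chrom in reads.chromosomes:
            for r in reads.on(chrom):
                fh.write(f"{chrom}\t{r.start}\t{r.end}\tread\t0\t{r.strand}\n")


def split_reads_by_chromosome(
    reads: ReadSet, outdir: os.PathLike | str, overwrite: bool = False
) -> List[Path]:
    """Write one BED file of reads per chromosome; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in reads.chromosomes:
        p = outdir / f"{chrom}.bed"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True")
        sub = ReadSet(fragment_length=reads.fragment_length)
        sub.reads[chrom] = reads.on(chrom)
        write_reads_bed(sub, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch_sequences(
    genome: os.PathLike | str | Fasta, peaks: PeakSet
) -> List[Tuple[GenomicInterval, str]]:
    """Extract the + strand sequence under every peak, uppercase.

    Raises if a peak names an unknown chromosome or extends beyond the
    chromosome end; all offenders are listed.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    bad = []
    for iv in peaks:
        if iv.chrom not in fa:
            bad.append(f"{iv.chrom} (unknown chromosome)")
        elif iv.end > len(fa[iv.chrom]):
            bad.append(f"{iv.chrom}:{iv.start}-{iv.end} (past chromosome end)")
    if bad:
        raise ValueError("out-of-bounds intervals: " + ", ".join(bad))
    out = []
    for iv in peaks:
        seq = str(fa[iv.chrom][iv.start : iv.end]).upper()
        out.append((iv, seq))
    return out


# ---------------------------------------------------------------------------
# Browser tracks
# ---------------------------------------------------------------------------


def write_peak_track(
    peaks: PeakSet, path: os.PathLike | str, name: str = "peaks"
) -> None:
    """BED track with a UCSC-style header line."""
    with open(path, "w") as fh:
        fh.write(f'track name="{name}" description="{name}"\n')
        for iv in peaks:
            label = iv.id if iv.id is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t{score}\t.\n")


def write_density_track(
    coverage: Dict[str, np.ndarray],
    path: os.PathLike | str,
    name: str = "density",
    step: int = 1,
) -> None:
    """fixedStep wiggle of per-base coverage (1-based start per the dialect)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(coverage):
            vec = coverage[chrom]
            fh.write(f"fixedStep chrom={chrom} start=1 step={step} span={step}\n")
            for i in range(0, len(vec), step):
                fh.write(f"{vec[i]:g}\n")


def write_tracks(data, kind: str, path: os.PathLike | str, name: str = "track") -> None:
    if kind == "peaks":
        write_peak_track(data, path, name=name)
    elif kind == "density":
        write_density_track(data, path, name=name)
    else:
        raise ValueError(f"unknown track kind {kind!r}")


# ---------------------------------------------------------------------------
# Gene models (refGene-style table)
# ---------------------------------------------------------------------------


def read_refgene(path: os.PathLike | str) -> List[GeneModel]:
    """Read a refGene-style tab table.

    Expected columns (an optional leading bin column is detected and
    skipped): name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds, name2. Exon lists are comma-separated,
    trailing comma accepted.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            # refGene dumps sometimes carry a leading numeric bin column
            if len(f) >= 12 and f[2] in ("+", "-") and f[3].isdigit():
                f = f[1:]
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: too few columns for refGene")
            exon_starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            exon_ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            symbol = f[10] if len(f) > 10 and f[10] else f[0]
            genes.append(
                GeneModel(
                    name=f[0],
                    symbol=symbol,
                    chrom=f[1],
                    strand=f[2],
                    tx_start=int(f[3]),
                    tx_end=int(f[4]),
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
    return genes


def write_refgene(genes: Sequence[GeneModel], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exon_count = len(g.exon_starts)
            cds_start, cds_end = g.tx_start, g.tx_end
            starts = ",".join(str(x) for x in g.exon_starts) + ","
            ends = ",".join(str(x) for x in g.exon_ends) + ","
            fh.write(
                "\t".join(
                    [
                        g.name,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(cds_start),
                        str(cds_end),
                        str(exon_count),
                        starts,
                        ends,
                        g.symbol,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Score tracks (wiggle / bedGraph)
# ---------------------------------------------------------------------------


def read_wiggle(path: os.PathLike | str) -> ScoreTrack:
    """fixedStep wiggle reader (step=span supported); 1-based starts shifted."""
    track = ScoreTrack()
    chrom, pos, step, span = None, 0, 1, 1
    buf: List[float] = []
    buf_start = 0

    def flush():
        nonlocal buf
        if chrom is not None and buf:
            if step == 1 and span == 1:
                track.add_run(chrom, buf_start, buf)
            else:
                for i, v in enumerate(buf):
                    track.add_run(chrom, buf_start + i * step, [v] * span)
        buf = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                buf_start = pos
            elif line.startswith("variableStep"):
                raise ValueError("variableStep wiggle not supported")
            else:
                buf.append(float(line))
    flush()
    track.finalize()
    return track


def read_bedgraph(path: os.PathLike | str) -> ScoreTrack:
    track = ScoreTrack()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            start, end = int(start), int(end)
            track.add_run(chrom, start, [float(value)] * (end - start))
    track.finalize()
    return track


def read_score_track(path: os.PathLike | str) -> ScoreTrack:
    """Auto-detect fixedStep wiggle vs bedGraph by content."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("fixedStep"):
                return read_wiggle(path)
            if line.strip() and not line.startswith(("#", "track", "browser")):
                return read_bedgraph(path)
    return ScoreTrack()


def write_wiggle(track: ScoreTrack, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            for start, arr in track.runs[chrom]:
                fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
                for v in arr:
                    fh.write(f"{v:g}\n")


# ---------------------------------------------------------------------------
# PFM (JASPAR) and GMT
# ---------------------------------------------------------------------------


def read_pfm(path: os.PathLike | str) -> List[PWM]:
    """JASPAR-style PFM: a '>' header then four labelled rows of counts.

    Rows may look like ``A  [ 4 19 0 ]`` or ``A 4 19 0``; row order follows
    the labels, not the file order.
    """
    motifs: List[PWM] = []
    name = None
    rows: Dict[str, List[float]] = {}

    def flush():
        nonlocal rows, name
        if name is not None and rows:
            missing = set("ACGT") - set(rows)
            if missing:
                raise ValueError(f"motif {name}: missing rows {sorted(missing)}")
            counts = np.array([rows[b] for b in "ACGT"])
            motifs.append(PWM(name=name, counts=counts))
        rows = {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                base = parts[0].upper()
                if base not in "ACGT":
                    raise ValueError(f"unexpected PFM row label {parts[0]!r}")
                rows[base] = [float(x) for x in parts[1:]]
    flush()
    return motifs


def write_pfm(motifs: Sequence[PWM], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


def read_gmt(path: os.PathLike | str) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member symbols."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs >= 3 columns")
            if f[0] in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {f[0]!r}")
            members = [g for g in f[2:] if g]
            sets[f[0]] = members
    return GeneSetCollection(sets=sets)


def write_gmt(gsc: GeneSetCollection, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# Chromosome sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: os.PathLike | str) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
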