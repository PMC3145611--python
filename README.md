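# peakatlas

A composable toolkit for interpreting ChIP-seq experiments after read
mapping. Every analysis consumes and emits plain peak lists — BED-style,
0-based half-open genomic intervals — so the modules chain into whatever
workflow a question needs: call peaks from read density, classify them into
gene parts, test overlaps between peak files against a genomic
randomization null, scan peak sequences for binding motifs against matched
backgrounds, associate peak-linked genes with pathways, profile
evolutionary conservation and read density, and cluster the resulting
matrices.

It is written for regulatory-genomics analysts who want scriptable,
reproducible building blocks rather than a monolithic pipeline: the
primary interface is the Python API (see `examples/`), with a thin
`peakatlas` command for shell use.

## The statistics at the core

**Overlap significance.** Whether peak list *A* overlaps peak list *B*
more than chance expects is assessed by randomization. Each replicate
re-places every peak of *A* uniformly within the genomic territory of its
own gene-part category (promoter, exonic, intronic, downstream,
intergenic) on its own chromosome, conserving the peak count, the
per-chromosome length multiset, and the category composition exactly.
With observed overlap *o* and null overlaps *r₁ … r_N*,

    p = (1 + #{i : rᵢ ≥ o}) / (1 + N),    z = (o − mean(r)) / sd(r).

**Jaccard similarity** between two peak files is computed on the connected
components of their merged union: components containing peaks from both
files, divided by all components — symmetric and bounded by 1.

**Motif scanning** uses Berg–von Hippel weights: each PWM column's counts
n(b,i) become w(b,i) = ln((n(b,i)+0.5) / (n_max(i)+0.5)), so the consensus
window scores 0 and every window's *relative affinity* exp(Σw) lies in
(0, 1]; windows with affinity ≥ τ (default 0.5) are hits, on both strands.
Matched backgrounds: `random` (uniform genomic), `adjacent` (flanking),
`CGI` (resampled to the peaks' CpG-island overlap fraction ±5%), `1MM`
(per-peak first-order Markov sequences).

**Pathway association** is the upper hypergeometric tail: with N universe
genes, K in the pathway and n linked to peaks,
p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n), BH-corrected across sets.

## Worked example

```python
from pathlib import Path
from peakatlas import call_peaks, classify_peaks, overlap_significance
from peakatlas.formats import read_reads, read_refgene, read_peaks
from peakatlas.simulate import FixtureSpec, make_fixture

fx = make_fixture(FixtureSpec(seed=7), Path("fx"))
chip = read_reads(fx.chip_bed)
control = read_reads(fx.control_bed)
genes = read_refgene(fx.genes_path)

peaks = call_peaks(chip, control, fx.spec.chrom_sizes)
result = classify_peaks(peaks, genes)
stats = overlap_significance(peaks, read_peaks(fx.mark1_bed), genes,
                             fx.spec.chrom_sizes, n_rand=99, seed=7)
```

Running `examples/01_call_and_annotate.py` and
`examples/02_overlap_significance.py` (which execute exactly this) prints:

```
called 30 peaks from 7599 ChIP reads
  promoter        50.0%
  distal          50.0%
observed overlap: 10 of 30 peaks
empirical p = 0.01 (min possible 1/100)
z = 7.91 null SDs above the random expectation
```

The caller recovers all 30 planted peaks; the 50/50 promoter/distal split
matches how the fixture planted them; and the overlap with the
enhancer-mark file is at the smallest p the 99-replicate null can report,
almost 8 null standard deviations above chance. The other examples cover
motif scanning (recovers the planted 80% embedding rate), pathway
enrichment (the planted set ranks first, p ≈ 0.0012), conservation
profiles (0.80 centre vs 0.13 random), density clustering, and the
distal → mark⁺ → mark⁻ → cofactor⁺ enhancer filter chain.

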