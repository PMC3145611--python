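# Methods

## Coordinate model

All intervals are 0-based, half-open `[start, end)`, BED-native. SAM input
is shifted by −1; fixedStep wiggle is shifted at both ends, as the dialect
is 1-based. Overlap is strict positive-width intersection: abutting
intervals (`a.end == b.start`) do not overlap, everywhere in the package.
Duplicate identical intervals are distinct peaks in every count.

## Interval engine

Per-chromosome augmented binary search trees keyed by interval start; each
node stores the maximum end over its subtree, letting a query prune any
subtree that cannot reach the query start while still reporting *all*
overlapping intervals. Trees built from a peak set are balanced by
median-split of the sorted intervals; incremental inserts are plain BST
inserts with max-end propagation. Correctness is tested against an
exhaustive linear scan and against the independent `intervaltree` package
on randomized instances.

## Peak caller

The caller is a deliberately transparent density thresholder. Reads are
extended to the fragment length L (default 200 bp) in their 3′ direction —
`+` reads rightward from their start, `−` reads leftward from their read
end, strandless reads rightward — and piled into per-base coverage via a
difference array. Bases with coverage ≥ t (default 15) seed candidate
runs; runs separated by < max_gap (200 bp) merge; merged regions shorter
than min_len (100 bp) are dropped. With a control, a region survives only
if the library-size-normalized mean-coverage ratio
(chip_mean/chip_total) / ((ctrl_mean + 1/region_len)/ctrl_total) ≥ fold
(default 2); the pseudocount is one read spread over the region, so empty
control regions never divide by zero. Score = max coverage; summit =
leftmost maximum.

The defaults were chosen once from the coverage arithmetic of the
simulated studies (background rate 0.02 reads/bp × L = mean coverage 4;
P(Poisson(4) ≥ 15) ≈ 4·10⁻⁶ keeps false bases to ~1 per genome, while
10-fold spikes reach coverage ≈ 30). A literal per-base threshold of 5
would admit ~37% of background bases at these settings, which is why the
caller's single-spike tests run at the default t = 15.

## Randomization null for peak overlaps

The null conserves, exactly: the number of peaks, the multiset of peak
lengths per chromosome, and each peak's gene-part category, collapsed to
promoter / exonic / intronic / downstream / intergenic (first intron
counts as intronic; distal and near-gene-no-part both count as
intergenic). The genome is labelled per-base with the same priority used
for classification, runs of same-category bases become that category's
territory, and each randomized peak is placed uniformly over all positions
where it fits wholly inside a run of its category on its own chromosome
(runs weighted by the number of start positions they offer). If no run
fits the peak, placement falls back to requiring only the midpoint inside
the territory, with a warning. The empirical p uses add-one smoothing so
p ∈ (0, 1]; z is undefined (reported as None) when the null has zero
spread. Each significance call derives its replicate seeds from one
`SeedSequence`, and the seed is recorded in the result.

Per-base labelling allocates one byte per genome base per call, which is
the right trade at the scale this package targets (simulated or
region-restricted studies up to tens of megabases); the territory table is
built once per significance call and shared by all replicates.

Calibration, verified in the acceptance suite: with the first list itself
drawn from the null, the fraction of p ≤ 0.05 over 200 replicates at
n_rand = 99 sits inside the binomial 99% band, |mean z| < 0.2 and
sd(z) ∈ [0.8, 1.25].

## Gene-part classification

Candidate labels are gathered against all transcripts; the primary
category is chosen by the fixed priority promoter > exon > first_intron >
intron > downstream > distal > other, so categories partition the peak set
and observed fractions sum to 1 exactly. Definitions:

* promoter — a window of `promoter_window` bp (default 4000) centred on
  the TSS, never extended past the transcript's downstream extremity;
* first intron — the 5′-most intron in transcription order, reported
  separately from other introns;
* downstream — `downstream_window` bp (default 2000) past the TES;
* distal — overlapping no transcript and ≥ `distal_min` bp (default 2000)
  from every transcript, measured as whole-interval gap;
* other — near a gene (< distal_min) but in no part; with the default
  windows this category is empty (the promoter and downstream windows tile
  the 2-kb margins exactly) and only appears under narrower windows.

Distances everywhere are whole-interval gaps (0 when overlapping), which
makes `classify`'s distal category coincide exactly with
`find_distal_peaks` at the same threshold — a tested invariant. Expected
genome fractions use the same priority applied per base, so observed and
expected fractions are directly comparable.

## Motif scanning

Berg–von Hippel weights with pseudocount 0.5:
w(b,i) = ln((n(b,i)+0.5)/(n_max(i)+0.5)) against each column's most
frequent base, so consensus scores exactly 0 and all weights are ≤ 0.
Acceptance is on relative affinity exp(score) ≥ τ, τ ∈ (0,1] defaulting to
0.5; both strands are scanned by default, reverse-strand hits reported at
their leftmost forward-strand base; windows containing N are rejected
rather than penalized. Consensus patterns are compiled as case-insensitive
regular expressions inside a lookahead so overlapping occurrences are all
found, on both the sequence and its reverse complement.

Backgrounds produce one same-length sequence per input peak. `random`
places regions uniformly over the genome (chromosomes weighted by the
positions they offer). `adjacent` alternates left/right flanks to avoid
directional bias, switching sides when a flank would leave the
chromosome. `CGI` redraws whole random batches (up to 1000) until the
batch's CpG-island overlap fraction is within ±0.05 of the input peaks'.
`1MM` generates each background from that peak's own first-order Markov
transition counts, starting from the source's first base and falling back
to the source's mononucleotide pool for contexts never observed — this
makes a homopolymer reproduce itself deterministically, and pooled
dinucleotide frequencies track the input within ±0.02.

## Pathway association

Gene-level counting: a gene with many peaks contributes once. The universe
defaults to all symbols seen in the links and the collection (or the
collection's explicit universe); genes outside it never affect N, K, n or
k. p is `scipy.stats.hypergeom.sf(k−1, N, K, n)`, verified against
exhaustive draw enumeration for all N ≤ 12. The multi-set scan applies BH
step-up q-values via statsmodels; correction can be switched off.

## Conservation and density

Score tracks are sparse per-base runs (fixedStep wiggle or bedGraph).
Missing bases default to 0 (`zero` policy, appropriate for near-complete
phastCons tracks); `skip` excludes them from means. The mean filter is
strictly greater-than. Profiles use windows (default 2000 bp) centred on
the recorded summit (midpoint when absent), in bins (default 10 bp, so 200
bins); windows leaving a chromosome are flagged and excluded from the
group mean. Strand is ignored — conservation is strand-symmetric.

Density matrices average per-base extended-read coverage in bins (default
4 kb / 10 bp = 400 columns) around TSS, TES or summit anchors;
minus-strand rows are flipped so column 0 is 5′-most. RPKM multiplies a
value by 10⁹/(region_bp × total mapped reads), with the bin width as the
region for density matrices and the peak length for read-count matrices,
making values invariant under uniform read duplication.

## Clustering

The self-organizing map is a rectangular grid of prototype vectors:
winners by Euclidean distance, Gaussian neighbourhood updates with radius
decaying linearly from max(grid)/2 to 0.5 and learning rate from 0.5 to
0.01 over 100 epochs, prototypes initialized from jittered random rows of
the seeded RNG — fixed seeds give byte-identical assignments. k-means is
scikit-learn's Lloyd iteration with seeded init; hierarchical clustering
is scipy average linkage cut to k clusters.

## Synthetic studies

The generator emulates: i.i.d. genome composition at configurable GC with
GC-rich planted CpG islands; regularly spaced multi-exon genes of
alternating strand with intergenic gaps wide enough to hold distal
territory; truth peaks split between TSS-centred promoter peaks and peaks
wholly inside distal-labelled territory (defaults: 30 peaks of 400 bp,
half and half, on a 260-kb two-chromosome genome with 18 genes); uniform
Poisson background reads at 0.02 reads/bp plus uniform spike reads at
10-fold the local background inside truth peaks, with the control sharing
the background generator; a conservation track at baseline 0.1 raised to
0.8 over truth peaks; a hard-consensus 10-bp motif written into 80% of
truth peaks; an enhancer-style mark configuration over the distal peaks;
and one planted gene set (the promoter-target symbols) among random
decoys. All outputs are byte-reproducible from the seed, and `truth.json`
records every planted fact.

What it does not emulate — and what passing tests therefore do not
establish about real data: mappability and duplication artifacts,
GC-dependent coverage bias, fragment-size variation, paired-end geometry,
overlapping/nested transcripts, chromatin-state-dependent backgrounds, and
genome-scale memory behaviour. Problem sizes in tests and the acceptance
script (260-kb genomes, thousands of reads, ≤ 200 null replicates at
n_rand = 99) were chosen as the smallest scales at which the statistical
properties under test are non-trivial.

## Known limitations

* The randomization territory model labels whole genomes per base;
  suitable for region-scale analyses, not a compressed representation for
  full mammalian genomes.
* BED and SAM are the supported read formats (BAM and legacy eland/export
  dialects are not parsed); BigWig tracks are not read or written.
* De-novo motif discovery is out of scope: enrichment of known motifs
  against matched backgrounds covers the supervised use case.
* The peak caller has no local-background FDR model; it is a transparent
  thresholder intended for well-behaved or simulated data.
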