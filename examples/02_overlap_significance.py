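"""Test whether two peak lists overlap more than chance expects.

Compares the planted truth peaks against the enhancer-mark peak file
from the same fixture. The null model re-places the first list 99 times,
conserving peak count, lengths and gene-part distribution; the p-value
counts null overlaps reaching the observed one, and the z-score is the
observed overlap's distance from the null mean in null SDs. A Jaccard
matrix summarises pairwise similarity of several peak files.
"""

import tempfile
from pathlib import Path

from peakatlas import jaccard_index, overlap_significance
from peakatlas.formats import read_peaks, read_refgene
from peakatlas.simulate import FixtureSpec, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture(FixtureSpec(seed=7), Path(tmp))
    genes = read_refgene(fx.genes_path)
    mark1 = read_peaks(fx.mark1_bed)

    stats = overlap_significance(
        fx.truth_peaks, mark1, genes, fx.spec.chrom_sizes, n_rand=99, seed=7
    )
    print(f"observed overlap: {stats.observed} of {len(fx.truth_peaks)} peaks")
    print(f"empirical p = {stats.p_value:.3g} (min possible 1/100)")
    print(f"z = {stats.z_score:.2f} null SDs above the random expectation")

    sets = [read_peaks(p) for p in (fx.mark1_bed, fx.mark2_bed, fx.cofactor_bed)]
    res = jaccard_index(sets, labels=["mark1", "mark2", "cofactor"])
    print("\nJaccard similarity (overlap components / union components):")
    for lab, row in zip(res.labels, res.matrix):
        print(f"  {lab:<9}" + " ".join(f"{v:5.2f}" for v in row))
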