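"""Call peaks from ChIP reads and classify them into gene parts.

Generates a small synthetic study (genome, genes, spiked reads), calls
peaks with the read-density caller, and annotates each peak as promoter,
exonic, intronic, downstream or distal. The printed fractions show where
the factor binds: here the truth peaks were planted half at promoters
and half in intergenic territory, so the caller + annotator should
recover roughly a 50/50 split.
"""

import tempfile
from pathlib import Path

from peakatlas import call_peaks, classify_peaks
from peakatlas.formats import read_reads, read_refgene
from peakatlas.simulate import FixtureSpec, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture(FixtureSpec(seed=7), Path(tmp))
    chip = read_reads(fx.chip_bed)
    control = read_reads(fx.control_bed)
    genes = read_refgene(fx.genes_path)

    peaks = call_peaks(chip, control, fx.spec.chrom_sizes)
    print(f"called {len(peaks)} peaks from {chip.total_reads} ChIP reads")

    result = classify_peaks(peaks, genes)
    for category, fraction in result.observed_fractions.items():
        if fraction:
            print(f"  {category:<14} {fraction:6.1%}")
    print("fractions are per-peak primary categories and sum to 1")
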