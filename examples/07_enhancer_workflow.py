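"""Chain peak-list filters to nominate putative enhancers.

Starting from distal (intergenic) peaks, keep those carrying the
enhancer-associated mark, drop those carrying the promoter-associated
mark, and keep those bound by the co-activator. Every step consumes and
emits a plain peak list, so the chain is just three compare operations;
the fixture's truth manifest verifies the survivors.
"""

import tempfile
from pathlib import Path

from peakatlas import compare_intervals, find_distal_peaks
from peakatlas.formats import read_peaks, read_refgene
from peakatlas.simulate import FixtureSpec, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture(FixtureSpec(seed=7), Path(tmp))
    genes = read_refgene(fx.genes_path)

    distal = find_distal_peaks(fx.truth_peaks, genes, 2000)
    print(f"distal peaks (>= 2 kb from any gene): {len(distal)}")

    step = compare_intervals(distal, read_peaks(fx.mark1_bed), "overlap")
    print(f"  with the enhancer mark:             {len(step)}")
    step = compare_intervals(step, read_peaks(fx.mark2_bed), "unique")
    print(f"  without the promoter mark:          {len(step)}")
    step = compare_intervals(step, read_peaks(fx.cofactor_bed), "overlap")
    print(f"  bound by the co-activator:          {len(step)}")

    truth = set(fx.truth["enhancer_ids"])
    got = {iv.id for iv in step}
    print(f"matches the planted enhancer set: {got == truth}")
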