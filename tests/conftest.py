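import warnings

import pytest

from peakatlas.formats import (
    read_chrom_sizes,
    read_gmt,
    read_peaks,
    read_pfm,
    read_reads,
    read_refgene,
    read_score_track,
)
from peakatlas.simulate import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    """One synthetic study shared by the whole session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(FixtureSpec(seed=1), outdir)


@pytest.fixture(scope="session")
def genes(fixture):
    return read_refgene(fixture.genes_path)


@pytest.fixture(scope="session")
def chrom_sizes(fixture):
    return read_chrom_sizes(fixture.chrom_sizes_path)


@pytest.fixture(scope="session")
def chip_reads(fixture):
    return read_reads(fixture.chip_bed)


@pytest.fixture(scope="session")
def control_reads(fixture):
    return read_reads(fixture.control_bed)


@pytest.fixture(scope="session")
def cons_track(fixture):
    return read_score_track(fixture.cons_wig)


@pytest.fixture(scope="session")
def truth_pwm(fixture):
    return read_pfm(fixture.motifs_pfm)[0]


@pytest.fixture(scope="session")
def gene_sets(fixture):
    return read_gmt(fixture.genesets_gmt)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
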