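import pytest

from phaswindow import (ScanParams, SimConfig, call_regions, collapse,
                        filter_for_phasing, filter_length, scan, simulate)
from phaswindow.sam_io import MappedRead


def mk_read(chrom="Chr01", start=100, length=21, strand="+", sample="s1",
            count=1, n_hits=1, sequence=None):
    return MappedRead(chrom=chrom, start=start, length=length, strand=strand,
                      sequence=sequence, sample=sample, count=count,
                      n_hits=n_hits)


@pytest.fixture(scope="session")
def sim7():
    """The default 20-locus simulation used throughout."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def phasing_set7(sim7):
    return filter_for_phasing(filter_length(collapse(iter(sim7.reads))))


@pytest.fixture(scope="session")
def regions7(phasing_set7):
    hits = scan(phasing_set7)
    return call_regions(hits, phasing_set7)


@pytest.fixture(scope="session")
def sim_outputs7(sim7, tmp_path_factory):
    from phaswindow import write_outputs
    d = tmp_path_factory.mktemp("sim7")
    return write_outputs(sim7, d)
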