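import pytest

from evcfkit.evcf_builder import ConfidencePolicy
from evcfkit.site_catalog import SiteRecord
from evcfkit.synthetic_data import SimulationConfig, simulate_dataset

GVCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\t.\tA\t.\t.\tPASS\tEND=199\tGT:GQX:DP:MIN_DP\t0/0:50:32:30
chr1\t200\t.\tC\t.\t.\tPASS\tEND=1400\tGT:GQX:DP:MIN_DP\t0/0:61:40:35
chr1\t1500\trs1\tA\tG\t120\tPASS\t.\tGT:GQX\t0/1:110
chr1\t1501\t.\tG\t.\t.\tPASS\tEND=2000\tGT:GQX:DP:MIN_DP\t0/0:45:30:25
chr1\t2500\t.\tT\t.\t.\tLowGQX\tEND=2600\tGT:GQX:DP:MIN_DP\t0/0:8:6:4
"""


@pytest.fixture
def gvcf_lines() -> list[str]:
    return GVCF_FIXTURE.splitlines()


@pytest.fixture
def default_policy() -> ConfidencePolicy:
    return ConfidencePolicy()


def make_site(pos, ref="A", alts=("G",), contig="chr1", rsid=None, freqs=()):
    return SiteRecord(
        contig=contig, pos=pos, ref=ref, alts=tuple(alts), rsid=rsid,
        alt_freqs=tuple(freqs),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 20 kb genome with 200 catalog sites and a 10% no-call mask."""
    return simulate_dataset(
        SimulationConfig(genome_length=20_000, n_sites=200, nocall_fraction=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: no no-call mask, no array errors."""
    return simulate_dataset(
        SimulationConfig(genome_length=20_000, n_sites=200, seed=11)
    )
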