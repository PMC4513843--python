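import pytest

from cleaveseq import builtin_designs, load_library_design
from cleaveseq.designs import DEFAULT_T7_PROMOTER

BARCODES = {"minus": "ATCACG", "plus": "CGATGT"}
ADAPTER_T = "ACACGACGCTCTTCCGATCT"
ADAPTER_B = "AGATCGGAAGAGCACACGTC"

# arbitrary valid toy scaffold: 10-nt 5' leader, constant core, k Ns, constant tail
_LEADER = "GGGACGTACG"
_CORE = "TTAGCC"
_TAIL = "ACGGATCCGTAGCAATTGCAGGTACGATT"


def make_toy_design(k=2, name=None, cleavage_site=10):
    template = DEFAULT_T7_PROMOTER + _LEADER + _CORE + "N" * k + _TAIL
    return load_library_design(
        {
            "name": name or f"toy{k}",
            "dna_template": template,
            "cleavage_site": cleavage_site,
            "barcodes": BARCODES,
            "adapter_t": ADAPTER_T,
            "adapter_b": ADAPTER_B,
        }
    )


@pytest.fixture(scope="session")
def toy2():
    return make_toy_design(k=2)


@pytest.fixture(scope="session")
def toy4():
    return make_toy_design(k=4)


@pytest.fixture(scope="session")
def fixtures():
    return builtin_designs()
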