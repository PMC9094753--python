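import pytest

from qtrna import (
    TRNAScaffold,
    enumerate_library,
    make_toy_scaffold,
)


@pytest.fixture(scope="session")
def ser_scaffold() -> TRNAScaffold:
    """Serine scaffold (anticodon CGA, decodes TCG), the workhorse example."""
    return make_toy_scaffold("Ser", "CGA")


@pytest.fixture(scope="session")
def tiny_scaffold() -> TRNAScaffold:
    """Hand-built 20-nt scaffold for splice-by-hand checks."""
    return TRNAScaffold(
        id="tiny",
        amino_acid="Ser",
        sequence="ACGUACGU" + "CGA" + "UUACGUACG",
        anticodon_start=8,
        pos32_index=6,
    )


@pytest.fixture(scope="session")
def loopside_library(ser_scaffold):
    """64-member loop-side library of qtRNA-Ser-TAGA."""
    return enumerate_library(ser_scaffold, "loopsides", codon="TAGA")
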