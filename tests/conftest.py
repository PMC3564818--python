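import pytest

from scdscan.seqio import ProteinRecord, Proteome
from scdscan.synthdata import SynthConfig, generate_proteome


@pytest.fixture
def tiny_proteome() -> Proteome:
    return Proteome(
        [
            ProteinRecord("P1", "has one SCD", "MSQAASQAATQGGAAAAAAA"),
            ProteinRecord("P2", "no motifs", "MAAAAAAAAKLVVVVE"),
            ProteinRecord("P3", "single motif", "MMMMSQMMMM"),
        ],
        source_label="tiny",
    )


@pytest.fixture(scope="session")
def synthetic_proteome():
    """Medium synthetic proteome with planted SCDs, shared across tests."""
    config = SynthConfig(n_proteins=300, planted_scds=((3, 50, 20),), seed=11)
    proteome, truth = generate_proteome(config)
    return proteome, truth, config
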