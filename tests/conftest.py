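import pandas as pd
import pytest

from betrewire.tables_io import ProteinSeq


@pytest.fixture
def h4_tail() -> str:
    # Histone H4 N-terminal tail (residues 1-20)
    return "SGRGKGGKGLGKGGAKRHRK"


@pytest.fixture
def interaction_fixture(tmp_path):
    """3-row interaction table: BRD3/TCOF1 at 0 and 60 min, two replicates."""
    path = tmp_path / "interactions.tsv"
    df = pd.DataFrame(
        {
            "bait": ["BRD3", "BRD3", "BRD3"],
            "prey": ["TCOF1", "TCOF1", "TCOF1"],
            "timepoint": [0, 60, 60],
            "replicate": ["rep1", "rep1", "rep2"],
            "spectral_count": [0, 218, 218],
            "fdr": [0.001, 0.001, 0.001],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path, df


@pytest.fixture
def tiny_proteome() -> list[ProteinSeq]:
    return [
        ProteinSeq("P1", "first", "MKAYKGGKLL"),
        ProteinSeq("P2", "second", "AAKYSKAAKGAK"),
    ]
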