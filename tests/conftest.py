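"""Shared fixtures: small FASTA files and worked-example species."""

import pytest

from halolan.catalog import SequenceRecord
from halolan.synthetic import example_species


@pytest.fixture
def sallan_a2():
    """Smallest natural lanthipeptide: CTRYSF with a Cys1-Ser5 ring."""
    return example_species("sallan_A2")


@pytest.fixture
def larlan_a2():
    """Two-chain (DADC) species: three MeLan rings, one internal scission."""
    return example_species("larlan_A2")


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">a1\nMCTRYSF\n>a2\nmctrysf\n>a3\nAACTRS\n")
    return path


def records(*seqs, label="test"):
    return [SequenceRecord(id=f"r{i}", sequence=s, set_label=label)
            for i, s in enumerate(seqs)]
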