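import numpy as np
import pytest

from ssipred.io_formats import Chain, ResidueRecord


MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.500   1.250   0.000  1.00  0.00           C
ATOM      4  CA  TRP A   3       8.000   0.000   2.000  1.00  0.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


def make_chain(coords, chain_id="A", aas=None, asa=None):
    """Helper: build a chain from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, xyz in enumerate(coords):
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_index=i + 1,
                aa=(aas[i] if aas else "A"),
                ca_xyz=xyz,
                asa=(asa[i] if asa is not None else None),
            )
        )
    return Chain(chain_id, residues)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
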