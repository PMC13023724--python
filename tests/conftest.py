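import numpy as np
import pytest

from shiftassign import LikelihoodMatrix
from shiftassign.model import MoleculeGraph


def likelihood_from_linear(M):
    """Wrap a linear-domain matrix as a LikelihoodMatrix (log domain)."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    with np.errstate(divide="ignore"):
        logm = np.log(M)
    return LikelihoodMatrix(
        log_L=logm,
        item_ids=[f"i{k}" for k in range(n)],
        peak_ids=[f"p{k}" for k in range(n)],
    )


@pytest.fixture
def methane():
    return MoleculeGraph(
        atoms=[("C1", "C"), ("H1", "H"), ("H2", "H"), ("H3", "H"), ("H4", "H")],
        bonds=[("C1", "H1", 1), ("C1", "H2", 1), ("C1", "H3", 1), ("C1", "H4", 1)],
    )


@pytest.fixture
def ethanol():
    return MoleculeGraph(
        atoms=[("C1", "C"), ("C2", "C"), ("O1", "O"),
               ("H1", "H"), ("H2", "H"), ("H3", "H"),
               ("H4", "H"), ("H5", "H"), ("H6", "H")],
        bonds=[("C1", "C2", 1), ("C2", "O1", 1), ("O1", "H6", 1),
               ("C1", "H1", 1), ("C1", "H2", 1), ("C1", "H3", 1),
               ("C2", "H4", 1), ("C2", "H5", 1)],
    )


@pytest.fixture
def halo_molecule():
    """Three carbons with mutually distinct environments: one CH bearing F2,
    one CH bridging, one quaternary CF3 — every motif matches only itself."""
    return MoleculeGraph(
        atoms=[("C1", "C"), ("C2", "C"), ("C3", "C"),
               ("H1", "H"), ("H2", "H"),
               ("F1", "F"), ("F2", "F"), ("F3", "F"), ("F4", "F"), ("F5", "F"),
               ("Cl1", "Cl")],
        bonds=[("C1", "C2", 1), ("C2", "C3", 1),
               ("C1", "H1", 1), ("C1", "F1", 1), ("C1", "F2", 1),
               ("C2", "H2", 1), ("C2", "Cl1", 1),
               ("C3", "F3", 1), ("C3", "F4", 1), ("C3", "F5", 1)],
    )


ETHANE_MOLBLOCK = """ethane
  test

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5000    0.9000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5000   -0.4500    0.8000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5000   -0.4500   -0.8000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.0400    0.9000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.0400   -0.4500    0.8000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.0400   -0.4500   -0.8000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
  2  7  1  0
  2  8  1  0
M  END
"""


@pytest.fixture
def ethane_molfile(tmp_path):
    path = tmp_path / "ethane.mol"
    path.write_text(ETHANE_MOLBLOCK)
    return path
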