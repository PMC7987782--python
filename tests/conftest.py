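import numpy as np
import pytest

from psndelta import (
    ChainModel,
    NormalizationTable,
    PSNGraph,
    default_normalization_table,
    make_chain,
)
from psndelta.synthetic_data import random_sequence

HANDCRAFTED_PDB = """\
HEADER    TEST                                    01-JAN-20   1ABC
REMARK   2 RESOLUTION.    2.50 ANGSTROMS.
REMARK   3   R VALUE            (WORKING SET) : 0.210
REMARK   3   FREE R VALUE                     : 0.250
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       1.900  -0.800  -1.200  1.00 10.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.100  1.00 10.00           N
ATOM      7  CA  GLY A   2       4.000   2.700   0.300  1.00 10.00           C
ATOM      8  C   GLY A   2       5.400   2.500   0.800  1.00 10.00           C
ATOM      9  O   GLY A   2       6.000   1.500   0.500  1.00 10.00           O
ATOM     10  N   SER A   3       6.000   3.600   1.200  1.00 10.00           N
ATOM     11  CA  SER A   3       7.400   3.600   1.700  1.00 10.00           C
ATOM     12  OG  SER A   3       8.000   4.900   1.500  1.00 10.00           O
TER
END
"""


@pytest.fixture(scope="session")
def norm_table() -> NormalizationTable:
    return default_normalization_table()


@pytest.fixture(scope="session")
def varied_chain() -> ChainModel:
    """A 30-residue helix with a varied sequence."""
    return make_chain(30, random_sequence(30, 11), seed=11)


@pytest.fixture
def handcrafted_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(HANDCRAFTED_PDB)
    return path


def graph_from_edges(n: int, edges: dict[tuple[int, int], float],
                     hub_threshold: int = 11) -> PSNGraph:
    """Small handmade PSN from an edge→weight dict."""
    adj = np.zeros((n, n))
    for (i, j), w in edges.items():
        adj[i, j] = adj[j, i] = w
    return PSNGraph(
        node_ids=[f"A:{k + 1}" for k in range(n)],
        node_types=["ALA"] * n,
        adjacency=adj,
        hub_threshold=hub_threshold,
    )


def random_psn_pair(n: int, rng: np.random.Generator, density: float = 0.4):
    """Two random weighted graphs on one node set, each with ≥ 1 edge."""
    def one():
        while True:
            mask = np.triu(rng.random((n, n)) < density, k=1)
            if mask.any():
                break
        w = np.triu(rng.uniform(0.05, 1.0, (n, n)), k=1) * mask
        adj = w + w.T
        return PSNGraph(
            node_ids=[f"A:{k + 1}" for k in range(n)],
            node_types=["ALA"] * n,
            adjacency=adj,
        )
    return one(), one()
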