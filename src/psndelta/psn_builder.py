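"""Weighted all-atom protein structure network construction.

Two residues are in contact when any pair of their heavy atoms lies within a
distance cutoff (default 4.5 Å) and the residues are non-adjacent in sequence
(separation ≥ 2).  The edge weight between residues i and j is

    I_ij = (number of atom contacts between i and j)
           / (highest atom-contact count ever observed between the
              amino-acid types of i and j)

so weights lie in (0, 1] relative to a normalization table derived from a
reference structure set.  A node is a *hub* when its degree (number of
incident edges) reaches a threshold, 11 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import ChainModel, STANDARD_AA3

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.5
DEFAULT_MIN_SEQ_SEPARATION = 2
DEFAULT_HUB_THRESHOLD = 11


@dataclass(frozen=True)
class ContactRecord:
    """Atom-contact count between two non-adjacent residues of one chain."""

    index_a: int          # sequence_index of the lower residue
    index_b: int
    type_a: str           # three-letter codes
    type_b: str
    atom_pair_count: int

    def __post_init__(self):
        if self.index_a == self.index_b:
            raise ValueError("contact requires two distinct residues")
        if self.atom_pair_count < 1:
            raise ValueError("stored contacts must have at least one atom pair")


class NormalizationTable:
    """Symmetric amino-acid-pair maxima of atom-contact counts.

    Keys are unordered pairs of three-letter codes; values are the highest
    atom-contact count observed for that pair in the reference structure set.
    Lookups of pairs never observed raise ``KeyError``.
    """

    def __init__(self, values: dict[tuple[str, str], int], provenance: str = ""):
        self._values: dict[tuple[str, str], int] = {}
        for (a, b), v in values.items():
            if v < 1:
                raise ValueError(f"normalization value for ({a},{b}) must be ≥ 1")
            self._values[self._key(a, b)] = int(v)
        self.provenance = provenance

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> int:
        key = self._key(a, b)
        if key not in self._values:
            raise KeyError(
                f"no normalization value for residue-type pair {key[0]}–{key[1]}; "
                "extend the reference set or supply a table covering this pair"
            )
        return self._values[key]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._values

    def __len__(self) -> int:
        return len(self._values)

    def items(self):
        return self._values.items()

    def covers_all_standard_pairs(self) -> bool:
        aas = STANDARD_AA3
        return all(
            self._key(a, b) in self._values
            for i, a in enumerate(aas) for b in aas[i:]
        )

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """20×20 matrix with 3-letter labels; blank cells for absent pairs."""
        mat = pd.DataFrame(index=list(STANDARD_AA3), columns=list(STANDARD_AA3), dtype="Int64")
        for (a, b), v in self._values.items():
            mat.loc[a, b] = v
            mat.loc[b, a] = v
        mat.to_csv(path, sep="\t", index_label="aa")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "NormalizationTable":
        mat = pd.read_csv(path, sep="\t", index_col=0)
        values: dict[tuple[str, str], int] = {}
        for a in mat.index:
            for b in mat.columns:
                v = mat.loc[a, b]
                if pd.notna(v):
                    key = cls._key(str(a), str(b))
                    prev = values.get(key)
                    if prev is not None and prev != int(v):
                        raise ValueError(f"asymmetric table: {key} has {prev} and {int(v)}")
                    values[key] = int(v)
        return cls(values, provenance=provenance or f"loaded from {path}")


@dataclass
class PSNGraph:
    """Weighted undirected residue network of one chain (or common-node subset).

    ``adjacency`` is symmetric with zero diagonal; stored weights are in
    (0, 1].  ``node_ids`` are residue labels in node order; ``node_types``
    the three-letter codes.  ``source_indices`` records each node's
    sequence_index in the originating chain (identity for full-chain graphs,
    the mapped indices after restriction to a common node set).
    """

    node_ids: list[str]
    node_types: list[str]
    adjacency: np.ndarray
    hub_threshold: int = DEFAULT_HUB_THRESHOLD
    atom_pair_counts: np.ndarray | None = None
    source_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, float)
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(self.adjacency < 0) or np.any(self.adjacency > 1.0 + 1e-12):
            raise ValueError("edge weights must lie in (0, 1]")
        if not self.source_indices:
            self.source_indices = list(range(n))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degree(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    @property
    def strength(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def hubs(self) -> np.ndarray:
        """Boolean per-node hub flags: degree ≥ hub_threshold."""
        return self.degree >= self.hub_threshold

    def edge_set(self) -> set[tuple[int, int]]:
        """Edges as sorted node-index pairs."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))

    @property
    def n_edges(self) -> int:
        return len(self.edge_set())

    def total_edge_weight(self) -> float:
        """Sum of weights, each undirected edge counted once."""
        return float(np.triu(self.adjacency, k=1).sum())

    # -- export ------------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for k, (nid, typ) in enumerate(zip(self.node_ids, self.node_types)):
            g.add_node(nid, residue_type=typ, index=k)
        for i, j in self.edge_set():
            attrs = {"weight": float(self.adjacency[i, j])}
            if self.atom_pair_counts is not None:
                attrs["atom_pair_count"] = int(self.atom_pair_counts[i, j])
            g.add_edge(self.node_ids[i], self.node_ids[j], **attrs)
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i, j in sorted(self.edge_set()):
            rows.append(
                {
                    "node_a": self.node_ids[i],
                    "node_b": self.node_ids[j],
                    "atom_pair_count": (
                        int(self.atom_pair_counts[i, j])
                        if self.atom_pair_counts is not None else None
                    ),
                    "weight": float(self.adjacency[i, j]),
                }
            )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "atom_pair_count", "weight"])


# ---------------------------------------------------------------------------
# operations


def find_atom_contacts(
    chain: ChainModel,
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
) -> list[ContactRecord]:
    """Count heavy-atom pairs within ``cutoff`` for every non-adjacent residue pair.

    Uses a k-d tree; the result is exactly the all-pairs computation with a
    closed boundary (distance ≤ cutoff).  Residue pairs with sequence-index
    separation < ``min_seq_separation`` are excluded.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    coords, res_idx = chain.heavy_atom_table()
    if coords.size == 0:
        return []
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        ra, rb = int(res_idx[a]), int(res_idx[b])
        if ra == rb:
            continue
        if abs(ra - rb) < min_seq_separation:
            continue
        key = (ra, rb) if ra < rb else (rb, ra)
        counts[key] = counts.get(key, 0) + 1
    out = []
    for (ra, rb), c in sorted(counts.items()):
        out.append(
            ContactRecord(
                index_a=ra,
                index_b=rb,
                type_a=chain.residues[ra].name3,
                type_b=chain.residues[rb].name3,
                atom_pair_count=c,
            )
        )
    return out


def derive_normalization(
    chains: Sequence[ChainModel],
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
    provenance: str | None = None,
) -> NormalizationTable:
    """Pool contacts over a reference chain set; keep the per-type-pair maximum."""
    if not chains:
        raise ValueError("derive_normalization requires at least one chain")
    values: dict[tuple[str, str], int] = {}
    for chain in chains:
        for rec in find_atom_contacts(chain, cutoff, min_seq_separation):
            key = NormalizationTable._key(rec.type_a, rec.type_b)
            if rec.atom_pair_count > values.get(key, 0):
                values[key] = rec.atom_pair_count
    return NormalizationTable(
        values,
        provenance=provenance
        or f"max over {len(chains)} chains, cutoff {cutoff} Å, separation ≥ {min_seq_separation}",
    )


def build_psn(
    chain: ChainModel,
    norm: NormalizationTable,
    cutoff: float = DEFAULT_CUTOFF,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
) -> PSNGraph:
    """Build the weighted PSN of a chain against a normalization table.

    Every residue is a node, contact-less residues included as isolated nodes.
    A weight ratio exceeding 1 (possible only with a foreign table) is clamped
    to 1.0 with a warning.
    """
    n = len(chain)
    adjacency = np.zeros((n, n))
    counts = np.zeros((n, n), int)
    for rec in find_atom_contacts(chain, cutoff, min_seq_separation):
        denom = norm.get(rec.type_a, rec.type_b)  # KeyError names the pair
        w = rec.atom_pair_count / denom
        if w > 1.0:
            logger.warning(
                "contact count %d for %s–%s exceeds table maximum %d; weight clamped to 1",
                rec.atom_pair_count, rec.type_a, rec.type_b, denom,
            )
            w = 1.0
        adjacency[rec.index_a, rec.index_b] = adjacency[rec.index_b, rec.index_a] = w
        counts[rec.index_a, rec.index_b] = counts[rec.index_b, rec.index_a] = rec.atom_pair_count
    return PSNGraph(
        node_ids=[r.label for r in chain.residues],
        node_types=[r.name3 for r in chain.residues],
        adjacency=adjacency,
        hub_threshold=hub_threshold,
        atom_pair_counts=counts,
    )


def node_metrics(psn: PSNGraph) -> pd.DataFrame:
    """Per-node table of degree, strength and hub flag, in node order."""
    return pd.DataFrame(
        {
            "node": psn.node_ids,
            "residue_type": psn.node_types,
            "degree": psn.degree,
            "strength": psn.strength,
            "is_hub": psn.hubs,
        }
    )
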