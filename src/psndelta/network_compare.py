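"""Wildtype/mutant PSN comparison on the common (topologically equivalent) node set.

Both networks are restricted to the residue pairs of a :class:`ResidueMapping`
so they share one node set; edges and hubs are then partitioned into
*retained* (present in both), *lost* (unique to the wildtype) and *gained*
(unique to the mutant).  Edge identity is presence of the node pair — a weight
change on a retained edge does not move it between classes; those changes are
reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import ResidueMapping
from .psn_builder import PSNGraph
from .structure_io import ExposureProfile

logger = logging.getLogger(__name__)


@dataclass
class EdgePartition:
    """Edge sets (as sorted common-node index pairs) by retention class."""

    retained: set[tuple[int, int]]
    lost: set[tuple[int, int]]
    gained: set[tuple[int, int]]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)


@dataclass
class HubPartition:
    """Hub node sets (common-node indices) by retention class."""

    retained: set[int]
    lost: set[int]
    gained: set[int]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)


def restrict_common(
    psn_wt: PSNGraph, psn_mut: PSNGraph, mapping: ResidueMapping
) -> tuple[PSNGraph, PSNGraph]:
    """Induce both PSNs on the mapped node pairs, in mapping order.

    Node k of each returned graph corresponds to mapping pair k; labels carry
    both original residue identities (``wt_label|mut_label``).  Edges between
    unmapped residues vanish with them.
    """
    idx_wt = [a for a, _ in mapping.pairs]
    idx_mut = [b for _, b in mapping.pairs]
    for name, idx, psn in (("wildtype", idx_wt, psn_wt), ("mutant", idx_mut, psn_mut)):
        bad = [i for i in idx if i < 0 or i >= psn.n_nodes]
        if bad:
            raise ValueError(f"mapped residue index {bad[0]} missing from {name} PSN")
    if psn_wt.hub_threshold != psn_mut.hub_threshold:
        raise ValueError("PSNs must share hub_threshold for comparison")

    labels = [
        f"{psn_wt.node_ids[a]}|{psn_mut.node_ids[b]}" for a, b in mapping.pairs
    ]

    def induce(psn: PSNGraph, idx: list[int]) -> PSNGraph:
        sel = np.asarray(idx, int)
        return PSNGraph(
            node_ids=labels,
            node_types=[psn.node_types[i] for i in idx],
            adjacency=psn.adjacency[np.ix_(sel, sel)],
            hub_threshold=psn.hub_threshold,
            atom_pair_counts=(
                psn.atom_pair_counts[np.ix_(sel, sel)]
                if psn.atom_pair_counts is not None else None
            ),
            source_indices=list(idx),
        )

    return induce(psn_wt, idx_wt), induce(psn_mut, idx_mut)


def _check_common(psn_wt: PSNGraph, psn_mut: PSNGraph) -> None:
    if psn_wt.n_nodes != psn_mut.n_nodes or psn_wt.node_ids != psn_mut.node_ids:
        raise ValueError("graphs must be restricted to a common node set first")


def partition_edges(psn_wt: PSNGraph, psn_mut: PSNGraph) -> EdgePartition:
    """Partition edges into retained / lost (wildtype-only) / gained (mutant-only)."""
    _check_common(psn_wt, psn_mut)
    e_wt, e_mut = psn_wt.edge_set(), psn_mut.edge_set()
    return EdgePartition(
        retained=e_wt & e_mut,
        lost=e_wt - e_mut,
        gained=e_mut - e_wt,
    )


def partition_hubs(psn_wt: PSNGraph, psn_mut: PSNGraph) -> HubPartition:
    """Partition hub nodes (degree ≥ threshold on the restricted graphs)."""
    _check_common(psn_wt, psn_mut)
    if psn_wt.hub_threshold != psn_mut.hub_threshold:
        raise ValueError("hub thresholds differ between the two graphs")
    h_wt = set(np.flatnonzero(psn_wt.hubs).tolist())
    h_mut = set(np.flatnonzero(psn_mut.hubs).tolist())
    return HubPartition(
        retained=h_wt & h_mut,
        lost=h_wt - h_mut,
        gained=h_mut - h_wt,
    )


def retained_edge_weight_changes(
    psn_wt: PSNGraph, psn_mut: PSNGraph, partition: EdgePartition | None = None
) -> pd.DataFrame:
    """Per-edge weight deltas on retained edges (presence unchanged, weight may move)."""
    _check_common(psn_wt, psn_mut)
    if partition is None:
        partition = partition_edges(psn_wt, psn_mut)
    rows = []
    for i, j in sorted(partition.retained):
        rows.append(
            {
                "node_a": psn_wt.node_ids[i],
                "node_b": psn_wt.node_ids[j],
                "weight_wt": float(psn_wt.adjacency[i, j]),
                "weight_mut": float(psn_mut.adjacency[i, j]),
                "dweight": float(psn_mut.adjacency[i, j] - psn_wt.adjacency[i, j]),
            }
        )
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "weight_wt", "weight_mut", "dweight"]
    )


def site_deltas(
    psn_wt: PSNGraph,
    psn_mut: PSNGraph,
    exposure_wt: ExposureProfile | None = None,
    exposure_mut: ExposureProfile | None = None,
    sites: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-node degree/strength (and optionally exposure) changes.

    ``sites`` maps a residue label (either side of the unified
    ``wt_label|mut_label`` node id, e.g. ``"A:304"``) to a role
    (``mutation_site`` / ``functional_site``); unmatched nodes get role
    ``other``.  Exposure columns are looked up through each restricted
    graph's ``source_indices`` into the full-chain exposure profiles.
    Sites that resolve to no common node are warned about and appended as
    rows with absent values.
    """
    _check_common(psn_wt, psn_mut)
    sites = sites or {}
    deg_wt, deg_mut = psn_wt.degree, psn_mut.degree
    str_wt, str_mut = psn_wt.strength, psn_mut.strength

    role_by_node: dict[int, str] = {}
    matched_sites: set[str] = set()
    for k, nid in enumerate(psn_wt.node_ids):
        halves = nid.split("|")
        for site_label, role in sites.items():
            if site_label in halves or site_label == nid:
                role_by_node[k] = role
                matched_sites.add(site_label)

    rows = []
    for k, nid in enumerate(psn_wt.node_ids):
        row = {
            "site": nid,
            "role": role_by_node.get(k, "other"),
            "degree_wt": int(deg_wt[k]),
            "degree_mut": int(deg_mut[k]),
            "ddegree": int(deg_mut[k] - deg_wt[k]),
            "strength_wt": float(str_wt[k]),
            "strength_mut": float(str_mut[k]),
            "dstrength": float(str_mut[k] - str_wt[k]),
            "exposure_wt": None,
            "exposure_mut": None,
        }
        if exposure_wt is not None:
            row["exposure_wt"] = exposure_wt.classes[psn_wt.source_indices[k]]
        if exposure_mut is not None:
            row["exposure_mut"] = exposure_mut.classes[psn_mut.source_indices[k]]
        rows.append(row)

    for site_label, role in sites.items():
        if site_label not in matched_sites:
            logger.warning("site %s (%s) not in the common node set", site_label, role)
            rows.append(
                {
                    "site": site_label, "role": role,
                    "degree_wt": None, "degree_mut": None, "ddegree": None,
                    "strength_wt": None, "strength_mut": None, "dstrength": None,
                    "exposure_wt": None, "exposure_mut": None,
                }
            )
    return pd.DataFrame(rows)


def site_delta_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Min/max degree change by role, over nodes with resolved values."""
    ok = deltas.dropna(subset=["ddegree"])
    return (
        ok.groupby("role")["ddegree"]
        .agg(["min", "max", "count"])
        .rename(columns={"min": "ddegree_min", "max": "ddegree_max", "count": "n_sites"})
        .reset_index()
    )
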