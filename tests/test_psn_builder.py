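import itertools
import logging

import numpy as np
import pytest

from psndelta import (
    NormalizationTable,
    build_psn,
    derive_normalization,
    find_atom_contacts,
    make_chain,
    node_metrics,
)
from psndelta.psn_builder import PSNGraph
from psndelta.structure_io import AtomRecord, ChainModel, ResidueUnit
from psndelta.synthetic_data import random_sequence

from conftest import graph_from_edges


def _point_residue(seq_number, name3, *positions):
    atoms = [AtomRecord("CA", "C", positions[0])]
    atoms += [AtomRecord(f"C{k}", "C", p) for k, p in enumerate(positions[1:])]
    return ResidueUnit("A", seq_number, "", name3, atoms)


def brute_force_contacts(chain, cutoff=4.5, min_sep=2):
    """O(N²) double loop over all heavy-atom pairs — the contact oracle."""
    counts = {}
    res = chain.residues
    for i, j in itertools.combinations(range(len(res)), 2):
        if j - i < min_sep:
            continue
        c = sum(
            1
            for a in res[i].heavy_atoms
            for b in res[j].heavy_atoms
            if np.linalg.norm(a.position - b.position) <= cutoff
        )
        if c:
            counts[(i, j)] = c
    return counts


class TestFindAtomContacts:
    def test_single_pair_under_cutoff(self):
        chain = ChainModel("X", "A", [
            _point_residue(1, "ALA", np.array([0.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([0.0, 0.0, 100.0])),
            _point_residue(3, "ALA", np.array([4.4 / np.sqrt(2), 4.4 / np.sqrt(2), 0.0])),
        ])
        recs = find_atom_contacts(chain)
        # residues 1 and 3: one heavy atom each, 4.4 Å apart
        assert len(recs) == 1
        assert (recs[0].index_a, recs[0].index_b) == (0, 2)
        assert recs[0].atom_pair_count == 1

    def test_adjacent_residues_excluded(self):
        chain = ChainModel("X", "A", [
            _point_residue(1, "ALA", np.array([0.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([3.0, 0.0, 0.0])),
        ])
        assert find_atom_contacts(chain) == []

    @pytest.mark.parametrize("seed", [1, 7, 13])
    def test_matches_brute_force_on_helix(self, seed):
        chain = make_chain(30, random_sequence(30, seed), seed=seed)
        got = {(r.index_a, r.index_b): r.atom_pair_count for r in find_atom_contacts(chain)}
        assert got == brute_force_contacts(chain)

    def test_cutoff_monotonicity(self):
        chain = make_chain(25, random_sequence(25, 2), seed=2)
        small = {(r.index_a, r.index_b) for r in find_atom_contacts(chain, cutoff=4.0)}
        large = {(r.index_a, r.index_b) for r in find_atom_contacts(chain, cutoff=5.0)}
        assert small <= large


class TestDeriveNormalization:
    def test_single_contact(self):
        chain = ChainModel("X", "A", [
            _point_residue(1, "LEU", np.array([0.0, 0.0, 0.0]),
                           np.array([1.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([0.0, 0.0, 50.0])),
            _point_residue(3, "LEU", np.array([1.0, 1.0, 0.0]),
                           np.array([2.0, 1.0, 0.0])),
        ])
        table = derive_normalization([chain])
        # 2 heavy atoms per LEU residue, all four cross-pairs within cutoff
        assert table.get("LEU", "LEU") == 4
        assert ("ALA", "ALA") not in table
        with pytest.raises(KeyError):
            table.get("ALA", "LEU")

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            derive_normalization([])

    def test_pooled_max_oracle(self):
        chains = [make_chain(20, random_sequence(20, s), seed=s) for s in range(10)]
        table = derive_normalization(chains)
        pooled = {}
        for ch in chains:
            for (i, j), c in brute_force_contacts(ch).items():
                key = tuple(sorted((ch.residues[i].name3, ch.residues[j].name3)))
                pooled[key] = max(pooled.get(key, 0), c)
        assert dict(table.items()) == pooled

    def test_tsv_roundtrip(self, tmp_path, norm_table):
        path = tmp_path / "norm.tsv"
        norm_table.to_tsv(path)
        back = NormalizationTable.from_tsv(path)
        assert dict(back.items()) == dict(norm_table.items())


class TestBuildPSN:
    def test_weight_arithmetic(self):
        chain = ChainModel("X", "A", [
            _point_residue(1, "ALA", np.array([0.0, 0.0, 0.0]),
                           np.array([1.0, 0.0, 0.0]), np.array([2.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([0.0, 0.0, 50.0])),
            _point_residue(3, "ALA", np.array([0.0, 3.0, 0.0])),
        ])
        recs = find_atom_contacts(chain)
        count = recs[0].atom_pair_count
        table = NormalizationTable({("ALA", "ALA"): count + 2})
        psn = build_psn(chain, table)
        assert psn.adjacency[0, 2] == pytest.approx(count / (count + 2))
        # count equal to the table maximum gives weight exactly 1
        psn_max = build_psn(chain, NormalizationTable({("ALA", "ALA"): count}))
        assert psn_max.adjacency[0, 2] == 1.0

    def test_clamped_weight_warns(self, caplog):
        chain = ChainModel("X", "A", [
            _point_residue(1, "ALA", np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([0.0, 0.0, 50.0])),
            _point_residue(3, "ALA", np.array([0.0, 3.0, 0.0])),
        ])
        with caplog.at_level(logging.WARNING, logger="psndelta.psn_builder"):
            psn = build_psn(chain, NormalizationTable({("ALA", "ALA"): 1}))
        assert psn.adjacency[0, 2] == 1.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_missing_pair_names_the_pair(self):
        chain = ChainModel("X", "A", [
            _point_residue(1, "TRP", np.array([0.0, 0.0, 0.0])),
            _point_residue(2, "ALA", np.array([0.0, 0.0, 50.0])),
            _point_residue(3, "TRP", np.array([0.0, 3.0, 0.0])),
        ])
        with pytest.raises(KeyError, match="TRP"):
            build_psn(chain, NormalizationTable({("ALA", "ALA"): 5}))

    def test_isolated_nodes_kept(self, norm_table):
        chain = make_chain(12, random_sequence(12, 4), seed=4)
        psn = build_psn(chain, norm_table)
        assert psn.n_nodes == 12

    def test_rigid_motion_leaves_graph_unchanged(self, norm_table):
        from scipy.spatial.transform import Rotation

        chain = make_chain(25, random_sequence(25, 9), seed=9)
        psn = build_psn(chain, norm_table)
        rot = Rotation.from_euler("zyx", [17, -40, 95], degrees=True)
        moved = make_chain(25, random_sequence(25, 9), seed=9)
        for res in moved.residues:
            for atom in res.atoms:
                atom.position = rot.apply(atom.position) + np.array([10.0, 0.0, -4.0])
        psn2 = build_psn(moved, norm_table)
        np.testing.assert_allclose(psn.adjacency, psn2.adjacency, atol=1e-12)


class TestHubsAndMetrics:
    def test_hub_threshold_boundary(self):
        star11 = graph_from_edges(13, {(0, j): 0.5 for j in range(2, 13)})
        star10 = graph_from_edges(12, {(0, j): 0.5 for j in range(2, 12)})
        assert star11.degree[0] == 11 and star11.hubs[0]
        assert star10.degree[0] == 10 and not star10.hubs[0]

    def test_degree_strength_example(self):
        g = graph_from_edges(5, {(0, 2): 0.5, (0, 4): 0.5})
        table = node_metrics(g)
        assert table.loc[0, "degree"] == 2
        assert table.loc[0, "strength"] == pytest.approx(1.0)
        assert table.loc[1, "degree"] == 0
        assert table.loc[1, "strength"] == 0.0
        assert not table.loc[1, "is_hub"]

    def test_metrics_match_matrix_recount(self, norm_table):
        psn = build_psn(make_chain(30, random_sequence(30, 21), seed=21), norm_table)
        table = node_metrics(psn)
        adj = psn.adjacency
        np.testing.assert_array_equal(table["degree"].to_numpy(), (adj > 0).sum(axis=0))
        np.testing.assert_allclose(table["strength"].to_numpy(), adj.sum(axis=0))

    def test_handshake_identities(self, norm_table):
        psn = build_psn(make_chain(30, random_sequence(30, 8), seed=8), norm_table)
        assert psn.degree.sum() == 2 * psn.n_edges
        assert psn.strength.sum() == pytest.approx(2 * psn.total_edge_weight())

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError):
            PSNGraph(["a", "b"], ["ALA", "ALA"], np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            PSNGraph(["a", "b"], ["ALA", "ALA"], np.array([[0.2, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            PSNGraph(["a", "b"], ["ALA", "ALA"], np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestExport:
    def test_graphml_and_edge_table(self, tmp_path, norm_table):
        import networkx as nx

        psn = build_psn(make_chain(20, random_sequence(20, 14), seed=14), norm_table)
        path = tmp_path / "psn.graphml"
        psn.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == psn.n_nodes
        assert g.number_of_edges() == psn.n_edges
        table = psn.edge_table()
        assert len(table) == psn.n_edges
        assert (table["weight"] > 0).all() and (table["weight"] <= 1).all()
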