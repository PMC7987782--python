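import itertools
import math

import numpy as np
import pytest

from psndelta import (
    EdgelessGraphError,
    crs,
    eds,
    ewcs,
    laplacian_spectrum,
    match_eigenvectors,
    nds_score,
)
from psndelta.nds import EigenvectorMatching, laplacian_matrix

from conftest import graph_from_edges, random_psn_pair


class TestLaplacianSpectrum:
    def test_k2_eigenvalues_any_weight(self):
        for w in (0.1, 0.5, 1.0):
            g = graph_from_edges(2, {(0, 1): w})
            spec = laplacian_spectrum(g)
            np.testing.assert_allclose(spec.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_unit_triangle(self):
        g = graph_from_edges(3, {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        spec = laplacian_spectrum(g)
        np.testing.assert_allclose(spec.eigenvalues, [0.0, 1.5, 1.5], atol=1e-12)

    def test_edgeless_graph_all_zero(self):
        lap = laplacian_matrix(np.zeros((4, 4)))
        np.testing.assert_array_equal(lap, np.zeros((4, 4)))

    def test_isolated_node_gets_zero_eigenpair(self):
        g = graph_from_edges(3, {(0, 1): 0.7})  # node 2 isolated
        spec = laplacian_spectrum(g)
        np.testing.assert_allclose(sorted(spec.eigenvalues), [0.0, 0.0, 2.0], atol=1e-12)

    def test_normalized_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, _ = random_psn_pair(7, rng)
            vals = laplacian_spectrum(a).eigenvalues
            assert vals.min() >= -1e-8 and vals.max() <= 2.0 + 1e-8

    def test_combinatorial_variant(self):
        g = graph_from_edges(3, {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        spec = laplacian_spectrum(g, variant="combinatorial")
        np.testing.assert_allclose(spec.eigenvalues, [0.0, 3.0, 3.0], atol=1e-12)


class TestEds:
    def test_identical_graphs_zero(self):
        g = graph_from_edges(4, {(0, 2): 0.5, (1, 3): 0.8})
        assert eds(g, g) == 0.0

    def test_halved_single_edge_pins_convention(self):
        """One edge at weight 1.0 vs 0.5: full-matrix Frobenius over a
        per-edge denominator gives exactly 1."""
        a = graph_from_edges(2, {(0, 1): 1.0})
        b = graph_from_edges(2, {(0, 1): 0.5})
        # ‖A−B‖_F = sqrt(2·0.25); denominator sqrt(1.0·0.5)
        assert eds(a, b) == pytest.approx(1.0, abs=1e-12)
        assert eds(a, b, denominator="full_matrix") == pytest.approx(
            math.sqrt(0.5) / math.sqrt(2.0 * 1.0), abs=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = random_psn_pair(6, rng)
            assert eds(a, b) == pytest.approx(eds(b, a), abs=1e-12)

    def test_edgeless_raises_distinct_error(self):
        a = graph_from_edges(3, {(0, 2): 0.5})
        b = graph_from_edges(3, {})
        with pytest.raises(EdgelessGraphError):
            eds(a, b)


class TestCrs:
    def test_identical_graphs_one(self):
        g = graph_from_edges(5, {(0, 2): 0.5, (1, 4): 0.9, (0, 3): 0.2})
        spec = laplacian_spectrum(g)
        assert crs(spec, spec) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_reversed_ranks_give_minus_one(self, n):
        """The Spearman lower bound: perfectly reversed ranks score −1."""
        g = graph_from_edges(n, {(0, j): 0.5 for j in range(2, n)})
        spec = laplacian_spectrum(g)
        reversed_match = EigenvectorMatching(
            pairs=[(i, n - 1 - i, 1.0) for i in range(n)]
        )
        direct = 1 - 6 * sum((2 * i - (n - 1)) ** 2 for i in range(n)) / (n * (n * n - 1))
        assert crs(spec, spec, reversed_match) == pytest.approx(-1.0)
        assert direct == pytest.approx(-1.0)

    def test_matching_equals_exhaustive_assignment(self):
        """On small graphs with well-separated spectra the one-to-one
        eigenvector matching equals the optimal assignment over all n!
        pairings."""
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 8:
            a, b = random_psn_pair(5, rng, density=0.6)
            sa, sb = laplacian_spectrum(a), laplacian_spectrum(b)
            if sa.degenerate or sb.degenerate:
                continue
            cos = np.abs(sa.eigenvectors.T @ sb.eigenvectors)
            best = max(
                itertools.permutations(range(5)),
                key=lambda perm: sum(cos[i, perm[i]] for i in range(5)),
            )
            matching = match_eigenvectors(sa, sb)
            assert sum(c for _, _, c in matching.pairs) == pytest.approx(
                sum(cos[i, best[i]] for i in range(5)), abs=1e-9
            )
            assert crs(sa, sb, matching) == pytest.approx(
                1 - 6 * sum((i - best[i]) ** 2 for i in range(5)) / (5 * 24)
            )
            checked += 1


class TestEwcs:
    def test_identical_graphs_zero(self):
        g = graph_from_edges(4, {(0, 2): 0.5, (1, 3): 0.8})
        spec = laplacian_spectrum(g)
        assert ewcs(spec, spec) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pair_with_all_weight_reaches_one(self):
        from psndelta.nds import SpectralDecomposition

        vecs_a = np.eye(2)
        vecs_b = np.array([[0.0, 1.0], [1.0, 0.0]])
        sa = SpectralDecomposition(np.array([0.0, 2.0]), vecs_a)
        sb = SpectralDecomposition(np.array([0.0, 2.0]), vecs_b)
        matching = EigenvectorMatching(pairs=[(0, 0, 0.0), (1, 1, 0.0)])
        assert ewcs(sa, sb, matching) == pytest.approx(1.0)

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(6):
            a, b = random_psn_pair(5, rng, density=0.6)
            sa, sb = laplacian_spectrum(a), laplacian_spectrum(b)
            m = match_eigenvectors(sa, sb)
            num = den = 0.0
            for i, j, c in m.pairs:
                w = abs(1 - sa.eigenvalues[i]) * abs(1 - sb.eigenvalues[j])
                num += w * (1 - c) ** 2
                den += w
            expected = math.sqrt(num / den) if den else 0.0
            assert ewcs(sa, sb, m) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a, b = random_psn_pair(6, rng)
            sa, sb = laplacian_spectrum(a), laplacian_spectrum(b)
            assert 0.0 <= ewcs(sa, sb) <= 1.0


class TestNdsScore:
    def test_self_comparison_exact_identity(self, norm_table):
        from psndelta import build_psn, make_chain
        from psndelta.synthetic_data import random_sequence

        psn = build_psn(make_chain(25, random_sequence(25, 15), seed=15), norm_table)
        res = nds_score(psn, psn)
        assert (res.eds, res.crs, res.ewcs, res.nds) == (0.0, 1.0, 0.0, 0.0)

    def test_component_aggregation(self):
        # eds 0.6, crs 0.2, ewcs 0 ⇒ nds = sqrt(0.36 + 0 + 0.64) = 1
        assert math.sqrt(0.6**2 + 0.0**2 + (1 - 0.2) ** 2) == pytest.approx(1.0)
        rng = np.random.default_rng(9)
        a, b = random_psn_pair(6, rng)
        res = nds_score(a, b)
        assert res.nds == pytest.approx(
            math.sqrt(res.eds**2 + res.ewcs**2 + (1 - res.crs) ** 2)
        )

    def test_swap_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            a, b = random_psn_pair(6, rng)
            r1, r2 = nds_score(a, b), nds_score(b, a)
            assert r1.eds == pytest.approx(r2.eds, abs=1e-9)
            assert r1.crs == pytest.approx(r2.crs, abs=1e-9)
            assert r1.ewcs == pytest.approx(r2.ewcs, abs=1e-9)
            assert r1.nds == pytest.approx(r2.nds, abs=1e-9)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(11)
        a, b = random_psn_pair(7, rng)
        perm = rng.permutation(7)
        pa = a.adjacency[np.ix_(perm, perm)]
        pb = b.adjacency[np.ix_(perm, perm)]
        r1 = nds_score(a.adjacency, b.adjacency)
        r2 = nds_score(pa, pb)
        assert r1.eds == pytest.approx(r2.eds, abs=1e-8)
        assert r1.crs == pytest.approx(r2.crs, abs=1e-8)
        assert r1.ewcs == pytest.approx(r2.ewcs, abs=1e-8)

    def test_edgeless_input_rejected(self):
        a = graph_from_edges(3, {(0, 2): 0.5})
        b = graph_from_edges(3, {})
        with pytest.raises(EdgelessGraphError):
            nds_score(a, b)

    def test_result_serializes(self, tmp_path):
        rng = np.random.default_rng(12)
        a, b = random_psn_pair(5, rng)
        res = nds_score(a, b)
        path = tmp_path / "nds.json"
        res.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["n"] == 5
        assert len(data["eigenvector_matching"]) == 5
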