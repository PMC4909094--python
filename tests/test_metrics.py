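import numpy as np
import pytest

from sfconn import (ConnectivityMatrix, SpectralConditionError, compute_metrics,
                    edge_lengths, euclidean_distance, fca, fit_coupling,
                    path_transitivity, search_information, shortest_paths)
from sfconn.metrics import matching_index_matrix, _normalise_w
import pandas as pd

import oracles


def chain_matrix(counts):
    """Path graph with given successive edge counts."""
    n = len(counts) + 1
    W = np.zeros((n, n))
    for i, c in enumerate(counts):
        W[i, i + 1] = W[i + 1, i] = c
    return W


class TestEdgeLengths:
    def test_inverse_count(self):
        W = chain_matrix([4.0])
        L = edge_lengths(W)
        assert L[0, 1] == 0.25

    def test_absent_edge_infinite(self):
        L = edge_lengths(np.zeros((3, 3)))
        assert np.isinf(L[0, 1])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            edge_lengths(np.array([[0, -1.0], [-1.0, 0]]))


class TestShortestPaths:
    def test_chain_sums_inverse_counts(self):
        W = chain_matrix([2.0, 4.0])
        pl, paths = shortest_paths(edge_lengths(W))
        assert pl[0, 2] == pytest.approx(0.5 + 0.25)
        assert paths[(0, 2)] == (0, 1, 2)

    def test_direct_edge_when_shortest(self):
        W = np.array([[0, 10.0, 1.0], [10.0, 0, 10.0], [1.0, 10.0, 0]])
        _, paths = shortest_paths(edge_lengths(W))
        assert paths[(0, 1)] == (0, 1)

    def test_lexicographic_tie_break(self):
        # square 0-1-3 and 0-2-3 with equal lengths: route via 1 wins
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 3), (0, 2), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        _, paths = shortest_paths(edge_lengths(W))
        assert paths[(0, 3)] == (0, 1, 3)

    def test_disconnected_pair_infinite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        pl, paths = shortest_paths(edge_lengths(W))
        assert np.isinf(pl[0, 2])
        assert (0, 2) not in paths

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            W = oracles.random_connected_graph(rng)
            pl, paths = shortest_paths(edge_lengths(W))
            for (s, t) in [(0, W.shape[0] - 1), (1, 2)]:
                blen, bpath = oracles.shortest_path_oracle(W, s, t)
                assert pl[s, t] == pytest.approx(blen, abs=1e-9)
                assert paths[(s, t)] == tuple(bpath)


class TestSearchInformation:
    def test_forced_walk_zero_bits(self):
        W = chain_matrix([1.0, 1.0])
        _, paths = shortest_paths(edge_lengths(W))
        si = search_information(W, paths)
        # after the first step the walker cannot return; the chain forces it
        assert si[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_star_branch_costs_one_bit(self):
        # B is node 1, connected to A=0, C=2, D=3 with unit weights
        W = np.zeros((4, 4))
        for j in (0, 2, 3):
            W[1, j] = W[j, 1] = 1.0
        _, paths = shortest_paths(edge_lengths(W))
        si = search_information(W, paths)
        assert si[0, 2] == pytest.approx(1.0, abs=1e-12)  # p = 1 * 1/2

    @pytest.mark.parametrize("variant", ["no_return", "memoryless"])
    def test_oracle_equivalence_random_graphs(self, rng, variant):
        for _ in range(40):
            W = oracles.random_connected_graph(rng)
            _, paths = shortest_paths(edge_lengths(W))
            si = search_information(W, paths, variant=variant)
            for (s, t), path in paths.items():
                p = oracles.walker_path_probability(W, path, no_return=(variant == "no_return"))
                assert si[s, t] == pytest.approx(-np.log2(p), abs=1e-10)

    def test_non_negative_and_scale_invariant(self, rng):
        W = oracles.random_connected_graph(rng)
        _, paths = shortest_paths(edge_lengths(W))
        si = search_information(W, paths)
        assert (si[np.isfinite(si)] >= -1e-12).all()
        _, paths2 = shortest_paths(edge_lengths(3.7 * W))
        si2 = search_information(3.7 * W, paths2)
        np.testing.assert_allclose(si, si2, atol=1e-9)


class TestPathTransitivity:
    def test_isolated_dyad_zero(self):
        W = chain_matrix([2.0])
        _, paths = shortest_paths(edge_lengths(W))
        pt = path_transitivity(W, paths)
        assert pt[0, 1] == 0.0

    def test_complete_uniform_graph_is_one(self):
        W = np.ones((5, 5)) - np.eye(5)
        _, paths = shortest_paths(edge_lengths(W))
        pt = path_transitivity(W, paths)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(pt[iu], 1.0)

    def test_oracle_equivalence_random_graphs(self, rng):
        for _ in range(40):
            W = oracles.random_connected_graph(rng)
            _, paths = shortest_paths(edge_lengths(W))
            pt = path_transitivity(W, paths)
            for (s, t), path in paths.items():
                if s < t:
                    assert pt[s, t] == pytest.approx(
                        oracles.path_transitivity_oracle(W, path), abs=1e-10)

    def test_bounded_and_scale_invariant(self, rng):
        W = oracles.random_connected_graph(rng)
        _, paths = shortest_paths(edge_lengths(W))
        pt = path_transitivity(W, paths)
        assert (pt >= 0).all() and (pt <= 1 + 1e-12).all()
        np.testing.assert_allclose(path_transitivity(2.5 * W, paths), pt, atol=1e-12)


class TestEuclideanDistance:
    def nodes(self, coords):
        return pd.DataFrame([(i, f"n{i}", "L", *c) for i, c in enumerate(coords)],
                            columns=["node_id", "label", "hemisphere", "x", "y", "z"])

    def test_3_4_5_triangle(self):
        ed = euclidean_distance(self.nodes([(0, 0, 0), (3, 4, 0)]))
        assert ed[0, 1] == pytest.approx(5.0)
        assert ed[0, 0] == 0.0

    def test_translation_invariance(self, rng):
        pts = rng.random((6, 3)) * 50
        a = euclidean_distance(self.nodes(pts))
        b = euclidean_distance(self.nodes(pts + np.array([10.0, -5.0, 2.0])))
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestFCA:
    def test_zero_coupling_identity(self, rng):
        W = oracles.random_connected_graph(rng)
        np.testing.assert_allclose(fca(W, 0.0), np.eye(W.shape[0]), atol=1e-12)

    @pytest.mark.parametrize("c", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_two_node_closed_form(self, c):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert fca(W, c)[0, 1] == pytest.approx(c, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        W = oracles.random_connected_graph(rng, n_min=6, n_max=6)
        Wn, _ = _normalise_w(W)
        np.testing.assert_allclose(fca(W, 0.3), oracles.fca_oracle(Wn, 0.3), atol=1e-10)

    def test_positive_semidefinite_under_spectral_condition(self, rng):
        W = oracles.random_connected_graph(rng)
        corr = fca(W, 0.6)
        assert np.linalg.eigvalsh(corr).min() > -1e-10

    def test_spectral_violation_reports_bound(self, rng):
        W = oracles.random_connected_graph(rng)
        _, c_max = _normalise_w(W)
        with pytest.raises(SpectralConditionError, match="admissible"):
            fca(W, c_max + 0.5)

    def test_scale_invariance(self, rng):
        W = oracles.random_connected_graph(rng)
        np.testing.assert_allclose(fca(W, 0.4), fca(10.0 * W, 0.4), atol=1e-10)


class TestFitCoupling:
    def test_self_consistent_recovery(self, rng):
        W = oracles.random_connected_graph(rng, n_min=8, n_max=8)
        target = fca(W, 0.32)
        fit = fit_coupling(W, target)
        assert fit.c_hat == pytest.approx(0.32, abs=0.011)

    def test_noisy_recovery(self, rng):
        # noise small relative to the FCA edge scale keeps c identifiable
        from sfconn import CohortSpec, generate_structural_runs, reconcile_runs
        spec = CohortSpec(n_nodes=64, ts_length=64, seed=1)
        s = generate_structural_runs(spec, 0)
        W = reconcile_runs(s.run1, s.run2).weights.values
        target = fca(W, 0.32)
        iu = np.triu_indices(64, 1)
        noisy = target.copy()
        noise = rng.normal(0, 0.002, iu[0].size)
        noisy[iu] += noise
        noisy.T[iu] += noise
        fit = fit_coupling(W, noisy)
        assert abs(fit.c_hat - 0.32) <= 0.02

    def test_objective_curve_shape(self, rng):
        W = oracles.random_connected_graph(rng, n_min=8, n_max=8)
        fit = fit_coupling(W, fca(W, 0.32))
        cs, rs = fit.curve[:, 0], fit.curve[:, 1]
        assert rs[np.argmin(np.abs(cs - 0.32))] == pytest.approx(1.0, abs=1e-6)
        assert 0 < fit.c_hat < fit.c_max_admissible


class TestComputeMetrics:
    def test_bundle_consistency(self, rng):
        from sfconn import CohortSpec, generate_structural_runs, reconcile_runs
        spec = CohortSpec(n_nodes=16, ts_length=64, seed=3)
        s = generate_structural_runs(spec, 0)
        rec = reconcile_runs(s.run1, s.run2)
        ms = compute_metrics(rec.weights, s.coords, coupling=0.32)
        fin = np.isfinite(ms.pl.values)
        assert (ms.pl.values[fin] >= 0).all()
        assert (ms.pt.values >= 0).all() and (ms.pt.values <= 1).all()
        np.testing.assert_allclose(ms.si.values, ms.si.values.T)
        off = ~np.eye(16, dtype=bool)
        absent = (rec.weights.values == 0) & off
        assert np.isnan(ms.logcount.values[absent]).all()
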