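"""Correlation-network construction and density thresholding."""

import numpy as np
import pandas as pd
import pytest

from scnet.errors import DataError, DensityError
from scnet.networks import (
    CovarianceNetwork,
    binarize_at_density,
    build_profile,
    correlation_network,
    density_grid,
    min_connectivity_density,
    n_edges_at_density,
    rank_edges,
    residualize,
)
from scnet.volumes import region_columns


def table_from_matrix(Y, extra=None):
    df = pd.DataFrame(Y, columns=[f"R{i}" for i in range(Y.shape[1])])
    df.insert(0, "sex", (extra or {}).get("sex", np.zeros(len(Y), dtype=int)))
    df.insert(0, "age", (extra or {}).get("age", np.arange(len(Y), dtype=float)))
    df.insert(0, "timepoint", "baseline")
    df.insert(0, "group", "g")
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(Y))])
    return df


def net_from_corr(corr, names=None):
    n = corr.shape[0]
    names = names or tuple(f"R{i}" for i in range(n))
    return CovarianceNetwork(tuple(names), corr, "g", 10)


class TestResidualize:
    def test_empty_covariates_demeans(self):
        Y = np.arange(12.0).reshape(4, 3)
        out = residualize(table_from_matrix(Y), covariate_names=())
        resid = out[region_columns(out)].to_numpy()
        assert np.allclose(resid, Y - Y.mean(axis=0))

    def test_ols_orthogonality_to_covariate(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 40, 50)
        Y = np.column_stack([2 * age + rng.normal(0, 0.1, 50) for _ in range(3)])
        out = residualize(table_from_matrix(Y, {"age": age}), ("age",))
        resid = out[region_columns(out)].to_numpy()
        assert np.abs(resid.mean(axis=0)).max() < 1e-10
        for col in resid.T:
            assert abs(np.corrcoef(col, age)[0, 1]) < 1e-10

    def test_matches_normal_equation_solve(self):
        """5 subjects x 3 regions, residuals from the explicit (X'X)^-1 X'Y fit."""
        Y = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [3.0, 5.0, 2.0], [4.0, 3.0, 3.5],
             [5.0, 7.0, 2.5]]
        )
        age = np.array([20.0, 25.0, 30.0, 35.0, 40.0])
        sex = np.array([0, 1, 0, 1, 0])
        X = np.column_stack([np.ones(5), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        expected = Y - X @ beta
        out = residualize(table_from_matrix(Y, {"age": age, "sex": sex}))
        assert np.allclose(out[region_columns(out)].to_numpy(), expected)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(20, 4))
        tab = table_from_matrix(
            Y, {"age": rng.uniform(20, 40, 20), "sex": rng.integers(0, 2, 20)}
        )
        once = residualize(tab)
        twice = residualize(once)
        assert np.allclose(
            once[region_columns(once)].to_numpy(),
            twice[region_columns(twice)].to_numpy(),
            atol=1e-10,
        )

    def test_constant_covariate_dropped_with_warning(self):
        Y = np.random.default_rng(2).normal(size=(10, 2))
        tab = table_from_matrix(Y, {"sex": np.ones(10, dtype=int)})
        with pytest.warns(UserWarning, match="constant"):
            residualize(tab, ("sex",))

    def test_more_covariates_than_subjects_errors(self):
        Y = np.random.default_rng(3).normal(size=(2, 2))
        with pytest.raises(DataError):
            residualize(table_from_matrix(Y), ("age", "sex"))


class TestCorrelationNetwork:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        Y = np.column_stack([x, x, -x])
        net = correlation_network(table_from_matrix(Y))
        assert net.corr[0, 1] == pytest.approx(1.0)
        assert net.corr[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_four_by_three(self):
        """4 subjects x 3 regions against the covariance/SD formula by hand."""
        Y = np.array([[1.0, 2.0, 1.0], [2.0, 4.5, 0.0], [3.0, 5.0, 3.0], [4.0, 9.0, 2.0]])
        net = correlation_network(table_from_matrix(Y))
        for i in range(3):
            for j in range(3):
                xi, xj = Y[:, i] - Y[:, i].mean(), Y[:, j] - Y[:, j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert net.corr[i, j] == pytest.approx(expected)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(15, 4))
        net1 = correlation_network(table_from_matrix(Y))
        scale = rng.uniform(0.5, 3.0, 4)
        shift = rng.normal(size=4)
        net2 = correlation_network(table_from_matrix(Y * scale + shift))
        assert np.allclose(net1.corr, net2.corr, atol=1e-12)

    def test_zero_variance_region_errors_by_name(self):
        Y = np.random.default_rng(6).normal(size=(5, 3))
        Y[:, 1] = 7.0
        with pytest.raises(DataError, match="R1"):
            correlation_network(table_from_matrix(Y))

    def test_too_few_subjects_errors(self):
        with pytest.raises(DataError):
            correlation_network(table_from_matrix(np.ones((2, 3))))


def symmetric(mat):
    m = np.asarray(mat, dtype=float)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class TestBinarize:
    def test_full_density_on_all_positive_matrix(self):
        corr = symmetric(np.full((5, 5), 0.4) + np.diag(np.ones(5) * 0.6))
        adj = binarize_at_density(net_from_corr(corr), 1.0)
        assert adj.sum() == 5 * 4  # complete graph, both triangle halves
        assert not adj.diagonal().any()

    def test_manual_ranking_top_three_of_six_pairs(self):
        corr = symmetric(
            [
                [1.0, 0.9, 0.2, 0.5],
                [0.9, 1.0, 0.7, 0.1],
                [0.2, 0.7, 1.0, 0.6],
                [0.5, 0.1, 0.6, 1.0],
            ]
        )
        adj = binarize_at_density(net_from_corr(corr), 0.5)  # k = round(0.5*6) = 3
        expected = {(0, 1), (1, 2), (2, 3)}  # ranks: .9, .7, .6
        got = {tuple(e) for e in np.argwhere(np.triu(adj, 1))}
        assert got == expected

    def test_tie_break_is_lexicographic_and_stable(self):
        corr = symmetric(
            [
                [1.0, 0.5, 0.5, 0.1],
                [0.5, 1.0, 0.1, 0.5],
                [0.5, 0.1, 1.0, 0.1],
                [0.1, 0.5, 0.1, 1.0],
            ]
        )
        net = net_from_corr(corr)
        # k=2 out of four 0.5-ties: (0,1) and (0,2) win lexicographically
        adj1 = binarize_at_density(net, 2 / 6)
        adj2 = binarize_at_density(net, 2 / 6)
        got = {tuple(e) for e in np.argwhere(np.triu(adj1, 1))}
        assert got == {(0, 1), (0, 2)}
        assert np.array_equal(adj1, adj2)

    def test_negative_correlations_never_become_edges(self):
        corr = symmetric(np.full((4, 4), -0.5))
        with pytest.raises(DensityError, match="positive"):
            binarize_at_density(net_from_corr(corr), 0.5)

    def test_zero_edge_density_errors(self):
        corr = symmetric(np.full((4, 4), 0.5))
        with pytest.raises(DensityError):
            binarize_at_density(net_from_corr(corr), 0.01)


class TestMinConnectivityDensity:
    def test_brute_force_scan_on_random_network(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(30, 12))
        net = correlation_network(table_from_matrix(Y))
        d = min_connectivity_density([net], grid_step=0.01)
        # oracle: scan the grid, binarize, check connectivity directly
        from scnet.networks import is_connected

        def connected_at(dd):
            try:
                return is_connected(binarize_at_density(net, dd))
            except DensityError:
                return False

        assert connected_at(d)
        smaller = round(d - 0.01, 10)
        if n_edges_at_density(smaller, 12) > 0:
            assert not connected_at(smaller)

    def test_star_structure_needs_exactly_n_minus_one_edges(self):
        n = 12
        corr = np.full((n, n), 0.05)
        corr[0, :] = corr[:, 0] = 0.9  # all top correlations involve region 0
        corr = symmetric(corr)
        d = min_connectivity_density([net_from_corr(corr)], grid_step=0.001)
        k = n_edges_at_density(d, n)
        assert k == n - 1  # the spanning star
        prev = n_edges_at_density(round(d - 0.001, 10), n)
        assert prev < n - 1

    def test_two_groups_take_the_maximum(self):
        rng = np.random.default_rng(8)
        nets = [
            correlation_network(table_from_matrix(rng.normal(size=(25, 10))))
            for _ in range(2)
        ]
        d_both = min_connectivity_density(nets)
        d_each = [min_connectivity_density([n]) for n in nets]
        assert d_both == max(d_each)


class TestBuildProfile:
    def test_grid_arithmetic(self):
        assert len(density_grid(0.1, 0.5, 0.01)) == 41
        assert len(density_grid(0.3, 0.3, 0.01)) == 1

    def test_profile_edge_counts_and_nestedness(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(40, 15))
        net = correlation_network(table_from_matrix(Y))
        d_min = min_connectivity_density([net])
        prof = build_profile(net, d_min)
        for d, adj in zip(prof.density_grid, prof.adjacency):
            assert adj.sum() // 2 == n_edges_at_density(float(d), 15)
        for a_lo, a_hi in zip(prof.adjacency[:-1], prof.adjacency[1:]):
            assert not (a_lo & ~a_hi).any()  # every edge persists at higher density

    def test_single_density_profile(self):
        corr = symmetric(np.full((6, 6), 0.5))
        prof = build_profile(net_from_corr(corr), 0.4, 0.4)
        assert prof.adjacency.shape[0] == 1


def test_rank_edges_orders_by_descending_correlation():
    rng = np.random.default_rng(10)
    Y = rng.normal(size=(20, 8))
    net = correlation_network(table_from_matrix(Y))
    rows, cols = rank_edges(net.corr)
    vals = net.corr[rows, cols]
    assert (np.diff(vals) <= 1e-15).all()
    assert (vals > 0).all()
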