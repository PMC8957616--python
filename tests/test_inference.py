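"""Neighbourhood lasso and StARS selection, checked against a brute-force
coordinate-descent oracle and constructed stability scenarios."""

import numpy as np
import pytest

from miconet import clr_transform, make_lambda_path, neighborhood_fit, stars_select
from miconet.inference import (
    RegularizationPath,
    lambda_max,
    network_from_coefs,
    _standardize,
)


def cd_lasso_oracle(x, y, lam, n_sweeps=4000, tol=1e-12):
    """Plain cyclic coordinate descent for (1/2n)||y - Xb||^2 + lam ||b||_1."""
    n, p = x.shape
    b = np.zeros(p)
    col = (x**2).sum(axis=0) / n
    r = y - x @ b
    for _ in range(n_sweeps):
        delta = 0.0
        for j in range(p):
            if col[j] == 0:
                continue
            r = r + x[:, j] * b[j]
            rho = x[:, j] @ r / n
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col[j]
            delta = max(delta, abs(new - b[j]))
            b[j] = new
            r = r - x[:, j] * b[j]
        if delta < tol:
            break
    return b


def _clr_like(n, p, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    return x - x.mean(axis=1, keepdims=True)


class TestNeighborhoodFit:
    def test_all_zero_at_lambda_max(self):
        x = _clr_like(60, 8, 0)
        lmax = lambda_max(x)
        assert not neighborhood_fit(x, lmax * 1.0001).any()
        # just below lambda_max something activates
        assert neighborhood_fit(x, lmax * 0.95).any()

    def test_matches_coordinate_descent_oracle_along_path(self):
        x = _clr_like(200, 5, 3)
        z, _ = _standardize(x)
        path = make_lambda_path(x, n_lambda=8, lambda_min_ratio=0.05)
        for lam in path.lambdas:
            b = neighborhood_fit(x, lam)
            for j in range(5):
                others = [k for k in range(5) if k != j]
                expect = cd_lasso_oracle(z[:, others], z[:, j], lam)
                assert np.allclose(b[others, j], expect, atol=1e-5)

    def test_duplicated_profile_pair_found_first(self):
        rng = np.random.default_rng(7)
        shared = rng.normal(size=200)
        x = np.column_stack([shared, shared, *(rng.normal(size=(3, 200)))])
        lam = 0.3 * lambda_max(x)
        b = neighborhood_fit(x, lam)
        assert b[1, 0] != 0 and b[0, 1] != 0
        mask = np.ones((5, 5), dtype=bool)
        mask[0, 1] = mask[1, 0] = False
        np.fill_diagonal(mask, False)
        assert not b[mask].any()

    def test_edge_count_monotone_in_lambda(self, small_table):
        clr = clr_transform(small_table)
        path = make_lambda_path(clr, n_lambda=12)
        counts = []
        for lam in path.lambdas:
            b = neighborhood_fit(clr, lam)
            counts.append(int(((b != 0) | (b != 0).T).sum() // 2))
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_zero_variance_taxon_excluded(self):
        x = _clr_like(50, 4, 1)
        x[:, 2] = 0.0
        b = neighborhood_fit(x, 0.05)
        assert not b[2, :].any() and not b[:, 2].any()


class TestLambdaPath:
    def test_endpoints_and_monotonicity(self):
        x = _clr_like(80, 10, 2)
        path = make_lambda_path(x, n_lambda=20, lambda_min_ratio=0.01)
        assert path.n_lambda == 20
        assert path.lambdas[0] == pytest.approx(lambda_max(x))
        assert path.lambdas[-1] == pytest.approx(0.01 * lambda_max(x))
        assert (np.diff(path.lambdas) < 0).all()

    def test_invalid_path_rejected(self):
        with pytest.raises(ValueError):
            RegularizationPath(lambdas=np.array([0.1, 0.2]), lambda_min_ratio=0.01)


class TestStars:
    def test_instability_in_range_and_selection_member_of_path(self, small_table, fast_config):
        clr = clr_transform(small_table)
        res = stars_select(clr, n_subsamples=10, seed=1)
        assert (res.instability >= 0).all() and (res.instability <= 0.5).all()
        assert res.selected_lambda in res.path.lambdas
        assert (np.diff(res.monotone_instability) >= 0).all()

    def test_identical_selection_gives_zero_instability(self):
        # two perfectly associated taxa + weak noise: at moderate lambda
        # every subsample selects exactly the same single edge
        rng = np.random.default_rng(5)
        shared = rng.normal(size=300)
        x = np.column_stack(
            [shared, shared + 0.01 * rng.normal(size=300), rng.normal(size=(300,)), rng.normal(size=(300,))]
        )
        res = stars_select(x, n_subsamples=15, seed=2)
        assert res.instability.min() == pytest.approx(0.0, abs=1e-12)

    def test_half_frequency_edge_contributes_half(self):
        # direct formula check: theta = 0.5 -> 2 * 0.5 * 0.5 = 0.5
        theta = 0.5
        assert 2 * theta * (1 - theta) == 0.5

    def test_seed_determinism(self, small_table):
        clr = clr_transform(small_table)
        r1 = stars_select(clr, n_subsamples=8, seed=3)
        r2 = stars_select(clr, n_subsamples=8, seed=3)
        assert r1.selected_lambda == r2.selected_lambda
        assert np.array_equal(r1.selection_freq, r2.selection_freq)

    def test_permutation_null_yields_nearly_empty_networks(self):
        """Independently shuffling each taxon's CLR column destroys the
        associations, so inferred networks should be essentially empty."""
        from miconet import CohortDesign, infer_network, sample_counts
        from miconet.synthetic import make_true_model

        model = make_true_model(20, "erdos_renyi", edge_density=0.25, seed=2)
        design = CohortDesign(
            n_baseline=300, n_post=300,
            depth_mean=50_000, depth_min=50_000, depth_max=50_000, seed=2,
        )
        clr = clr_transform(sample_counts(model, design))
        base = stars_select(clr, n_subsamples=20, seed=4)
        net = infer_network(clr, stars=base)
        n_edges = net.number_of_edges()
        assert n_edges > 0
        rng = np.random.default_rng(4)
        perm_edges = []
        for _ in range(10):
            x = clr.to_array().copy()
            for j in range(x.shape[1]):
                rng.shuffle(x[:, j])
            stars = stars_select(x, n_subsamples=20, seed=5)
            coefs = neighborhood_fit(x, stars.selected_lambda)
            g = network_from_coefs(coefs, [f"t{i}" for i in range(x.shape[1])])
            perm_edges.append(g.number_of_edges())
        assert np.mean(perm_edges) <= 0.05 * n_edges + 1e-9


class TestNetworkFromCoefs:
    def test_all_zero_matrix_gives_empty_network_full_node_set(self):
        g = network_from_coefs(np.zeros((4, 4)), ["a", "b", "c", "d"])
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b", "c", "d"}

    def test_or_and_rules_and_weight_arithmetic(self):
        coefs = np.zeros((3, 3))
        coefs[0, 1] = 0.4  # taxon a predicts taxon b
        g_or = network_from_coefs(coefs, ["a", "b", "c"], symmetrization="OR")
        assert g_or.edges["a", "b"]["weight"] == pytest.approx(0.2)
        g_and = network_from_coefs(coefs, ["a", "b", "c"], symmetrization="AND")
        assert g_and.number_of_edges() == 0

    def test_symmetric_coefficients_same_weight_under_both_rules(self):
        coefs = np.zeros((3, 3))
        coefs[0, 1] = coefs[1, 0] = 0.3
        for sym in ("OR", "AND"):
            g = network_from_coefs(coefs, ["a", "b", "c"], symmetrization=sym)
            assert g.edges["a", "b"]["weight"] == pytest.approx(0.3)
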