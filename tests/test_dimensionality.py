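"""Polychoric eigenstructure, empirical Kaiser criterion, Mokken/AISP."""

import math

import numpy as np
import pytest

from polygrade.data_model import ResponseMatrix, ValidationError
from polygrade.dimensionality import (aisp, empirical_kaiser, mokken_scalability,
                                      nearest_psd_correlation, polychoric_matrix,
                                      polychoric_corr_from_table)
from polygrade.irt import ItemParameters
from polygrade.simulate import GeneratingSpec, simulate_grm


class TestPolychoric:
    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 4, size=(10_000, 2))
        data = ResponseMatrix(values=values, item_names=["a", "b"])
        R = polychoric_matrix(data)
        assert abs(R[0, 1]) < 0.05

    def test_known_rho_recovered_and_matches_grid_search(self):
        """Discretized bivariate normal with rho=0.6; grid-search ML oracle."""
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=50_000)
        cuts = [-0.5, 0.7]
        x = np.digitize(z[:, 0], cuts)
        y = np.digitize(z[:, 1], cuts)
        table = np.zeros((3, 3))
        np.add.at(table, (x, y), 1.0)
        rho_hat = polychoric_corr_from_table(table)
        assert abs(rho_hat - 0.6) < 0.02
        # independent oracle: coarse-to-fine grid search of the same likelihood
        from scipy.stats import multivariate_normal, norm
        tau_r = np.concatenate([[-12], norm.ppf(np.cumsum(table.sum(1))[:-1]
                                                / table.sum()), [12]])
        tau_c = np.concatenate([[-12], norm.ppf(np.cumsum(table.sum(0))[:-1]
                                                / table.sum()), [12]])

        def ll(r):
            mvn = multivariate_normal([0, 0], [[1, r], [r, 1]])
            R, C = np.meshgrid(tau_r, tau_c, indexing="ij")
            G = mvn.cdf(np.stack([R.ravel(), C.ravel()], 1)).reshape(R.shape)
            cell = np.clip(G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1], 1e-12, 1)
            return np.sum(table * np.log(cell))

        grid = np.arange(-0.99, 0.991, 0.001)
        # evaluate near the estimate only (full grid is equivalent but slow)
        window = grid[np.abs(grid - rho_hat) < 0.05]
        best = max(window, key=ll)
        assert abs(rho_hat - best) <= 0.002

    def test_comonotone_items_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, size=4000)
        data = ResponseMatrix(values=np.column_stack([x, x]), item_names=["a", "b"])
        R = polychoric_matrix(data)
        assert R[0, 1] >= 0.99

    def test_single_category_item_named_in_error(self):
        values = np.column_stack([np.zeros(50, dtype=int),
                                  np.arange(50) % 4])
        data = ResponseMatrix(values=values, item_names=["flat", "ok"],
                              n_categories=4)
        with pytest.raises(ValidationError, match="flat"):
            polychoric_matrix(data)

    def test_trace_conservation(self, sim_study):
        R = nearest_psd_correlation(polychoric_matrix(sim_study))
        lam = np.linalg.eigvalsh(R)
        assert math.isclose(lam.sum(), sim_study.n_items, rel_tol=1e-9)
        assert lam.min() > -1e-10


class TestEmpiricalKaiser:
    SAMPLE = np.array([4.97, 0.45, 0.41, 0.39, 0.27, 0.27, 0.21])

    def test_first_reference_matches_printed_value(self):
        res = empirical_kaiser(self.SAMPLE, n=2219, p=7)
        first = (1 + math.sqrt(7 / 2219)) ** 2
        assert math.isclose(res.reference_eigenvalues[0], first, rel_tol=1e-12)
        assert round(res.reference_eigenvalues[0], 1) == 1.1
        assert res.n_retained == 1

    def test_second_reference_near_printed(self):
        res = empirical_kaiser(self.SAMPLE, n=2219, p=7)
        assert abs(res.reference_eigenvalues[1] - 0.37) < 0.02

    def test_rank_one_limit(self):
        lam = np.array([7.0, 0, 0, 0, 0, 0, 0])
        assert empirical_kaiser(lam, n=1000, p=7).n_retained == 1

    def test_references_nonincreasing_for_descending_sample(self):
        res = empirical_kaiser(self.SAMPLE, n=2219, p=7)
        assert np.all(np.diff(res.reference_eigenvalues) <= 1e-12)

    def test_rejects_nondescending(self):
        with pytest.raises(ValidationError):
            empirical_kaiser(np.array([1.0, 2.0, 4.0]), n=100, p=3)


class TestMokken:
    def test_identical_items_h_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, size=2000)
        data = ResponseMatrix(values=np.column_stack([x, x, x]),
                              item_names=["a", "b", "c"])
        res = mokken_scalability(data)
        assert np.allclose(res.Hij[np.triu_indices(3, 1)], 1.0)
        assert math.isclose(res.H, 1.0, abs_tol=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 4, size=(10_000, 2))
        res = mokken_scalability(ResponseMatrix(values=values, item_names=["a", "b"]))
        assert abs(res.Hij[0, 1]) < 0.05

    def test_toy_table_matches_covariance_oracle(self):
        """20 listed responses, 3 items: Hij from direct covariance arithmetic."""
        values = np.array([
            [0, 0, 1], [0, 1, 0], [1, 1, 1], [2, 2, 1], [3, 3, 3],
            [0, 0, 0], [1, 0, 1], [2, 1, 2], [3, 2, 3], [1, 1, 2],
            [2, 3, 2], [0, 1, 1], [3, 3, 2], [2, 2, 2], [1, 2, 1],
            [0, 0, 1], [3, 2, 3], [1, 1, 0], [2, 2, 3], [0, 1, 0],
        ])
        data = ResponseMatrix(values=values, item_names=["a", "b", "c"])
        res = mokken_scalability(data)
        for i in range(3):
            for j in range(i + 1, 3):
                xi, xj = values[:, i].astype(float), values[:, j].astype(float)
                cov = np.mean(xi * xj) - xi.mean() * xj.mean()
                cov_max = np.mean(np.sort(xi) * np.sort(xj)) - xi.mean() * xj.mean()
                assert math.isclose(res.Hij[i, j], cov / cov_max, abs_tol=1e-12)

    def test_zero_variance_item_rejected(self):
        values = np.column_stack([np.ones(50, dtype=int), np.arange(50) % 4])
        data = ResponseMatrix(values=values, item_names=["flat", "ok"],
                              n_categories=4)
        with pytest.raises(ValidationError, match="flat"):
            mokken_scalability(data)


class TestAISP:
    def test_single_scale_on_study_simulation(self, sim_study):
        parts = aisp(sim_study, (0.40, 0.50, 0.60))
        for c, assignment in parts.items():
            assert np.all(assignment == 1), f"bound {c}: {assignment}"

    def test_two_independent_clusters_split(self):
        items = [ItemParameters(name=f"I{j}", a=2.5,
                                b=np.array([-0.5, 0.3, 1.0])) for j in range(3)]
        spec = GeneratingSpec(item_params=items, n_persons=4000)
        d1 = simulate_grm(spec, seed=10)
        d2 = simulate_grm(spec, seed=20)  # independent latent trait
        values = np.hstack([d1.values, d2.values])
        data = ResponseMatrix(values=values,
                              item_names=[f"X{j}" for j in range(6)])
        parts = aisp(data, (0.40,))
        assignment = parts[0.40]
        assert set(assignment[:3]) == {assignment[0]} and assignment[0] > 0
        assert set(assignment[3:]) == {assignment[3]} and assignment[3] > 0
        assert assignment[0] != assignment[3]
        # block structure confirmed by exhaustive pairwise check
        from polygrade.dimensionality import mokken_scalability
        H = mokken_scalability(data).Hij
        within = [H[i, j] for i in range(3) for j in range(i + 1, 3)]
        within += [H[i, j] for i in range(3, 6) for j in range(i + 1, 6)]
        across = [H[i, j] for i in range(3) for j in range(3, 6)]
        assert min(within) > 0.4 and max(np.abs(across)) < 0.2

    def test_unscalable_item_labeled_zero(self):
        rng = np.random.default_rng(5)
        items = [ItemParameters(name=f"I{j}", a=2.5,
                                b=np.array([-0.5, 0.3, 1.0])) for j in range(2)]
        d = simulate_grm(GeneratingSpec(item_params=items, n_persons=3000), seed=6)
        noise = rng.integers(0, 4, size=3000)
        data = ResponseMatrix(values=np.column_stack([d.values, noise]),
                              item_names=["a", "b", "noise"])
        assignment = aisp(data, (0.40,))[0.40]
        assert assignment[2] == 0
        assert assignment[0] == assignment[1] == 1
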