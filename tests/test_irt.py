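"""Response functions, parameter summaries and MML-EM estimation."""

import math

import numpy as np
import pytest
from scipy import optimize

from polygrade.data_model import ResponseMatrix, ValidationError
from polygrade.irt import (ItemParameters, LatentGrid, category_probabilities,
                           classify_slope, fit_mml, loading_from_slope,
                           threshold_spacing)
from polygrade.simulate import GeneratingSpec, simulate_grm


ITEM1 = ItemParameters(name="I1", a=3.98, b=np.array([0.13, 1.09, 1.52]))


class TestCategoryProbabilities:
    def test_boundary_probability_half_at_its_location(self):
        # P(X>=2) = 0.5 exactly when theta = b2
        p = category_probabilities("GRM", ITEM1, 1.09)
        assert math.isclose(p[2] + p[3], 0.5, abs_tol=1e-12)

    def test_direct_logistic_evaluation(self):
        # P(X=0) at theta=0 is 1 - logistic(-a*b1) = 1 - 1/(1+e^{a b1})
        p = category_probabilities("GRM", ITEM1, 0.0)
        expected = 1.0 - 1.0 / (1.0 + math.exp(3.98 * 0.13))
        assert math.isclose(p[0], expected, abs_tol=1e-12)
        assert math.isclose(p[0], 0.6265, abs_tol=5e-4)

    @pytest.mark.parametrize("kind", ["GRM", "GPCM"])
    @pytest.mark.parametrize("theta", [-3.0, -0.7, 0.0, 1.3, 4.0])
    def test_normalization(self, kind, theta):
        p = category_probabilities(kind, ITEM1, theta)
        assert p.min() >= 0
        assert math.isclose(p.sum(), 1.0, abs_tol=1e-12)

    def test_unordered_grm_thresholds_rejected(self):
        bad = ItemParameters(name="x", a=1.0, b=np.array([1.0, 0.5, 2.0]))
        with pytest.raises(ValidationError):
            category_probabilities("GRM", bad, 0.0)

    def test_boundary_derivative_identity(self):
        """d/dtheta P(X>=k) equals a * P* (1 - P*) for the GRM."""
        h = 1e-6
        for theta in (-1.0, 0.3, 1.5):
            for k in (1, 2, 3):
                up = category_probabilities("GRM", ITEM1, theta + h)[k:].sum()
                dn = category_probabilities("GRM", ITEM1, theta - h)[k:].sum()
                pstar = category_probabilities("GRM", ITEM1, theta)[k:].sum()
                assert math.isclose((up - dn) / (2 * h),
                                    ITEM1.a * pstar * (1 - pstar), abs_tol=1e-6)


class TestParameterSummaries:
    @pytest.mark.parametrize("a,expected", [(3.98, 0.92), (2.48, 0.82), (0.0, 0.0)])
    def test_loading_conversion(self, a, expected):
        assert round(loading_from_slope(a), 2) == expected

    def test_loading_monotone_and_bounded(self):
        grid = np.linspace(0, 10, 50)
        f = np.array([loading_from_slope(a) for a in grid])
        assert np.all(np.diff(f) > 0)
        assert f[0] == 0 and f[-1] < 1

    @pytest.mark.parametrize("a,label", [
        (3.98, "very high"), (1.0, "moderate"), (0.64, "low"), (0.65, "moderate"),
        (1.34, "moderate"), (1.35, "high"), (1.69, "high"), (1.70, "very high"),
    ])
    def test_slope_classification_bands(self, a, label):
        assert classify_slope(a) == label

    def test_threshold_spacing_published_values(self, gad7_items):
        sp = threshold_spacing(gad7_items)
        assert math.isclose(sp["delta_12"][0], -0.96, abs_tol=1e-9)
        assert math.isclose(sp["delta_23"][0], -0.43, abs_tol=1e-9)
        assert round(sp["mean_delta_23"], 2) == -0.57
        assert round(sp["mean_delta_12"], 2) == -0.96
        assert not sp["disordered"].any()

    def test_equal_thresholds_not_flagged(self):
        it = ItemParameters(name="x", a=1.0, b=np.array([0.5, 0.5, 0.5]))
        sp = threshold_spacing([it])
        assert sp["delta_12"][0] == 0 and not sp["disordered"][0]


def _independent_grm_marginal_ll(values, a, b_list, grid):
    """Independent GRM marginal log-likelihood (direct formula, no EM code)."""
    nodes, w = grid.nodes, grid.weights
    n, p = values.shape
    L = np.zeros((n, nodes.size))
    for j in range(p):
        bj = b_list[j]
        pstar = 1.0 / (1.0 + np.exp(-a[j] * (nodes[None, :] - bj[:, None])))
        probs = np.vstack([1 - pstar[0],
                           pstar[0] - pstar[1],
                           pstar[1] - pstar[2],
                           pstar[2]])
        L += np.log(np.clip(probs, 1e-300, 1.0))[values[:, j], :]
    mx = L.max(axis=1, keepdims=True)
    return float(np.sum(mx[:, 0] + np.log(np.exp(L - mx) @ w)))


class TestFitMML:
    def test_em_matches_direct_numerical_maximization(self, small_grid):
        """EM optimum equals brute-force ML on a small 3-item instance."""
        items = [ItemParameters(name=f"I{j}", a=a, b=np.array(b))
                 for j, (a, b) in enumerate([(2.0, (-0.5, 0.5, 1.2)),
                                             (1.4, (0.0, 0.8, 1.6)),
                                             (2.6, (-1.0, 0.2, 1.0))])]
        data = simulate_grm(GeneratingSpec(item_params=items, n_persons=200), seed=4)
        fit = fit_mml(data, "GRM", grid=small_grid, tol=1e-9, max_iter=2000,
                      compute_se=False)

        def pack(a, bs):
            out = []
            for j in range(3):
                d = np.diff(bs[j])
                out += [math.log(a[j]), bs[j][0], *np.log(d)]
            return np.array(out)

        def unpack(x):
            a, bs = [], []
            for j in range(3):
                seg = x[4 * j : 4 * j + 4]
                a.append(math.exp(seg[0]))
                bs.append(np.concatenate([[seg[1]], seg[1] + np.cumsum(np.exp(seg[2:]))]))
            return np.array(a), bs

        def nll(x):
            a, bs = unpack(x)
            return -_independent_grm_marginal_ll(data.values, a, bs, small_grid)

        x0 = pack(np.array([it.a for it in items]), [it.b for it in items])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-8,
                                         "fatol": 1e-10})
        res = optimize.minimize(nll, res.x, method="BFGS", options={"gtol": 1e-10})
        assert fit.loglik >= -res.fun - 1e-4
        assert abs(fit.loglik - (-res.fun)) < 1e-3

    def test_em_loglik_monotone(self, grm_study):
        diffs = np.diff(grm_study.ll_history)
        assert np.all(diffs > -1e-6)
        assert grm_study.converged

    def test_constrained_never_beats_free_grm(self, sim_study, grm_study):
        cons = fit_mml(sim_study, "GRM_constrained", compute_se=False)
        assert cons.loglik <= grm_study.loglik + 1e-6
        assert cons.k == 22 and grm_study.k == 28
        # single common slope
        assert len({round(it.a, 10) for it in cons.items}) == 1

    def test_parameter_counts_per_kind(self, sim_study, grm_study):
        assert grm_study.k == 28  # 7 items x (slope + 3 thresholds)
        rsm = fit_mml(sim_study, "RSM", compute_se=False, tol=1e-3)
        assert rsm.k == 10  # common slope + 7 locations + 2 free steps

    def test_empty_category_collapsed(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 2, size=(300, 3)) * 3  # only categories 0 and 3
        data = ResponseMatrix(values=values, item_names=["a", "b", "c"],
                              n_categories=4)
        fit = fit_mml(data, "GRM", compute_se=False, tol=1e-4)
        assert fit.category_remaps  # remap logged
        assert all(it.n_categories == 2 for it in fit.items)

    def test_constant_item_rejected(self):
        values = np.zeros((100, 3), dtype=int)
        values[:, :2] = np.random.default_rng(1).integers(0, 4, size=(100, 2))
        data = ResponseMatrix(values=values, item_names=["a", "b", "c"],
                              n_categories=4)
        with pytest.raises(ValidationError, match="fewer than 2 observed"):
            fit_mml(data, "GRM")

    def test_slope_recovery_single_seed(self, recovery_fits, gad7_items):
        """Estimated slopes sit within two printed SEs of the generating values."""
        _, fit = recovery_fits[0]
        for est, gen in zip(fit.items, gad7_items):
            assert abs(est.a - gen.a) < 2 * gen.se_a + 1e-9


class TestLatentGrid:
    def test_weights_normalized_and_nodes_increasing(self):
        g = LatentGrid.standard_normal(61, 6.0)
        assert math.isclose(g.weights.sum(), 1.0, abs_tol=1e-12)
        assert np.all(np.diff(g.nodes) > 0)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValidationError):
            LatentGrid(nodes=np.array([0.0, 0.0]), weights=np.array([0.5, 0.5]))
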