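"""EAP scoring, information curves, conditional and empirical reliability."""

import itertools
import math

import numpy as np
import pytest

from polygrade.data_model import ResponseMatrix
from polygrade.irt import FittedModel, ItemParameters, LatentGrid
from polygrade.scoring import eap_scores, information_curves, reliability
from polygrade.simulate import gad7_item_parameters


def _truth_model(items=None, grid=None) -> FittedModel:
    items = items or gad7_item_parameters()
    return FittedModel(kind="GRM", items=items, loglik=0.0, k=4 * len(items),
                       grid=grid or LatentGrid.standard_normal(),
                       converged=True, n_iterations=0, n_persons=0)


def _dense_eap_oracle(items, pattern):
    """EAP by dense 2001-node integration with the direct GRM formula."""
    nodes = np.linspace(-6, 6, 2001)
    w = np.exp(-0.5 * nodes**2)
    w /= w.sum()
    post = w.copy()
    for it, x in zip(items, pattern):
        pstar = 1 / (1 + np.exp(-it.a * (nodes[None, :] - it.b[:, None])))
        probs = np.vstack([1 - pstar[0], pstar[0] - pstar[1],
                           pstar[1] - pstar[2], pstar[2]])
        post *= probs[x]
    post /= post.sum()
    return float(post @ nodes)


class TestEAP:
    def test_empty_pattern_recovers_prior(self):
        model = _truth_model()
        values = np.zeros((1, 7), dtype=int)
        mask = np.ones_like(values, dtype=bool)
        # a second person keeps items from being all-missing
        values = np.vstack([values, np.ones((1, 7), dtype=int)])
        mask = np.vstack([mask, np.zeros((1, 7), dtype=bool)])
        data = ResponseMatrix(values=values, n_categories=4,
                              item_names=[it.name for it in model.items],
                              missing_mask=mask)
        sc = eap_scores(model, data)
        assert abs(sc.eap[0]) < 1e-10
        assert abs(sc.psd[0] - 1.0) < 0.01  # prior SD on the truncated grid
        assert sc.all_missing[0] and not sc.all_missing[1]

    @pytest.mark.parametrize("pattern", [
        (0, 0, 0, 0, 0, 0, 0), (3, 3, 3, 3, 3, 3, 3),
        (1, 0, 2, 1, 0, 1, 2), (2, 3, 1, 2, 3, 2, 1),
    ])
    def test_matches_dense_quadrature_oracle(self, pattern):
        items = gad7_item_parameters()
        model = _truth_model(items)
        data = ResponseMatrix(values=np.array([pattern]), n_categories=4,
                              item_names=[it.name for it in items])
        sc = eap_scores(model, data)
        assert abs(sc.eap[0] - _dense_eap_oracle(items, pattern)) < 1e-4

    def test_all_max_pattern_above_thresholds(self):
        items = gad7_item_parameters()
        model = _truth_model(items)
        data = ResponseMatrix(values=np.full((1, 7), 3), n_categories=4,
                              item_names=[it.name for it in items])
        sc = eap_scores(model, data)
        assert sc.eap[0] > 1.5

    def test_eap_monotone_in_raw_score_three_items(self):
        """All 64 patterns of a 3-item scale: EAP never decreases when the
        raw total increases (positive slopes)."""
        items = gad7_item_parameters()[:3]
        model = _truth_model(items)
        patterns = np.array(list(itertools.product(range(4), repeat=3)))
        data = ResponseMatrix(values=patterns, n_categories=4,
                              item_names=[it.name for it in items])
        sc = eap_scores(model, data)
        totals = patterns.sum(axis=1)
        for t in range(totals.max()):
            assert sc.eap[totals == t + 1].min() > sc.eap[totals == t].max() - 0.5
        # group means strictly increase
        means = [sc.eap[totals == t].mean() for t in range(totals.max() + 1)]
        assert np.all(np.diff(means) > 0)


class TestInformation:
    def test_nonnegative_and_additive(self):
        model = _truth_model()
        res = information_curves(model)
        assert np.all(res.item_information >= 0)
        assert np.allclose(res.test_information,
                           res.item_information.sum(axis=0))

    def test_doubling_slope_quadruples_peak_information(self):
        """Single-boundary item: information scales ~ a^2 at the peak."""
        it1 = ItemParameters(name="x", a=1.0, b=np.array([0.0]))
        it2 = ItemParameters(name="x", a=2.0, b=np.array([0.0]))
        g = LatentGrid.standard_normal(241, 6.0)
        i1 = information_curves(_truth_model([it1, it1], g)).item_information[0]
        i2 = information_curves(_truth_model([it2, it2], g)).item_information[0]
        mid = np.argmin(np.abs(g.nodes))
        assert math.isclose(i2[mid] / i1[mid], 4.0, rel_tol=1e-6)

    def test_study_information_peaks(self):
        """Test information peaks near the trait mean and around 1.5."""
        model = _truth_model()
        res = information_curves(model)
        nodes, info = res.info_grid, res.test_information
        inner = (nodes > -1.5) & (nodes < 3.0)
        # local maxima of the curve restricted to the plausible range
        peaks = [nodes[i] for i in range(1, len(nodes) - 1)
                 if inner[i] and info[i] >= info[i - 1] and info[i] >= info[i + 1]]
        assert any(-0.2 <= p <= 0.3 for p in peaks)
        assert any(1.0 <= p <= 1.9 for p in peaks)


class TestReliability:
    def test_conditional_reliability_form(self):
        model = _truth_model()
        sc = eap_scores(model, ResponseMatrix(
            values=np.array([[1, 1, 1, 1, 1, 1, 1], [2, 2, 2, 2, 2, 2, 2]]),
            n_categories=4, item_names=[it.name for it in model.items]))
        sc = reliability(model, sc)
        r = sc.conditional_reliability
        i = sc.test_information
        assert np.allclose(r, i / (i + 1))
        assert np.all((r >= 0) & (r < 1))

    def test_high_reliability_band(self):
        """Conditional reliability >= 0.80 over a wide band whose edges fall
        near -1 on the left and near 2.5 on the right."""
        model = _truth_model()
        res = information_curves(model)
        r = res.test_information / (res.test_information + 1)
        nodes = res.info_grid
        assert np.all(r[(nodes >= -0.5) & (nodes <= 2.3)] >= 0.80)
        above = nodes[r >= 0.80]
        assert -1.1 <= above.min() <= -0.4
        assert 2.2 <= above.max() <= 2.7

    def test_empirical_reliability_on_study_fit(self, recovery_fits):
        data, fit = recovery_fits[0]
        sc = reliability(fit, eap_scores(fit, data))
        assert 0.80 <= sc.empirical_reliability <= 0.90

    def test_empirical_reliability_increases_with_items(self):
        items = gad7_item_parameters()
        from polygrade.simulate import GeneratingSpec, simulate_grm

        rels = []
        for subset in (items[:3], items):
            data = simulate_grm(GeneratingSpec(item_params=subset,
                                               n_persons=3000), seed=21)
            model = _truth_model(subset)
            sc = reliability(model, eap_scores(model, data))
            rels.append(sc.empirical_reliability)
        assert 0 < rels[0] < rels[1] <= 1
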