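"""EAP scoring, information curves and reliability.

Person scores are expected a posteriori (EAP) means of the latent trait
under the standard-normal prior and the fitted measurement model, with
posterior standard deviations as their uncertainty. Test information is the
pointwise sum of item Fisher informations; conditional reliability is
``I(theta) / (I(theta) + 1)`` (prior variance 1), and the single-number
empirical reliability is ``var(EAP) / (var(EAP) + mean(PSD^2))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ResponseMatrix
from .irt import FittedModel, LatentGrid, _adjacent_probs, _grm_probs, _PMIN

__all__ = ["ScoreResult", "eap_scores", "information_curves", "reliability"]


@dataclass
class ScoreResult:
    eap: np.ndarray
    psd: np.ndarray
    all_missing: np.ndarray
    item_information: np.ndarray | None = None  # (p, q)
    test_information: np.ndarray | None = None  # (q,)
    info_grid: np.ndarray | None = None
    conditional_reliability: np.ndarray | None = None
    empirical_reliability: float | None = None
    extras: dict = field(default_factory=dict)


def _item_prob_fn(kind: str):
    return _grm_probs if kind in ("GRM", "GRM_constrained") else _adjacent_probs


def posterior_over_grid(model: FittedModel, data: ResponseMatrix,
                        grid: LatentGrid | None = None) -> np.ndarray:
    """(n, q) posterior weights of each person over the grid nodes."""
    grid = grid or model.grid
    fn = _item_prob_fn(model.kind)
    n, q = data.n_persons, grid.nodes.size
    L = np.zeros((n, q))
    for j, item in enumerate(model.items):
        logP = np.log(np.maximum(fn(item.a, item.b, grid.nodes), _PMIN))
        ok = ~data.missing_mask[:, j]
        vj = np.minimum(data.values[ok, j], item.n_categories - 1)
        L[ok] += logP[vj, :]
    L += np.log(grid.weights)[None, :]
    L -= L.max(axis=1, keepdims=True)
    post = np.exp(L)
    post /= post.sum(axis=1, keepdims=True)
    return post


def eap_scores(model: FittedModel, data: ResponseMatrix,
               grid: LatentGrid | None = None) -> ScoreResult:
    """Posterior mean (EAP) and SD of theta for every person.

    Persons with no observed responses recover the prior: EAP 0, PSD equal
    to the prior SD on the grid (1 for the standard-normal default); they
    are flagged in ``all_missing``.
    """
    grid = grid or model.grid
    post = posterior_over_grid(model, data, grid)
    eap = post @ grid.nodes
    second = post @ grid.nodes**2
    psd = np.sqrt(np.maximum(second - eap**2, 1e-12))
    all_missing = data.missing_mask.all(axis=1)
    return ScoreResult(eap=eap, psd=psd, all_missing=all_missing)


def information_curves(model: FittedModel, grid: LatentGrid | None = None) -> ScoreResult:
    """Item and test Fisher information over the latent grid.

    Item information is the variance of the score function,
    ``I_i(theta) = sum_k P_k'(theta)^2 / P_k(theta)``; category-probability
    derivatives are analytic for the GRM and central finite differences for
    the adjacent-category family. Test information is the pointwise sum.
    """
    grid = grid or model.grid
    nodes = grid.nodes
    fn = _item_prob_fn(model.kind)
    infos = []
    for item in model.items:
        P = np.maximum(fn(item.a, item.b, nodes), _PMIN)
        if model.kind in ("GRM", "GRM_constrained"):
            z = item.a * (nodes[None, :] - np.asarray(item.b)[:, None])
            ps = 1.0 / (1.0 + np.exp(-z))
            dps = item.a * ps * (1 - ps)  # d/dtheta of boundary curves
            m = len(item.b) + 1
            dP = np.empty((m, nodes.size))
            dP[0] = -dps[0]
            for k in range(1, m - 1):
                dP[k] = dps[k - 1] - dps[k]
            dP[m - 1] = dps[m - 2]
        else:
            h = 1e-5
            dP = (fn(item.a, item.b, nodes + h) - fn(item.a, item.b, nodes - h)) / (2 * h)
        infos.append(np.sum(dP**2 / P, axis=0))
    item_info = np.vstack(infos)
    return ScoreResult(
        eap=np.array([]), psd=np.array([]), all_missing=np.array([], dtype=bool),
        item_information=item_info, test_information=item_info.sum(axis=0),
        info_grid=nodes,
    )


def reliability(model: FittedModel, scores: ScoreResult,
                grid: LatentGrid | None = None) -> ScoreResult:
    """Conditional reliability curve and empirical reliability scalar."""
    grid = grid or model.grid
    curves = information_curves(model, grid)
    info = curves.test_information
    cond = info / (info + 1.0)
    v = float(np.var(scores.eap))
    if v <= 0:
        warnings.warn("EAP variance is zero; empirical reliability set to 0")
        emp = 0.0
    else:
        emp = v / (v + float(np.mean(scores.psd**2)))
    scores.item_information = curves.item_information
    scores.test_information = info
    scores.info_grid = curves.info_grid
    scores.conditional_reliability = cond
    scores.empirical_reliability = emp
    return scores
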