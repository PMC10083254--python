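"""Per-item fit (generalized S-chi^2) and local-dependence screening (JSI).

S-chi^2 compares observed category frequencies within rest-score groups to
model-implied frequencies, where the rest-score distribution conditional on
theta is obtained by recursive convolution of the other items' category
probabilities over the quadrature grid. Groups whose expected cell counts
fall below 1 are collapsed toward the nearest group.

The Jackknife Slope Index screens for local dependence: removing an item
and refitting, the change in another item's slope in standard-error units
(``JSI_ij = (a_j - a_j^(-i)) / se(a_j^(-i))``) is large when the pair
shares variance beyond the latent trait. Pairs whose index exceeds the
sample mean plus a multiplier (default 2.58, two-sided p < .01) times the
SD of all pairwise indices are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .data_model import ResponseMatrix
from .irt import FittedModel, LatentGrid, _adjacent_probs, _grm_probs, fit_mml
from .global_fit import rmsea_from_m2

__all__ = ["ItemFitResult", "JSIMatrix", "collapse_expected_table", "s_x2",
           "jsi", "jsi_threshold"]


@dataclass
class ItemFitResult:
    item: str
    sx2: float
    df: int
    p_value: float
    item_rmsea: float
    n_groups: int
    untestable: bool = False


@dataclass
class JSIMatrix:
    values: np.ndarray  # (p, p), NaN diagonal; symmetric, larger-magnitude direction
    directional: np.ndarray  # (p, p): entry [i, j] = JSI_ij (item i removed)
    mean: float
    sd: float
    threshold: float
    flagged_pairs: list[tuple[int, int]]
    item_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# S-chi^2
# ---------------------------------------------------------------------------

def collapse_expected_table(O: np.ndarray, E: np.ndarray,
                            min_expected: float = 1.0):
    """Deterministic collapsing of an observed/expected frequency table.

    Rows (rest-score groups) with no observations are dropped; rows whose
    total expected count is below ``m * min_expected`` merge into the
    nearest remaining row; within each row, cells expected below
    ``min_expected`` merge into the adjacent cell with the larger
    expectation. Returns ``(rows, n_groups, collapsed_cells)`` where
    ``rows`` is a list of (observed, expected) vectors.
    """
    m = O.shape[1]
    rows = [(O[s].copy(), E[s].copy()) for s in range(O.shape[0])
            if O[s].sum() > 0]
    # row-level merging on total expected mass
    changed = True
    while changed and len(rows) > 1:
        changed = False
        for idx, (o, e) in enumerate(rows):
            if e.sum() < m * min_expected:
                tgt = idx + 1 if idx < len(rows) - 1 else idx - 1
                rows[tgt] = (rows[tgt][0] + o, rows[tgt][1] + e)
                del rows[idx]
                changed = True
                break
    # cell-level merging within rows
    collapsed_cells = 0
    out = []
    for o, e in rows:
        o, e = list(o), list(e)
        while len(e) > 1 and min(e) < min_expected:
            i = int(np.argmin(e))
            if i == 0:
                j = 1
            elif i == len(e) - 1:
                j = i - 1
            else:
                j = i - 1 if e[i - 1] >= e[i + 1] else i + 1
            e[j] += e[i]
            o[j] += o[i]
            del e[i], o[i]
            collapsed_cells += 1
        out.append((np.asarray(o), np.asarray(e)))
    return out, len(out), collapsed_cells


def _rest_score_distribution(probs: list[np.ndarray]) -> np.ndarray:
    """(S_max+1, q) distribution of the sum of item scores given theta."""
    q = probs[0].shape[1]
    dist = np.ones((1, q))
    for P in probs:
        m = P.shape[0]
        new = np.zeros((dist.shape[0] + m - 1, q))
        for k in range(m):
            new[k : k + dist.shape[0]] += P[k] * dist
        dist = new
    return dist


def s_x2(model: FittedModel, data: ResponseMatrix) -> list[ItemFitResult]:
    """Generalized S-chi^2 item-fit statistics.

    Uses persons with complete response vectors (rest scores are undefined
    otherwise). Expected tables come from the model-implied joint
    distribution of (item category, rest score) integrated over the grid.
    """
    fn = _grm_probs if model.kind in ("GRM", "GRM_constrained") else _adjacent_probs
    grid = model.grid
    w = grid.weights
    complete = ~data.missing_mask.any(axis=1)
    values = data.values[complete]
    n = values.shape[0]
    p = data.n_items
    probs = [fn(it.a, it.b, grid.nodes) for it in model.items]
    results = []
    for j, item in enumerate(model.items):
        m = item.n_categories
        others = [probs[t] for t in range(p) if t != j]
        rest = _rest_score_distribution(others)  # (S+1, q)
        smax = rest.shape[0] - 1
        # joint P(X_j = k, S = s) and observed counts
        joint = np.einsum("kq,sq,q->sk", probs[j], rest, w)  # (S+1, m)
        rest_obs = values.sum(axis=1) - values[:, j]
        O = np.zeros((smax + 1, m))
        np.add.at(O, (rest_obs, np.minimum(values[:, j], m - 1)), 1.0)
        row_n = O.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = joint / joint.sum(axis=1, keepdims=True)
        E = row_n[:, None] * cond
        rows, n_groups, collapsed_cells = collapse_expected_table(O, E)
        item_params = m  # slope + m-1 locations (shared-slope models: upper bound)
        df = sum(len(e) - 1 for _, e in rows) - item_params
        if n_groups < 2 or df < 1:
            results.append(ItemFitResult(item=item.name, sx2=np.nan, df=0,
                                         p_value=np.nan, item_rmsea=np.nan,
                                         n_groups=n_groups, untestable=True))
            continue
        stat = float(sum(np.sum((o - e) ** 2 / e) for o, e in rows))
        pval = float(chi2.sf(stat, df))
        results.append(ItemFitResult(item=item.name, sx2=stat, df=df, p_value=pval,
                                     item_rmsea=rmsea_from_m2(stat, df, n),
                                     n_groups=n_groups))
    return results


# ---------------------------------------------------------------------------
# Jackknife Slope Index
# ---------------------------------------------------------------------------

def jsi_threshold(values: np.ndarray, multiplier: float = 2.58) -> tuple[float, float, float]:
    """(mean, sd, threshold) of the reported pairwise indices."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return mean, sd, mean + multiplier * sd


def jsi(model_kind: str, data: ResponseMatrix, grid: LatentGrid | None = None,
        multiplier: float = 2.58, full_model: FittedModel | None = None) -> JSIMatrix:
    """Jackknife Slope Index matrix with mean + multiplier*SD flagging.

    The index is computed in both directions for every unordered pair; the
    reported (symmetric) entry is the direction of larger magnitude. The
    threshold uses the signed reported entries; flagging compares absolute
    values to the absolute threshold.
    """
    p = data.n_items
    if p < 3:
        raise ValueError("JSI needs at least 3 items so refits stay identified")
    if full_model is None:
        full_model = fit_mml(data, model_kind, grid=grid, compute_se=False)
    a_full = full_model.slopes
    directional = np.full((p, p), np.nan)
    for i in range(p):
        keep = [t for t in range(p) if t != i]
        sub = data.subset_items(keep)
        try:
            red = fit_mml(sub, model_kind, grid=grid or full_model.grid,
                          compute_se=True)
        except Exception:
            continue  # refit failure: pair entries stay missing
        for pos, j in enumerate(keep):
            se = red.items[pos].se_a
            if se and np.isfinite(se) and se > 0:
                directional[i, j] = (a_full[j] - red.items[pos].a) / se
    reported = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            cand = [x for x in (directional[i, j], directional[j, i]) if np.isfinite(x)]
            if cand:
                val = max(cand, key=abs)
                reported[i, j] = reported[j, i] = val
    iu = np.triu_indices(p, 1)
    vals = reported[iu]
    mean, sd, threshold = jsi_threshold(vals[np.isfinite(vals)], multiplier)
    flagged = [(i, j) for i, j in zip(*iu)
               if np.isfinite(reported[i, j]) and abs(reported[i, j]) > abs(threshold)]
    return JSIMatrix(values=reported, directional=directional, mean=mean, sd=sd,
                     threshold=threshold, flagged_pairs=flagged,
                     item_names=list(data.item_names))
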