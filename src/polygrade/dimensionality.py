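"""Latent dimensionality checks for ordinal item sets.

Two complementary routes are implemented:

* eigenstructure of the inter-item polychoric correlation matrix, judged
  with the empirical Kaiser criterion (sample eigenvalues against
  sampling-adjusted reference values);
* Mokken scalability (H coefficients) with the automated item selection
  procedure (AISP), which greedily partitions items into Mokken scales at a
  sequence of lower bounds ``c``.

Both routes use pairwise-complete observations when responses are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from .data_model import ResponseMatrix, ValidationError

__all__ = [
    "EigenResult",
    "ScalabilityResult",
    "polychoric_matrix",
    "polychoric_corr_from_table",
    "nearest_psd_correlation",
    "empirical_kaiser",
    "mokken_scalability",
    "aisp",
]

_INF = 12.0  # effective infinity for normal thresholds


@dataclass
class EigenResult:
    sample_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_retained: int


@dataclass
class ScalabilityResult:
    Hij: np.ndarray
    Hi: np.ndarray
    H: float
    item_names: list[str]


# ---------------------------------------------------------------------------
# polychoric correlations (two-step maximum likelihood)
# ---------------------------------------------------------------------------

def _thresholds_from_margins(counts: np.ndarray) -> np.ndarray:
    """Normal quantiles of the cumulative marginal proportions (step one)."""
    props = counts / counts.sum()
    cum = np.cumsum(props)[:-1]
    tau = norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    return np.concatenate([[-_INF], tau, [_INF]])


def _cell_probs(tau_r: np.ndarray, tau_c: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for every table cell."""
    mvn = multivariate_normal(mean=[0.0, 0.0],
                              cov=[[1.0, rho], [rho, 1.0]], allow_singular=True)
    R, C = np.meshgrid(tau_r, tau_c, indexing="ij")
    grid = mvn.cdf(np.stack([R.ravel(), C.ravel()], axis=1)).reshape(R.shape)
    probs = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(probs, 1e-12, 1.0)


def polychoric_corr_from_table(table: np.ndarray) -> float:
    """Two-step polychoric correlation from a contingency table.

    Thresholds are fixed at the normal quantiles of the marginal cumulative
    proportions; the correlation is then estimated by maximizing the
    multinomial likelihood over ``rho`` in (-0.999, 0.999).
    """
    table = np.asarray(table, dtype=float)
    tau_r = _thresholds_from_margins(table.sum(axis=1))
    tau_c = _thresholds_from_margins(table.sum(axis=0))

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tau_r, tau_c, rho))))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(data: ResponseMatrix) -> np.ndarray:
    """Inter-item polychoric correlation matrix (pairwise complete)."""
    p = data.n_items
    for j in range(p):
        if (data.observed_counts(j) > 0).sum() < 2:
            raise ValidationError(
                f"item {data.item_names[j]} has a single observed category"
            )
    R = np.eye(p)
    m = data.n_categories
    for i in range(p):
        for j in range(i + 1, p):
            ok = ~(data.missing_mask[:, i] | data.missing_mask[:, j])
            xi, xj = data.values[ok, i], data.values[ok, j]
            table = np.zeros((m, m))
            np.add.at(table, (xi, xj), 1.0)
            # drop empty rows/cols so thresholds stay finite
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            R[i, j] = R[j, i] = polychoric_corr_from_table(table)
    return R


def nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and rescale to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R
    w = np.clip(w, 0.0, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


# ---------------------------------------------------------------------------
# empirical Kaiser criterion
# ---------------------------------------------------------------------------

def empirical_kaiser(sample_eigenvalues: np.ndarray, n: int, p: int) -> EigenResult:
    """Empirical Kaiser criterion retention decision.

    The j-th reference eigenvalue is
    ``((p - sum_{i<j} lambda_i) / (p - j + 1)) * (1 + sqrt(p/n))^2`` and a
    component is retained while the sample eigenvalue exceeds
    ``max(reference, 1)``.
    """
    lam = np.asarray(sample_eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-10):
        raise ValidationError("sample eigenvalues must be in descending order")
    if len(lam) != p:
        raise ValidationError("need exactly p eigenvalues")
    infl = (1.0 + np.sqrt(p / n)) ** 2
    refs = np.empty(p)
    used = 0.0
    for j in range(p):
        refs[j] = (p - used) / (p - j) * infl
        used += lam[j]
    n_retained = 0
    for j in range(p):
        if lam[j] > max(refs[j], 1.0):
            n_retained += 1
        else:
            break
    return EigenResult(sample_eigenvalues=lam, reference_eigenvalues=refs,
                       n_retained=n_retained)


# ---------------------------------------------------------------------------
# Mokken scalability and AISP
# ---------------------------------------------------------------------------

def _pair_covariances(data: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Observed and maximal (Guttman / comonotone) covariances per item pair."""
    p = data.n_items
    cov = np.zeros((p, p))
    covmax = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            ok = ~(data.missing_mask[:, i] | data.missing_mask[:, j])
            xi = data.values[ok, i].astype(float)
            xj = data.values[ok, j].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                name = data.item_names[i if xi.std() == 0 else j]
                raise ValidationError(f"zero-variance item: {name}")
            c = float(np.mean(xi * xj) - xi.mean() * xj.mean())
            # comonotone coupling of the two empirical marginals
            e_max = float(np.mean(np.sort(xi) * np.sort(xj)))
            cmax = e_max - xi.mean() * xj.mean()
            cov[i, j] = cov[j, i] = c
            covmax[i, j] = covmax[j, i] = cmax
    return cov, covmax


def mokken_scalability(data: ResponseMatrix) -> ScalabilityResult:
    """Mokken H coefficients for polytomous items.

    ``Hij = cov(Xi, Xj) / covmax(Xi, Xj)`` where the maximal covariance is
    attained by the comonotone (perfect Guttman ordering) coupling of the
    observed marginals; ``Hi`` and ``H`` are the corresponding ratio-of-sums
    aggregates.
    """
    if data.n_items < 2:
        raise ValidationError("scalability needs at least 2 items")
    cov, covmax = _pair_covariances(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hij = np.where(covmax > 0, cov / np.where(covmax > 0, covmax, 1.0), np.nan)
    np.fill_diagonal(Hij, np.nan)
    Hi = cov.sum(axis=1) / covmax.sum(axis=1)
    iu = np.triu_indices(data.n_items, 1)
    H = float(cov[iu].sum() / covmax[iu].sum())
    return ScalabilityResult(Hij=Hij, Hi=Hi, H=H, item_names=list(data.item_names))


def _scale_H(cov: np.ndarray, covmax: np.ndarray, members: list[int]) -> float:
    tot_c = sum(cov[i, j] for a, i in enumerate(members) for j in members[a + 1:])
    tot_m = sum(covmax[i, j] for a, i in enumerate(members) for j in members[a + 1:])
    return tot_c / tot_m if tot_m > 0 else -np.inf


def aisp(data: ResponseMatrix, lower_bounds=(0.40, 0.50, 0.60)) -> dict[float, np.ndarray]:
    """Automated item selection procedure (classical greedy variant).

    For each lower bound ``c``: seed a scale with the admissible pair
    (``Hij >= c``) of maximal ``Hij``; repeatedly add the unassigned item
    that maximizes the scale's ``H`` among candidates whose ``Hij`` with
    every scale member is positive and whose scalability with the scale is
    at least ``c``; then start further scales from the leftovers. Items in
    no scale are labeled 0.
    """
    cov, covmax = _pair_covariances(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hij = np.where(covmax > 0, cov / np.where(covmax > 0, covmax, 1.0), -np.inf)
    p = data.n_items
    out: dict[float, np.ndarray] = {}
    for c in lower_bounds:
        assignment = np.zeros(p, dtype=int)
        unassigned = set(range(p))
        scale_idx = 0
        while True:
            best_pair, best_h = None, c
            for i in sorted(unassigned):
                for j in sorted(unassigned):
                    if j <= i:
                        continue
                    if Hij[i, j] >= best_h:
                        best_pair, best_h = (i, j), Hij[i, j]
            if best_pair is None:
                break
            scale_idx += 1
            members = list(best_pair)
            unassigned -= set(members)
            while True:
                best_item, best_scale_h = None, -np.inf
                for x in sorted(unassigned):
                    if any(Hij[x, i] <= 0 for i in members):
                        continue
                    hx = sum(cov[x, i] for i in members) / sum(covmax[x, i] for i in members)
                    if hx < c:
                        continue
                    new_h = _scale_H(cov, covmax, members + [x])
                    if new_h > best_scale_h:
                        best_item, best_scale_h = x, new_h
                if best_item is None:
                    break
                members.append(best_item)
                unassigned.remove(best_item)
            assignment[members] = scale_idx
        out[float(c)] = assignment
    return out
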