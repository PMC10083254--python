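"""Limited-information goodness of fit and model comparison.

The global test statistic is the ordinal limited-information statistic
built from first- and second-order margins: univariate free category
proportions (``p * (m-1)`` of them) and bivariate score product-moments
(``p*(p-1)/2``). Residuals between observed and model-implied values are
combined in the quadratic form

    M2 = N * e' [ Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1 ] e

where ``Xi`` is the model-implied asymptotic covariance of the sample
statistics and ``D`` the Jacobian of the implied statistics with respect to
the free item parameters; under the fitted model the statistic is
asymptotically chi-square with ``df = (#statistics) - k``. RMSEA, SRMR and
CFI (against an independence baseline) summarize approximate fit; AIC/BIC
and the Vuong test (distinguishability + superiority) drive selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2, ncx2, norm

from .data_model import ResponseMatrix, ValidationError
from .irt import (FittedModel, _adjacent_probs, _apply_natural, _grm_probs,
                  _natural_params, marginal_loglik_per_person)

__all__ = [
    "FitSummary",
    "VuongResult",
    "m2_star",
    "rmsea_from_m2",
    "rmsea_confidence_interval",
    "information_criteria",
    "srmr_cfi",
    "vuong_compare",
    "fit_summary",
]


@dataclass
class FitSummary:
    M2: float
    df: int
    p_value: float
    RMSEA2: float
    RMSEA2_ci: tuple[float, float]
    SRMR: float | None
    CFI: float | None
    AIC: float
    BIC: float
    LL: float
    N: int
    k: int


@dataclass
class VuongResult:
    omega2: float
    omega2_p: float
    z: float
    z_p: float
    direction: str
    distinguishable: bool


# ---------------------------------------------------------------------------
# model-implied moments over the quadrature grid
# ---------------------------------------------------------------------------

def _model_node_moments(kind: str, a, b, nodes):
    """Per-node category probabilities and first two score moments per item."""
    fn = _grm_probs if kind in ("GRM", "GRM_constrained") else _adjacent_probs
    P, m1, m2 = [], [], []
    for j in range(len(b)):
        Pj = fn(a[j], np.asarray(b[j], dtype=float), nodes)  # (m_j, q)
        ks = np.arange(Pj.shape[0])[:, None]
        P.append(Pj)
        m1.append(np.sum(ks * Pj, axis=0))
        m2.append(np.sum(ks**2 * Pj, axis=0))
    return P, m1, m2


def _stat_index(m_items: list[int]):
    """Enumerate the margin statistics: (item, category) then (item, item)."""
    uni = [(j, k) for j, mj in enumerate(m_items) for k in range(1, mj)]
    biv = [(i, j) for i in range(len(m_items)) for j in range(i + 1, len(m_items))]
    return uni, biv


def _implied_stats(kind, a, b, grid, m_items) -> np.ndarray:
    P, m1, _ = _model_node_moments(kind, a, b, grid.nodes)
    w = grid.weights
    uni, biv = _stat_index(m_items)
    vals = [float(P[j][k] @ w) for j, k in uni]
    vals += [float((m1[i] * m1[j]) @ w) for i, j in biv]
    return np.array(vals)


def _observed_stats(data: ResponseMatrix, m_items: list[int]) -> np.ndarray:
    uni, biv = _stat_index(m_items)
    vals = []
    for j, k in uni:
        ok = ~data.missing_mask[:, j]
        vals.append(float(np.mean(data.values[ok, j] == k)))
    for i, j in biv:
        ok = ~(data.missing_mask[:, i] | data.missing_mask[:, j])
        vals.append(float(np.mean(data.values[ok, i] * data.values[ok, j])))
    return np.array(vals)


def _xi_matrix(kind, a, b, grid, m_items) -> np.ndarray:
    """Asymptotic covariance of the sample margins under the model.

    Statistics are means of per-person quantities g; given theta the items
    are independent, so E[g_a g_b | theta] factorizes across items and
    integrates over the grid.
    """
    P, m1, m2 = _model_node_moments(kind, a, b, grid.nodes)
    w = grid.weights
    uni, biv = _stat_index(m_items)
    stats = [({j: ("ind", k)},) for j, k in uni] + [({i: ("x", None), j: ("x", None)},) for i, j in biv]
    factors = [s[0] for s in stats]
    q = grid.nodes.size
    n_stats = len(factors)

    def factor_value(j, spec) -> np.ndarray:
        typ, k = spec
        return P[j][k] if typ == "ind" else m1[j]

    def merged_value(j, s1, s2) -> np.ndarray:
        t1, k1 = s1
        t2, k2 = s2
        if t1 == "ind" and t2 == "ind":
            return P[j][k1] if k1 == k2 else np.zeros(q)
        if t1 == "ind" and t2 == "x":
            return k1 * P[j][k1]
        if t1 == "x" and t2 == "ind":
            return k2 * P[j][k2]
        return m2[j]

    sigma = np.empty(n_stats)
    for r, f in enumerate(factors):
        prod = np.ones(q)
        for j, spec in f.items():
            prod = prod * factor_value(j, spec)
        sigma[r] = prod @ w

    Xi = np.empty((n_stats, n_stats))
    for r in range(n_stats):
        for s in range(r, n_stats):
            fa, fb = factors[r], factors[s]
            prod = np.ones(q)
            items = set(fa) | set(fb)
            for j in items:
                if j in fa and j in fb:
                    prod = prod * merged_value(j, fa[j], fb[j])
                elif j in fa:
                    prod = prod * factor_value(j, fa[j])
                else:
                    prod = prod * factor_value(j, fb[j])
            e_ab = prod @ w
            Xi[r, s] = Xi[s, r] = e_ab - sigma[r] * sigma[s]
    return Xi


def _jacobian(kind, model: FittedModel, grid, m_items) -> np.ndarray:
    """Numeric Jacobian of the implied statistics wrt the free parameters."""
    p = len(model.items)
    a = model.slopes
    b = [it.b for it in model.items]
    theta0 = _natural_params(kind, a, b, model.tau, p)
    n_par = len(theta0)
    base = _implied_stats(kind, a, b, grid, m_items)
    D = np.empty((len(base), n_par))
    for r in range(n_par):
        h = 1e-5 * max(1.0, abs(theta0[r]))
        up, dn = theta0.copy(), theta0.copy()
        up[r] += h
        dn[r] -= h
        aa_u, bb_u = _apply_natural(kind, up, p, m_items, model.items[0].n_categories)
        aa_d, bb_d = _apply_natural(kind, dn, p, m_items, model.items[0].n_categories)
        D[:, r] = (_implied_stats(kind, aa_u, bb_u, grid, m_items)
                   - _implied_stats(kind, aa_d, bb_d, grid, m_items)) / (2 * h)
    return D


def _quadratic_form(e, Xi, D, N) -> float:
    ridge = 0.0
    for _ in range(6):
        try:
            Xi_r = Xi + ridge * np.eye(len(Xi))
            Xi_inv = np.linalg.inv(Xi_r)
            inner = D.T @ Xi_inv @ D
            W = Xi_inv - Xi_inv @ D @ np.linalg.solve(inner, D.T @ Xi_inv)
            return float(N * e @ W @ e)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular weight matrix in M2; applying ridge")
            ridge = 1e-8 if ridge == 0 else ridge * 100
    raise np.linalg.LinAlgError("M2 weight matrix irreparably singular")


def m2_star(model: FittedModel, data: ResponseMatrix) -> FitSummary:
    """Limited-information global fit statistic and derived indices."""
    m_items = [it.n_categories for it in model.items]
    grid = model.grid
    a = model.slopes
    b = [it.b for it in model.items]
    kind = model.kind
    sigma = _implied_stats(kind, a, b, grid, m_items)
    obs = _observed_stats(data, m_items)
    Xi = _xi_matrix(kind, a, b, grid, m_items)
    D = _jacobian(kind, model, grid, m_items)
    n_stats = len(sigma)
    df = max(n_stats - model.k, 0)
    M2 = _quadratic_form(obs - sigma, Xi, D, data.n_persons)
    pval = float(chi2.sf(M2, df)) if df > 0 else float("nan")
    rmsea = rmsea_from_m2(M2, df, data.n_persons) if df > 0 else float("nan")
    ci = rmsea_confidence_interval(M2, df, data.n_persons) if df > 0 else (np.nan, np.nan)
    aic, bic = information_criteria(model.loglik, model.k, data.n_persons)
    srmr, cfi = srmr_cfi(model, data)
    return FitSummary(M2=M2, df=df, p_value=pval, RMSEA2=rmsea, RMSEA2_ci=ci,
                      SRMR=srmr, CFI=cfi, AIC=aic, BIC=bic, LL=model.loglik,
                      N=data.n_persons, k=model.k)


def rmsea_from_m2(M2: float, df: int, N: int) -> float:
    """``sqrt(max(M2 - df, 0) / (df * (N - 1)))``; undefined for df = 0."""
    if df <= 0:
        return float("nan")
    if N <= 1:
        raise ValidationError("N must exceed 1")
    return float(np.sqrt(max(M2 - df, 0.0) / (df * (N - 1))))


def rmsea_confidence_interval(M2: float, df: int, N: int,
                              level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-inversion confidence interval for RMSEA."""
    alpha = (1 - level) / 2

    def bound(prob, lo_default=0.0):
        f = lambda nc: ncx2.cdf(M2, df, nc) - prob
        if f(0) < 0:
            return lo_default
        hi = max(M2 * 2, df + 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                break
        try:
            return optimize.brentq(f, 0, hi)
        except ValueError:
            return lo_default

    nc_lo = bound(1 - alpha)
    nc_hi = bound(alpha)
    conv = lambda nc: float(np.sqrt(max(nc, 0.0) / (df * (N - 1))))
    return (conv(nc_lo), conv(nc_hi))


def information_criteria(LL: float, k: int, N: int) -> tuple[float, float]:
    """AIC = -2 LL + 2k; BIC = -2 LL + k ln N."""
    if not np.isfinite(LL):
        raise ValidationError("log-likelihood must be finite")
    lnN = np.log(N) if N > 0 and k > 0 else 0.0
    return (-2.0 * LL + 2.0 * k, -2.0 * LL + k * lnN)


# ---------------------------------------------------------------------------
# SRMR / CFI
# ---------------------------------------------------------------------------

def _implied_correlations(kind, a, b, grid) -> np.ndarray:
    P, m1, m2 = _model_node_moments(kind, a, b, grid.nodes)
    w = grid.weights
    p = len(b)
    mu = np.array([m1[j] @ w for j in range(p)])
    var = np.array([m2[j] @ w for j in range(p)]) - mu**2
    C = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            cov = (m1[i] * m1[j]) @ w - mu[i] * mu[j]
            C[i, j] = C[j, i] = cov / np.sqrt(var[i] * var[j])
    return C


def _observed_correlations(data: ResponseMatrix) -> np.ndarray:
    p = data.n_items
    C = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            ok = ~(data.missing_mask[:, i] | data.missing_mask[:, j])
            C[i, j] = C[j, i] = np.corrcoef(data.values[ok, i], data.values[ok, j])[0, 1]
    return C


def _baseline_m2(data: ResponseMatrix, m_items, grid) -> tuple[float, int]:
    """Independence-model statistic on the same margins (CFI baseline).

    The baseline fits each item's marginal proportions freely and implies
    independence for the product moments; its free parameter count is
    ``sum(m_i - 1)``.
    """
    uni, biv = _stat_index(m_items)
    obs = _observed_stats(data, m_items)
    p = data.n_items
    props = []
    for j in range(p):
        counts = data.observed_counts(j)[: m_items[j]].astype(float)
        props.append(counts / counts.sum())

    def stats_from(props_):
        mu = [float(np.arange(m_items[j]) @ props_[j]) for j in range(p)]
        vals = [props_[j][k] for j, k in uni]
        vals += [mu[i] * mu[j] for i, j in biv]
        return np.array(vals)

    sigma = stats_from(props)

    # Xi under independence: univariate multinomial covariances, product
    # moments from independent items.
    n_stats = len(obs)
    Xi = np.zeros((n_stats, n_stats))
    mu = [float(np.arange(m_items[j]) @ props[j]) for j in range(p)]
    m2v = [float((np.arange(m_items[j]) ** 2) @ props[j]) for j in range(p)]

    def e_ind(j, k):  # E[I(Xj=k)]
        return props[j][k]

    nu = len(uni)
    for r, (j1, k1) in enumerate(uni):
        for s, (j2, k2) in enumerate(uni):
            if s < r:
                continue
            if j1 == j2:
                e = props[j1][k1] if k1 == k2 else 0.0
            else:
                e = props[j1][k1] * props[j2][k2]
            Xi[r, s] = Xi[s, r] = e - sigma[r] * sigma[s]
    for rb, (i, j) in enumerate(biv):
        r = nu + rb
        for s, (j2, k2) in enumerate(uni):
            if j2 == i:
                e = k2 * props[i][k2] * mu[j]
            elif j2 == j:
                e = k2 * props[j][k2] * mu[i]
            else:
                e = props[j2][k2] * mu[i] * mu[j]
            Xi[r, s] = Xi[s, r] = e - sigma[r] * sigma[s]
        for sb, (i2, j2) in enumerate(biv):
            s = nu + sb
            if s < r:
                continue
            pair = {i, j, i2, j2}
            e = 1.0
            for it in pair:
                cnt = (it in (i, j)) + (it in (i2, j2))
                e *= m2v[it] if cnt == 2 else mu[it]
            Xi[r, s] = Xi[s, r] = e - sigma[r] * sigma[s]

    # Jacobian wrt free proportions (categories 1..m_i-1 per item)
    free = [(j, k) for j, mj in enumerate(m_items) for k in range(1, mj)]
    D = np.empty((n_stats, len(free)))
    h = 1e-6
    for c, (j, k) in enumerate(free):
        pp_u = [q.copy() for q in props]
        pp_d = [q.copy() for q in props]
        pp_u[j][k] += h
        pp_u[j][0] -= h
        pp_d[j][k] -= h
        pp_d[j][0] += h
        D[:, c] = (stats_from(pp_u) - stats_from(pp_d)) / (2 * h)
    df_base = n_stats - len(free)
    M2b = _quadratic_form(obs - sigma, Xi, D, data.n_persons)
    return M2b, df_base


def srmr_cfi(model: FittedModel, data: ResponseMatrix) -> tuple[float, float | None]:
    """SRMR over inter-item correlation residuals; CFI vs independence."""
    m_items = [it.n_categories for it in model.items]
    a = model.slopes
    b = [it.b for it in model.items]
    C_obs = _observed_correlations(data)
    C_imp = _implied_correlations(model.kind, a, b, model.grid)
    iu = np.triu_indices(data.n_items, 1)
    srmr = float(np.sqrt(np.mean((C_obs[iu] - C_imp[iu]) ** 2)))
    try:
        sigma = _implied_stats(model.kind, a, b, model.grid, m_items)
        obs = _observed_stats(data, m_items)
        Xi = _xi_matrix(model.kind, a, b, model.grid, m_items)
        D = _jacobian(model.kind, model, model.grid, m_items)
        M2 = _quadratic_form(obs - sigma, Xi, D, data.n_persons)
        df = max(len(sigma) - model.k, 0)
        M2b, dfb = _baseline_m2(data, m_items, model.grid)
        denom = max(M2b - dfb, M2 - df, 0.0)
        cfi = 1.0 - max(M2 - df, 0.0) / denom if denom > 0 else 1.0
    except np.linalg.LinAlgError:
        cfi = None
    return srmr, cfi


# ---------------------------------------------------------------------------
# Vuong comparison
# ---------------------------------------------------------------------------

def vuong_compare(model_A: FittedModel, model_B: FittedModel,
                  data: ResponseMatrix, alpha: float = 0.01) -> VuongResult:
    """Two-step Vuong test on pointwise log-likelihood ratios.

    ``omega2`` is the sample variance of the per-person log-likelihood
    ratios; distinguishability is a one-sided normal test of it against
    zero (fourth-moment standard error). Superiority
    ``z = sum(l_i) / (sqrt(n) * omega)`` is only interpreted when
    distinguishability is rejected.
    """
    lA = marginal_loglik_per_person(
        "GRM" if model_A.kind in ("GRM", "GRM_constrained") else "GPCM",
        model_A.slopes, [it.b for it in model_A.items],
        data.values, data.missing_mask, model_A.grid)
    lB = marginal_loglik_per_person(
        "GRM" if model_B.kind in ("GRM", "GRM_constrained") else "GPCM",
        model_B.slopes, [it.b for it in model_B.items],
        data.values, data.missing_mask, model_B.grid)
    li = lA - lB
    n = len(li)
    omega2 = float(np.var(li))
    if omega2 <= 1e-14:
        return VuongResult(omega2=0.0, omega2_p=1.0, z=0.0, z_p=1.0,
                           direction="indistinguishable", distinguishable=False)
    m4 = float(np.mean((li - li.mean()) ** 4))
    se_omega2 = np.sqrt(max(m4 - omega2**2, 1e-300) / n)
    z_omega = omega2 / se_omega2
    omega2_p = float(norm.sf(z_omega))
    z = float(np.sum(li) / (np.sqrt(n) * np.sqrt(omega2)))
    z_p = float(2 * norm.sf(abs(z)))
    disting = omega2_p < alpha
    if not disting:
        direction = "indistinguishable"
    else:
        direction = model_A.kind if z > 0 else model_B.kind
    return VuongResult(omega2=omega2, omega2_p=omega2_p, z=z, z_p=z_p,
                       direction=direction, distinguishable=disting)


def fit_summary(model: FittedModel, data: ResponseMatrix) -> FitSummary:
    """Convenience wrapper: full limited-information summary for one model."""
    return m2_star(model, data)
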