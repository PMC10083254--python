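"""Person fit via the standardized log-likelihood statistic Zh.

For each respondent, the log-likelihood of the observed response pattern at
the person's trait estimate is standardized by its conditional mean and
variance under the fitted model:

    l0    = sum_i log P_{x_i}(theta_hat)
    E[l0] = sum_i sum_k P_k log P_k
    V[l0] = sum_i [ sum_k P_k (log P_k)^2 - (sum_k P_k log P_k)^2 ]
    Zh    = (l0 - E[l0]) / sqrt(V[l0])

Large negative values flag aberrant (model-inconsistent) patterns; large
positive values flag overfitting (unexpectedly deterministic) patterns.
The trait estimate plugged in is the EAP score; the mild conservatism that
induces is documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ResponseMatrix
from .irt import FittedModel, _PMIN, _adjacent_probs, _grm_probs

__all__ = ["PersonFitResult", "zh", "zh_external_check"]


@dataclass
class PersonFitResult:
    zh: np.ndarray
    flag_aberrant: np.ndarray
    flag_overfit: np.ndarray
    prop_aberrant: float
    prop_overfit: float
    undefined: np.ndarray
    cut: float


def zh(model: FittedModel, data: ResponseMatrix, theta: np.ndarray,
       cut: float = 2.0) -> PersonFitResult:
    """Zh statistic per person at the supplied trait estimates."""
    fn = _grm_probs if model.kind in ("GRM", "GRM_constrained") else _adjacent_probs
    n = data.n_persons
    l0 = np.zeros(n)
    mean = np.zeros(n)
    var = np.zeros(n)
    theta = np.asarray(theta, dtype=float)
    for j, item in enumerate(model.items):
        P = np.maximum(fn(item.a, item.b, theta), _PMIN)  # (m, n)
        logP = np.log(P)
        ok = ~data.missing_mask[:, j]
        vj = np.minimum(data.values[:, j], item.n_categories - 1)
        l0[ok] += logP[vj[ok], np.where(ok)[0]]
        e = np.sum(P * logP, axis=0)
        e2 = np.sum(P * logP**2, axis=0)
        mean[ok] += e[ok]
        var[ok] += (e2 - e**2)[ok]
    undefined = var <= 1e-12
    z = np.full(n, np.nan)
    z[~undefined] = (l0[~undefined] - mean[~undefined]) / np.sqrt(var[~undefined])
    aberrant = (z < -cut) & ~undefined
    overfit = (z > cut) & ~undefined
    return PersonFitResult(
        zh=z, flag_aberrant=aberrant, flag_overfit=overfit,
        prop_aberrant=float(aberrant.mean()), prop_overfit=float(overfit.mean()),
        undefined=undefined, cut=cut,
    )


def zh_external_check(pf: PersonFitResult, externals: dict[str, np.ndarray],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations of Zh with external variables, Fisher-z CIs."""
    from scipy.stats import norm

    rows = []
    z = pf.zh
    crit = norm.ppf(1 - alpha / 2)
    for name, vec in externals.items():
        v = np.asarray(vec, dtype=float)
        ok = np.isfinite(z) & np.isfinite(v)
        n = int(ok.sum())
        if n < 4 or np.std(v[ok]) == 0 or np.std(z[ok]) == 0:
            rows.append({"external": name, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": n})
            continue
        r = float(np.corrcoef(z[ok], v[ok])[0, 1])
        fz = np.arctanh(np.clip(r, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(n - 3)
        rows.append({
            "external": name, "r": r,
            "ci_low": float(np.tanh(fz - crit * se)),
            "ci_high": float(np.tanh(fz + crit * se)),
            "n": n,
        })
    return pd.DataFrame(rows)
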