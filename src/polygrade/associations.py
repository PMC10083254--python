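"""External-validity correlations of trait scores with other variables.

Pearson correlations (point-biserial for binary externals coded 0/1) of
EAP scores with convergent and divergent criteria, with Fisher-z 95%
confidence intervals. Because EAP scores are shrunken toward the prior
mean, an observed correlation with an error-free criterion is attenuated
by roughly the square root of the empirical reliability; the attenuation-
corrected estimate is reported alongside the raw value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["correlate_scores", "fisher_ci"]


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return (r, r)
    crit = norm.ppf(0.5 + level / 2)
    fz = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return (float(np.tanh(fz - crit * se)), float(np.tanh(fz + crit * se)))


def correlate_scores(eap: np.ndarray, externals: dict[str, np.ndarray],
                     pairwise: bool = True, alpha: float = 0.05,
                     reliability: float | None = None) -> pd.DataFrame:
    """Association table of EAP scores against each external variable.

    Rows with fewer than 3 complete pairs are reported missing. When an
    empirical reliability is supplied, a disattenuated correlation
    ``r / sqrt(reliability)`` is added.
    """
    eap = np.asarray(eap, dtype=float)
    rows = []
    for name, vec in externals.items():
        v = np.asarray(vec, dtype=float)
        ok = np.isfinite(eap) & np.isfinite(v)
        n = int(ok.sum())
        if n < 3 or np.std(v[ok]) == 0:
            rows.append({"external": name, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": n, "significant": False})
            continue
        r = float(np.corrcoef(eap[ok], v[ok])[0, 1])
        lo, hi = fisher_ci(r, n, level=1 - alpha)
        row = {"external": name, "r": r, "ci_low": lo, "ci_high": hi, "n": n,
               "significant": bool(lo > 0 or hi < 0)}
        if reliability is not None and reliability > 0:
            row["r_disattenuated"] = float(np.clip(r / np.sqrt(reliability), -1, 1))
        rows.append(row)
    return pd.DataFrame(rows)
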