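"""Synthetic ordinal response data with known graded-response structure.

The generator inverts the measurement models estimated elsewhere in the
package: given item discriminations and thresholds, a latent trait draw per
person, and the graded-response (or partial-credit-family) category curves,
it produces a :class:`~polygrade.data_model.ResponseMatrix`. Optional
features mimic the artefacts the validation pipeline is designed to detect:

* differential item functioning, as focal-group threshold shifts and/or a
  focal-group slope ratio on chosen items;
* aberrant responders, who answer uniformly at random regardless of theta;
* external variables with a specified latent correlation to theta
  (``r * theta + sqrt(1 - r^2) * noise``, then affinely mapped to a
  plausible observed scale).

``GAD7_ITEM_PARAMS`` holds the published GAD-7 graded-response estimates
for workers (discriminations 2.48-4.40, thresholds spanning roughly -0.1 to
1.9) and is the default generating configuration, so simulations reproduce
the statistical conditions of that validation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ResponseMatrix, ValidationError
from .irt import ItemParameters, _adjacent_probs, _grm_probs

__all__ = [
    "GeneratingSpec",
    "DIFSpec",
    "ExternalSpec",
    "GAD7_ITEM_PARAMS",
    "gad7_item_parameters",
    "simulate_grm",
    "simulate_pcm_family",
    "model_implied_marginals",
]

# Published GRM estimates for the 7 anxiety items (a, b1, b2, b3) and their
# standard errors (se_a, se_b1, se_b2, se_b3). Single source of truth for
# every simulation-based test in the package.
GAD7_ITEM_PARAMS: tuple[tuple[str, float, tuple[float, float, float],
                              float, tuple[float, float, float]], ...] = (
    ("GAD7_1", 3.98, (0.13, 1.09, 1.52), 0.17, (0.02, 0.03, 0.04)),
    ("GAD7_2", 4.40, (0.13, 1.04, 1.59), 0.20, (0.02, 0.03, 0.04)),
    ("GAD7_3", 3.57, (-0.13, 0.95, 1.57), 0.14, (0.03, 0.03, 0.04)),
    ("GAD7_4", 3.69, (0.02, 1.01, 1.56), 0.15, (0.02, 0.03, 0.04)),
    ("GAD7_5", 2.89, (0.31, 1.19, 1.78), 0.12, (0.03, 0.04, 0.05)),
    ("GAD7_6", 2.48, (0.07, 1.15, 1.87), 0.10, (0.03, 0.04, 0.06)),
    ("GAD7_7", 3.00, (0.49, 1.30, 1.83), 0.13, (0.03, 0.04, 0.05)),
)


def gad7_item_parameters() -> list[ItemParameters]:
    """The default generating item parameters as :class:`ItemParameters`."""
    return [
        ItemParameters(name=name, a=a, b=np.array(b), se_a=se_a, se_b=np.array(se_b))
        for name, a, b, se_a, se_b in GAD7_ITEM_PARAMS
    ]


@dataclass
class DIFSpec:
    """Differential functioning injected for a focal group.

    ``threshold_shift[j]`` is added to every threshold of item ``j`` for the
    focal group (uniform DIF); ``slope_ratio[j]`` multiplies its slope
    (non-uniform DIF). ``focal_proportion`` is the focal group's share of
    the sample.
    """

    threshold_shift: dict[int, float] = field(default_factory=dict)
    slope_ratio: dict[int, float] = field(default_factory=dict)
    focal_proportion: float = 0.5
    group_labels: tuple[str, str] = ("reference", "focal")

    def __post_init__(self) -> None:
        for v in self.threshold_shift.values():
            if not np.isfinite(v):
                raise ValidationError("DIF threshold shifts must be finite")
        if not (0 < self.focal_proportion < 1):
            raise ValidationError("focal_proportion must be in (0, 1)")


@dataclass
class ExternalSpec:
    """External variable correlated with the latent trait.

    Generated as ``r * theta + sqrt(1-r^2) * z`` with standard-normal noise
    ``z``, then mapped to ``loc + scale * value``.
    """

    name: str
    latent_correlation: float
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (-1 < self.latent_correlation < 1):
            raise ValidationError("latent correlation must be in (-1, 1)")


@dataclass
class GeneratingSpec:
    """Full description of a simulated sample."""

    item_params: list[ItemParameters] = field(default_factory=gad7_item_parameters)
    n_persons: int = 2219
    theta_dist: str = "normal"  # or "fixed"
    theta_value: float = 0.0  # used when theta_dist == "fixed"
    dif_spec: DIFSpec | None = None
    aberrant_fraction: float = 0.0
    external_spec: list[ExternalSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.aberrant_fraction < 1):
            raise ValidationError("aberrant_fraction must be in [0, 1)")
        for it in self.item_params:
            if not np.all(np.isfinite(it.b)):
                raise ValidationError(f"non-finite locations for {it.name}")


def _draw_theta(spec: GeneratingSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.theta_dist == "fixed":
        return np.full(spec.n_persons, spec.theta_value)
    if spec.theta_dist == "normal":
        return rng.standard_normal(spec.n_persons)
    raise ValidationError(f"unknown theta distribution: {spec.theta_dist}")


def _attach_side_info(spec, rng, theta, n):
    group = None
    focal = np.zeros(n, dtype=bool)
    if spec.dif_spec is not None:
        focal = rng.random(n) < spec.dif_spec.focal_proportion
        labels = spec.dif_spec.group_labels
        group = np.where(focal, labels[1], labels[0])
    externals: dict[str, np.ndarray] = {}
    for ext in spec.external_spec:
        r = ext.latent_correlation
        z = rng.standard_normal(n)
        raw = r * theta + np.sqrt(1 - r * r) * z
        externals[ext.name] = ext.loc + ext.scale * raw
    return group, focal, externals


def _effective_item(item: ItemParameters, dif: DIFSpec | None, j: int,
                    focal: bool) -> tuple[float, np.ndarray]:
    a, b = item.a, np.asarray(item.b, dtype=float)
    if dif is not None and focal:
        if j in dif.threshold_shift:
            b = b + dif.threshold_shift[j]
        if j in dif.slope_ratio:
            a = a * dif.slope_ratio[j]
    return a, b


def simulate_grm(spec: GeneratingSpec, seed: int) -> ResponseMatrix:
    """Draw graded-response data under the generating spec.

    Each response uses the single-uniform coupling ``X = #{k : u < P(X>=k)}``,
    which is exact for the GRM because the boundary probabilities are
    decreasing in ``k``. Identical seeds yield identical output.
    """
    for it in spec.item_params:
        if len(it.b) > 1 and np.any(np.diff(it.b) <= 0):
            raise ValidationError(
                f"thresholds for {it.name} must be strictly increasing"
            )
    rng = np.random.default_rng(seed)
    n = spec.n_persons
    p = len(spec.item_params)
    theta = _draw_theta(spec, rng)
    group, focal, externals = _attach_side_info(spec, rng, theta, n)
    values = np.zeros((n, p), dtype=np.int64)
    u = rng.random((n, p))
    for j, item in enumerate(spec.item_params):
        for is_focal in (False, True):
            sel = focal == is_focal
            if not sel.any():
                continue
            a, b = _effective_item(item, spec.dif_spec, j, is_focal)
            z = a * (theta[sel, None] - b[None, :])
            pstar = 1.0 / (1.0 + np.exp(-z))  # (n_sel, m-1)
            values[sel, j] = (u[sel, j, None] < pstar).sum(axis=1)
    if spec.aberrant_fraction > 0:
        n_ab = int(round(spec.aberrant_fraction * n))
        ab_rows = rng.choice(n, size=n_ab, replace=False)
        for j, item in enumerate(spec.item_params):
            m = item.n_categories
            values[ab_rows, j] = rng.integers(0, m, size=n_ab)
        externals["is_aberrant"] = np.isin(np.arange(n), ab_rows).astype(float)
    return ResponseMatrix(
        values=values,
        item_names=[it.name for it in spec.item_params],
        n_categories=max(it.n_categories for it in spec.item_params),
        group=group,
        externals=externals,
    )


def simulate_pcm_family(spec: GeneratingSpec, model: str, seed: int) -> ResponseMatrix:
    """Draw adjacent-category (partial-credit family) data.

    ``model`` is one of RSM / PCM / GPCM; thresholds in the spec are read as
    step parameters. RSM additionally requires every item to share the same
    step pattern up to an additive item location; PCM requires equal slopes.
    """
    if model not in ("RSM", "PCM", "GPCM"):
        raise ValidationError(f"not a partial-credit-family model: {model}")
    items = spec.item_params
    if model in ("RSM", "PCM"):
        slopes = {round(it.a, 12) for it in items}
        if len(slopes) != 1:
            raise ValidationError(f"{model} requires a common slope across items")
    if model == "RSM":
        centered = [np.asarray(it.b) - np.mean(it.b) for it in items]
        for c in centered[1:]:
            if not np.allclose(c, centered[0], atol=1e-10):
                raise ValidationError(
                    "RSM requires identical centered step patterns across items"
                )
    rng = np.random.default_rng(seed)
    n = spec.n_persons
    p = len(items)
    theta = _draw_theta(spec, rng)
    group, focal, externals = _attach_side_info(spec, rng, theta, n)
    values = np.zeros((n, p), dtype=np.int64)
    u = rng.random((n, p))
    for j, item in enumerate(items):
        for is_focal in (False, True):
            sel = focal == is_focal
            if not sel.any():
                continue
            a, d = _effective_item(item, spec.dif_spec, j, is_focal)
            P = _adjacent_probs(a, d, theta[sel]).T  # (n_sel, m)
            cum = np.cumsum(P, axis=1)
            values[sel, j] = (u[sel, j, None] > cum).sum(axis=1)
    if spec.aberrant_fraction > 0:
        n_ab = int(round(spec.aberrant_fraction * n))
        ab_rows = rng.choice(n, size=n_ab, replace=False)
        for j, item in enumerate(items):
            values[ab_rows, j] = rng.integers(0, item.n_categories, size=n_ab)
        externals["is_aberrant"] = np.isin(np.arange(n), ab_rows).astype(float)
    return ResponseMatrix(
        values=values,
        item_names=[it.name for it in items],
        n_categories=max(it.n_categories for it in items),
        group=group,
        externals=externals,
    )


def model_implied_marginals(items: list[ItemParameters], kind: str = "GRM",
                            n_nodes: int = 401, bound: float = 8.0) -> np.ndarray:
    """Model-implied marginal category proportions under a N(0,1) trait.

    Numerical integration of the category curves over a dense normal grid;
    the independent oracle for marginal-convergence checks. Returns an
    ``(n_items, m)`` array.
    """
    nodes = np.linspace(-bound, bound, n_nodes)
    w = np.exp(-0.5 * nodes**2)
    w /= w.sum()
    fn = _grm_probs if kind in ("GRM", "GRM_constrained") else _adjacent_probs
    out = []
    for it in items:
        P = fn(it.a, np.asarray(it.b, dtype=float), nodes)  # (m, q)
        out.append(P @ w)
    return np.vstack(out)
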