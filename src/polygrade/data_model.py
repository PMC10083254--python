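"""Core domain containers and delimited-text I/O.

The central object is :class:`ResponseMatrix`: an ``n_persons x n_items``
integer matrix of ordinal item responses coded ``0..m-1`` (for the GAD-7,
``0..3``), with an explicit missingness mask, optional two-level grouping
(for differential item functioning) and optional continuous external
variables aligned to rows (for convergent/divergent validity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "RunConfig",
    "ValidationError",
    "read_responses",
    "write_results_table",
    "read_results_table",
]


class ValidationError(ValueError):
    """Raised when input data violate the response-matrix contract."""


@dataclass
class ResponseMatrix:
    """Ordinal item responses with missingness mask and side information.

    Parameters
    ----------
    values
        Integer matrix ``(n_persons, n_items)``; categories coded ``0..m-1``.
        Entries under the mask are ignored (conventionally set to 0).
    item_names
        Unique item labels, one per column.
    n_categories
        Number of ordered categories ``m``; inferred as ``max + 1`` if None.
    missing_mask
        Boolean matrix, True where the response is missing.
    group
        Optional categorical vector of length ``n_persons`` (two levels for
        DIF analyses).
    externals
        Optional mapping of name -> continuous vector aligned to rows.
    """

    values: np.ndarray
    item_names: list[str]
    n_categories: int | None = None
    missing_mask: np.ndarray | None = None
    group: np.ndarray | None = None
    externals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 2:
            raise ValidationError("at least 2 items are required")
        if n < 1:
            raise ValidationError("at least 1 person is required")
        self.item_names = [str(x) for x in self.item_names]
        if len(self.item_names) != p:
            raise ValidationError("item_names length does not match columns")
        if len(set(self.item_names)) != p:
            raise ValidationError("item_names must be unique")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValidationError("missing_mask shape mismatch")
        obs = self.values[~self.missing_mask]
        if obs.size and obs.min() < 0:
            raise ValidationError("negative category code encountered")
        m_inferred = int(obs.max()) + 1 if obs.size else 2
        if self.n_categories is None:
            self.n_categories = max(m_inferred, 2)
        elif obs.size and obs.max() >= self.n_categories:
            raise ValidationError(
                f"category code {int(obs.max())} outside 0..{self.n_categories - 1}"
            )
        if self.n_categories < 2:
            raise ValidationError("need at least 2 categories")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != n:
                raise ValidationError("group length does not match n_persons")
        for name, vec in self.externals.items():
            v = np.asarray(vec, dtype=float)
            if len(v) != n:
                raise ValidationError(f"external '{name}' length mismatch")
            self.externals[name] = v
        # every item needs at least one observed response
        if bool(self.missing_mask.all(axis=0).any()):
            bad = [self.item_names[j] for j in np.where(self.missing_mask.all(axis=0))[0]]
            raise ValidationError(f"item(s) fully missing: {bad}")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def observed_counts(self, item: int) -> np.ndarray:
        """Category counts for one item over observed responses."""
        ok = ~self.missing_mask[:, item]
        return np.bincount(self.values[ok, item], minlength=self.n_categories)

    def subset_items(self, keep: Sequence[int]) -> "ResponseMatrix":
        keep = list(keep)
        return ResponseMatrix(
            values=self.values[:, keep],
            item_names=[self.item_names[j] for j in keep],
            n_categories=self.n_categories,
            missing_mask=self.missing_mask[:, keep],
            group=self.group,
            externals=dict(self.externals),
        )


@dataclass
class RunConfig:
    """Analysis configuration collecting the pipeline's cut-offs.

    Defaults follow common practice for a 7-item, 4-category screener:
    Mokken AISP lower bounds stepped by 0.10 from 0.40, a 2.58-SD local
    dependence threshold (two-sided p < .01), DIF alpha 0.01 and a person-fit
    cut of |Zh| = 2.
    """

    model_set: tuple[str, ...] = ("RSM", "PCM", "GPCM", "GRM", "GRM_constrained")
    quadrature_nodes: int = 61
    quadrature_range: float = 6.0
    aisp_start: float = 0.40
    aisp_step: float = 0.10
    aisp_stop: float = 0.60
    jsi_multiplier: float = 2.58
    dif_alpha: float = 0.01
    zh_cut: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"RSM", "PCM", "GPCM", "GRM", "GRM_constrained"}
        bad = set(self.model_set) - valid
        if bad:
            raise ValidationError(f"unknown model kind(s): {sorted(bad)}")
        if self.quadrature_nodes < 11:
            raise ValidationError("quadrature needs at least 11 nodes")
        if self.quadrature_range <= 0:
            raise ValidationError("quadrature range must be positive (symmetric about 0)")
        if not (0 < self.aisp_start < 1 and 0 < self.aisp_step < 1):
            raise ValidationError("AISP start and step must lie in (0, 1)")

    @property
    def aisp_bounds(self) -> list[float]:
        bounds = []
        c = self.aisp_start
        while c <= self.aisp_stop + 1e-9:
            bounds.append(round(c, 10))
            c += self.aisp_step
        return bounds


def read_responses(
    path: str | Path,
    item_columns: Sequence[str],
    group_column: str | None = None,
    external_columns: Sequence[str] | None = None,
    n_categories: int | None = None,
    missing_tokens: Sequence[str] = ("NA", "", "nan", "NaN"),
    offset: int = 0,
    sep: str | None = None,
) -> ResponseMatrix:
    """Read a delimited table of ordinal responses.

    ``offset`` is subtracted from every parsed response, so files coded
    1..m can be read with ``offset=1``. ``sep=None`` auto-detects comma vs
    tab from the header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        header = path.open("r", encoding="utf-8").readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_set = set(missing_tokens)
    for col in item_columns:
        if col not in df.columns:
            raise ValidationError(f"item column '{col}' not found in {path.name}")
    n = len(df)
    p = len(item_columns)
    values = np.zeros((n, p), dtype=np.int64)
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(item_columns):
        for i, cell in enumerate(df[col].astype(str).str.strip()):
            if cell in missing_set:
                mask[i, j] = True
                continue
            try:
                values[i, j] = int(cell) - offset
            except ValueError as exc:
                raise ValidationError(
                    f"unparseable cell at row {i + 1}, column '{col}': {cell!r}"
                ) from exc
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ValidationError(f"group column '{group_column}' not found")
        group = df[group_column].to_numpy()
    externals: dict[str, np.ndarray] = {}
    for col in external_columns or ():
        if col not in df.columns:
            raise ValidationError(f"external column '{col}' not found")
        externals[col] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    return ResponseMatrix(
        values=values,
        item_names=list(item_columns),
        n_categories=n_categories,
        missing_mask=mask,
        group=group,
        externals=externals,
    )


def write_results_table(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a result table so a round-trip read reproduces 12 significant digits."""
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty results table")
    table.to_csv(Path(path), sep=sep, index=False, float_format="%.12g", encoding="utf-8")


def read_results_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=sep, encoding="utf-8")
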