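"""End-to-end validation pipeline.

Runs the stages in the order a scale-validation study reports them:
dimensionality (polychoric eigenstructure + Mokken AISP), competing-model
estimation and selection (BIC primary, Vuong confirmation), item fit and
local dependence on the selected model, item-parameter summaries,
precision (information curves, reliability), differential item
functioning, person fit, and external associations. A stage failure is
recorded and the pipeline continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .associations import correlate_scores
from .data_model import ResponseMatrix, RunConfig
from .dif import dif_olr
from .dimensionality import (aisp, empirical_kaiser, mokken_scalability,
                             nearest_psd_correlation, polychoric_matrix)
from .global_fit import fit_summary, vuong_compare
from .irt import LatentGrid, fit_mml, threshold_spacing, classify_slope
from .item_fit import jsi, s_x2
from .person_fit import zh, zh_external_check
from .scoring import eap_scores, reliability

log = logging.getLogger("polygrade")

__all__ = ["ReportBundle", "run_pipeline"]


@dataclass
class ReportBundle:
    stages: dict[str, Any] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)
    selected_model: str | None = None
    models: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        """JSON-serializable report (numpy arrays to lists, tables to records)."""
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, pd.DataFrame):
                return x.replace({np.nan: None}).to_dict(orient="records")
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if hasattr(x, "__dict__"):
                return conv(vars(x))
            if isinstance(x, float) and not np.isfinite(x):
                return None
            return x

        return {
            "metadata": conv(self.metadata),
            "selected_model": self.selected_model,
            "stages": conv(self.stages),
            "failures": self.failures,
            "skipped": self.skipped,
        }


def _stage(bundle: ReportBundle, name: str):
    """Decorator-style stage runner: record output, duration or failure."""
    def run(fn):
        t0 = time.time()
        try:
            bundle.stages[name] = fn()
            log.info("stage %-16s done in %.2fs", name, time.time() - t0)
        except Exception as exc:
            log.warning("stage %s failed: %s", name, exc)
            bundle.failures[name] = f"{type(exc).__name__}: {exc}"
    return run


def run_pipeline(config: RunConfig, data: ResponseMatrix) -> ReportBundle:
    """Execute the full validation sequence and return a consolidated report."""
    bundle = ReportBundle(metadata={
        "seed": config.seed,
        "n_persons": data.n_persons,
        "n_items": data.n_items,
        "n_categories": data.n_categories,
        "model_set": list(config.model_set),
        "version": __version__,
    })
    grid = LatentGrid.standard_normal(config.quadrature_nodes, config.quadrature_range)

    def dimensionality():
        R = nearest_psd_correlation(polychoric_matrix(data))
        lam = np.sort(np.linalg.eigvalsh(R))[::-1]
        ekc = empirical_kaiser(lam, data.n_persons, data.n_items)
        scal = mokken_scalability(data)
        parts = aisp(data, config.aisp_bounds)
        return {
            "polychoric": R,
            "eigenvalues": ekc.sample_eigenvalues,
            "ekc_references": ekc.reference_eigenvalues,
            "n_retained": ekc.n_retained,
            "H": scal.H,
            "Hi": scal.Hi,
            "aisp": {str(c): v for c, v in parts.items()},
        }

    _stage(bundle, "dimensionality")(dimensionality)

    def model_comparison():
        rows = []
        for kind in config.model_set:
            model = fit_mml(data, kind, grid=grid, compute_se=(kind == "GRM"))
            bundle.models[kind] = model
            fs = fit_summary(model, data)
            rows.append({
                "model": kind, "M2": fs.M2, "df": fs.df, "p": fs.p_value,
                "RMSEA2": fs.RMSEA2, "SRMR": fs.SRMR, "CFI": fs.CFI,
                "AIC": fs.AIC, "BIC": fs.BIC, "LL": fs.LL, "k": fs.k,
                "converged": model.converged,
            })
        table = pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)
        # BIC-minimal selection, ties toward fewer parameters
        best = table.sort_values(["BIC", "k"]).iloc[0]["model"]
        vuong = None
        if len(table) >= 2:
            second = table.sort_values(["BIC", "k"]).iloc[1]["model"]
            v = vuong_compare(bundle.models[best], bundle.models[second], data,
                              alpha=config.dif_alpha)
            vuong = {"comparison": f"{best} vs {second}", "omega2": v.omega2,
                     "omega2_p": v.omega2_p, "z": v.z, "z_p": v.z_p,
                     "direction": v.direction}
            if v.distinguishable and v.direction == second:
                best = second
        else:
            bundle.skipped["vuong"] = "single model configured"
        bundle.selected_model = str(best)
        return {"table": table, "vuong": vuong, "selected": str(best)}

    _stage(bundle, "model_comparison")(model_comparison)

    model = bundle.models.get(bundle.selected_model) if bundle.selected_model else None
    if model is None:
        bundle.skipped["downstream"] = "no model could be fitted"
        return bundle

    def item_parameters():
        spacing = threshold_spacing(model.items)
        rows = []
        for idx, it in enumerate(model.items):
            rows.append({
                "item": it.name, "a": it.a, "se_a": it.se_a,
                **{f"b{t+1}": float(v) for t, v in enumerate(it.b)},
                **({f"se_b{t+1}": float(v) for t, v in enumerate(it.se_b)}
                   if it.se_b is not None else {}),
                "loading": it.loading, "slope_class": classify_slope(it.a),
                "delta_12": spacing["delta_12"][idx],
                "delta_23": spacing["delta_23"][idx],
                "disordered": bool(spacing["disordered"][idx]),
            })
        return {"table": pd.DataFrame(rows),
                "mean_delta_12": spacing["mean_delta_12"],
                "mean_delta_23": spacing["mean_delta_23"]}

    _stage(bundle, "item_parameters")(item_parameters)

    def item_fit():
        res = s_x2(model, data)
        table = pd.DataFrame([vars(r) for r in res])
        return {"table": table}

    _stage(bundle, "item_fit")(item_fit)

    def local_dependence():
        J = jsi(model.kind, data, grid=grid, multiplier=config.jsi_multiplier,
                full_model=model)
        return {"matrix": J.values, "mean": J.mean, "sd": J.sd,
                "threshold": J.threshold,
                "flagged_pairs": [(J.item_names[i], J.item_names[j])
                                  for i, j in J.flagged_pairs]}

    _stage(bundle, "local_dependence")(local_dependence)

    scores = None

    def precision():
        nonlocal scores
        scores = eap_scores(model, data, grid)
        scores = reliability(model, scores, grid)
        return {
            "empirical_reliability": scores.empirical_reliability,
            "info_grid": scores.info_grid,
            "test_information": scores.test_information,
            "item_information": scores.item_information,
            "conditional_reliability": scores.conditional_reliability,
        }

    _stage(bundle, "precision")(precision)

    if data.group is not None and scores is not None:
        def dif_stage():
            res = dif_olr(data, scores.eap, alpha=config.dif_alpha)
            return {"table": res.table, "flagged": res.flagged_items()}

        _stage(bundle, "dif")(dif_stage)
    else:
        bundle.skipped["dif"] = ("no group column present"
                                 if data.group is None else "scoring failed")

    if scores is not None:
        def person_fit():
            pf = zh(model, data, scores.eap, cut=config.zh_cut)
            out = {"prop_aberrant": pf.prop_aberrant, "prop_overfit": pf.prop_overfit,
                   "zh": pf.zh}
            if data.externals:
                out["external_check"] = zh_external_check(pf, data.externals)
            return out

        _stage(bundle, "person_fit")(person_fit)

        if data.externals:
            def associations():
                rel = scores.empirical_reliability
                return {"table": correlate_scores(scores.eap, data.externals,
                                                  reliability=rel)}

            _stage(bundle, "associations")(associations)
        else:
            bundle.skipped["associations"] = "no external variables present"
    return bundle
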