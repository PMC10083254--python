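"""Shared fixtures: generating parameters and cached model fits.

Expensive MML-EM fits are computed once per session and shared across test
modules; every simulation is seeded so the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from polygrade.irt import LatentGrid, fit_mml
from polygrade.simulate import GeneratingSpec, gad7_item_parameters, simulate_grm


@pytest.fixture(scope="session")
def gad7_items():
    return gad7_item_parameters()


@pytest.fixture(scope="session")
def study_spec():
    """The default study conditions: 7 items, published parameters, n=2219."""
    return GeneratingSpec(n_persons=2219)


@pytest.fixture(scope="session")
def sim_study(study_spec):
    """One simulated study-sized sample."""
    return simulate_grm(study_spec, seed=11)


@pytest.fixture(scope="session")
def grm_study(sim_study):
    """GRM fitted to the study-sized sample (no standard errors)."""
    return fit_mml(sim_study, "GRM", compute_se=False)


@pytest.fixture(scope="session")
def recovery_fits(study_spec):
    """Twenty seed-replicated (data, GRM fit) pairs at the study size.

    Shared between the parameter-recovery and reliability checks so the
    heavy EM fits run only once.
    """
    out = []
    for seed in range(20):
        data = simulate_grm(study_spec, seed=1000 + seed)
        out.append((data, fit_mml(data, "GRM", compute_se=False)))
    return out


@pytest.fixture(scope="session")
def small_grid():
    return LatentGrid.standard_normal(61, 6.0)
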