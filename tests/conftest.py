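"""Shared fixtures: small simulated cohorts and the heavy recovery runs.

The three full-scale cohort fixtures (used by the acceptance-level recovery
tests) are session-scoped so each construct's simulate -> idealize -> dwell
-> global-fit chain runs once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import siteexposure as se
from siteexposure.globalfit import global_fit_site_exposure
from siteexposure.pipeline import analyze_traces
from siteexposure.presets import DEFAULT_K21, KINETIC_CONC_GRIDS, KINETIC_PARAMS

warnings.filterwarnings("ignore", message="Model is not converging")

RECOVERY_SEED = 20260926  # master seed of the simulated study


@pytest.fixture(scope="session")
def emission():
    return se.EmissionModel()


def _recovery_run(label: str, n_traces: int = 400):
    truth = KINETIC_PARAMS[label]
    rates = truth.to_rateset(DEFAULT_K21)
    em = se.EmissionModel()
    traces, _ = se.simulate_experiment(
        rates,
        KINETIC_CONC_GRIDS[label],
        n_traces,
        duration=120.0,
        emission=em,
        seed=RECOVERY_SEED,
        label=label,
    )
    series = analyze_traces(
        traces, em, seed=RECOVERY_SEED + 1, dwell_cfg={"bootstrap_reps": 100}, label=label
    )
    fit = global_fit_site_exposure(series, n_boot=300, seed=RECOVERY_SEED + 2, label=label)
    return truth, series, fit


@pytest.fixture(scope="session")
def p26_recovery():
    """Full-scale outer-region cohort: 400 traces x [1, 2, 5, 10] nM."""
    return _recovery_run("P26")


@pytest.fixture(scope="session")
def p31_recovery():
    """Full-scale inner-region cohort: 400 traces x [50..500] nM."""
    return _recovery_run("P31")


@pytest.fixture(scope="session")
def p36_recovery():
    """Full-scale inner-region cohort at the P36 rate triple."""
    return _recovery_run("P36")


@pytest.fixture(scope="session")
def small_cohort(emission):
    """A quick 30-trace-per-concentration P26-style cohort for unit tests."""
    rates = KINETIC_PARAMS["P26"].to_rateset(DEFAULT_K21)
    traces, meta = se.simulate_experiment(
        rates, [2.0, 10.0], 30, duration=60.0, emission=emission, seed=42, label="unit"
    )
    return traces, meta, rates
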