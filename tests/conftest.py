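"""Shared fixtures: synthetic-subject targets and fitted curve models.

The fitted models are expensive (a few seconds each), so they are built once
per session and shared between the fitting tests and the acceptance checks.
"""

from __future__ import annotations

import pytest

import coincatch as cc

#: Generative init of the synthetic "subject" cohort (an uncertain NIG
#: learner with a slight initial variance underestimate plus motor noise).
SUBJECT_INIT = {"mu": 0.0, "lam": 0.8, "alpha": 1.3, "beta": 0.015}
SUBJECT_MOTOR_SD = 0.02


@pytest.fixture(scope="session")
def subject_observer():
    return cc.ObserverSpec("nig_learner", {"init": SUBJECT_INIT},
                           motor_noise_sd=SUBJECT_MOTOR_SD)


@pytest.fixture(scope="session")
def exp1_configs():
    return (cc.SessionConfig.exp1(prior_sd=0.2),
            cc.SessionConfig.exp1(prior_sd=0.05))


@pytest.fixture(scope="session")
def exp2_configs():
    return (cc.SessionConfig.exp2(first_sd=0.2),
            cc.SessionConfig.exp2(first_sd=0.05))


@pytest.fixture(scope="session")
def exp1_target(subject_observer, exp1_configs):
    wide, narrow = exp1_configs
    return cc.make_fit_target(wide, narrow, subject_observer, n_subjects=7, seed=5)


@pytest.fixture(scope="session")
def exp2_subject_curves(subject_observer, exp2_configs):
    a, b = exp2_configs
    return (cc.cohort_curves(a, subject_observer, n_subjects=7, seed=21),
            cc.cohort_curves(b, subject_observer, n_subjects=7, seed=22))


@pytest.fixture(scope="session")
def fitted_nig(exp1_target, exp1_configs):
    wide, narrow = exp1_configs
    model = cc.NIGCurveModel(exp1_target, wide, narrow, n_runs=200, seed=1)
    return model.fit(restarts=3, maxfev=200)


@pytest.fixture(scope="session")
def fitted_lf(exp1_target, exp1_configs):
    wide, narrow = exp1_configs
    model = cc.LinearFilterCurveModel(exp1_target, wide, narrow, n_runs=200, seed=1)
    return model.fit(restarts=3, maxfev=200)
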