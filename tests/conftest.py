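import numpy as np
import pytest

import isletprog as ip
from isletprog.datamodel import BaselineCovariates, LongitudinalRecord, StateRecord, Subject
from isletprog.longitudinal import LongitudinalFit
from isletprog.multistate import PiecewiseConstantHazard, TransitionModel
from isletprog.splines import LongitudinalSpec, SplineSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Default-truth cohort of 60 subjects, fixed seed."""
    return ip.simulate_cohort(ip.default_config(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def midsize_cohort():
    """Default-truth cohort of 400 subjects for distributional checks."""
    return ip.simulate_cohort(ip.default_config(n_subjects=400, seed=21))


def make_baseline(age=4.0, sex="male", fdr=0, dq="DQ2/8"):
    return BaselineCovariates(sex=sex, age_at_gada=age, fdr=fdr, dq_group=dq)


@pytest.fixture
def baseline():
    return make_baseline()


def single_transition_config(levels=(0.2,), cuts=(), roster=(), censor_vars=False):
    """Config with only the direct 1->4 transition enabled and no covariates."""
    return ip.SimulationConfig(
        n_subjects=0,
        seed=0,
        transition_coefs={(1, 4): tuple((name, c) for name, c in roster)},
        baseline_hazards={(1, 4): (tuple(cuts), tuple(levels))},
    )


def toy_1d_longitudinal_fit(beta=(5.0, 0.1), tau2=0.25, sigma=0.3):
    """One variable (HbA1c-like), random intercept only."""
    spec = LongitudinalSpec(
        "hba1c",
        SplineSpec("piecewise_linear", (), boundary=(0.0, 15.0)),
        log_transformed=False,
        random_terms=(0,),
    )
    return LongitudinalFit(
        specs=[spec],
        beta={"hba1c": np.asarray(beta, dtype=float)},
        sigma={"hba1c": sigma},
        sigma_b=np.array([[tau2]]),
        log_likelihood=np.nan,
        converged=True,
        n_iter=0,
        loglik_trace=np.zeros(0),
    )


def toy_1d_joint_fit(alpha=0.8, h0=0.05, center=5.0, **kwargs):
    lfit = toy_1d_longitudinal_fit(**kwargs)
    tm = TransitionModel(
        (1, 4),
        ("hba1c",),
        np.array([alpha]),
        PiecewiseConstantHazard((), (h0,)),
        center=np.array([center]),
    )
    return ip.JointModelFit(longitudinal=lfit, transitions={(1, 4): tm})


def history_in_state1(baseline, records, s):
    return ip.SubjectHistory(
        baseline=baseline, records=records, state_path=[StateRecord(1, 0.0, s, None)]
    )
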