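"""Default ground-truth parameters for the synthetic GADA-first cohort.

The simulator is calibrated to the published characteristics of the study
population it emulates: baseline covariate frequencies and variable medians of
the cohort table, the reported transition-specific log hazard ratios (with
LASSO-excluded covariates kept at exactly zero), and the visit/OGTT/HbA1c
observation scheme.  Quantities the source does not print — baseline hazard
levels, spline knots, random-effect and residual scales — are fixed here once,
at values a longitudinal T1D-risk cohort would plausibly show, and documented
in the methods note.

All longitudinal truth values are on the analysis scale (log(1+x) for OGTT
measures and titer z-scores; raw percent for HbA1c).
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

from .datamodel import LONGITUDINAL_VARIABLES
from .splines import LongitudinalSpec, SplineSpec

MAX_FOLLOWUP_AGE = 15.0

# ---------------------------------------------------------------------------
# Baseline covariates (cohort-table marginals)
# ---------------------------------------------------------------------------

COVARIATE_FREQS: Dict[str, float] = {
    "female": 0.459,
    "fdr": 0.174,
    "dq2_8": 0.488,
    "dq8_x": 0.296,
    "dq2_x": 0.216,
}

#: Quantile anchors (probability, age in years) for age at confirmed GADA
#: positivity: median 5.1, IQR (2.4, 9.0); support chosen inside (0, 15).
AGE_QUANTILE_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.3),
    (0.25, 2.4),
    (0.5, 5.1),
    (0.75, 9.0),
    (1.0, 14.5),
)

AGE_REFERENCE = 5.1  # years; centering point for the age covariate in hazards

# ---------------------------------------------------------------------------
# Longitudinal truth
# ---------------------------------------------------------------------------

_METABOLIC_SPLINE = SplineSpec("natural_cubic", interior_knots=(2.0, 6.0), boundary=(0.0, MAX_FOLLOWUP_AGE))
_TITER_SPLINE = SplineSpec("piecewise_linear", interior_knots=(1.0, 3.0), boundary=(0.0, MAX_FOLLOWUP_AGE))

#: per variable: (spline, fixed-effect vector, intercept SD, slope SD,
#: intercept-slope correlation, residual SD).  Intercepts are the analysis-
#: scale values of the cohort-table baseline medians (log(1+x) where
#: applicable); slopes/hinges encode the qualitative trends of the
#: trajectory figure (metabolic rise with age/growth, titer shifts after
#: seroconversion).
_LONGITUDINAL_TRUTH: Dict[str, tuple] = {
    # variable: (spline, beta, sd_int, sd_slope, corr, sd_resid)
    "fasting_glu": (_METABOLIC_SPLINE, (math.log(89.0), 0.004, 0.0, 0.0), 0.060, 0.010, 0.2, 0.060),
    "glu_2h": (_METABOLIC_SPLINE, (math.log(107.0), 0.010, 0.0, 0.0), 0.115, 0.020, 0.2, 0.120),
    "fasting_cp": (_METABOLIC_SPLINE, (math.log(1.98), 0.060, 0.0, 0.0), 0.155, 0.020, 0.2, 0.150),
    "cp_2h": (_METABOLIC_SPLINE, (math.log(4.77), 0.050, 0.0, 0.0), 0.250, 0.030, 0.2, 0.200),
    "hba1c": (_METABOLIC_SPLINE, (5.20, 0.030, 0.0, 0.0), 0.250, 0.040, 0.3, 0.150),
    "gada_z": (_TITER_SPLINE, (math.log1p(0.417), 0.150, -0.120, -0.020), 0.350, 0.100, 0.3, 0.200),
    "ia2a_z": (_TITER_SPLINE, (math.log1p(-0.087), 0.020, 0.060, 0.030), 0.150, 0.120, 0.3, 0.200),
    "iaa_z": (_TITER_SPLINE, (math.log1p(-0.322), 0.050, 0.000, 0.000), 0.150, 0.120, 0.3, 0.200),
    "znt8a_z": (_TITER_SPLINE, (math.log1p(-0.105), 0.080, 0.020, 0.000), 0.200, 0.120, 0.3, 0.200),
}

#: rank-1 loading on the titer random slopes: a shared "autoimmune drive"
#: factor inducing positive cross-variable correlation of titer trajectories.
_TITER_SLOPE_LOADING = 0.05


def default_specs() -> List[LongitudinalSpec]:
    return [
        LongitudinalSpec(
            variable=v,
            spline=_LONGITUDINAL_TRUTH[v][0],
            log_transformed=(v != "hba1c"),
            random_terms=(0, 1),
        )
        for v in LONGITUDINAL_VARIABLES
    ]


def default_beta() -> Dict[str, np.ndarray]:
    return {v: np.asarray(_LONGITUDINAL_TRUTH[v][1], dtype=float) for v in LONGITUDINAL_VARIABLES}


def default_sigma() -> Dict[str, float]:
    return {v: _LONGITUDINAL_TRUTH[v][5] for v in LONGITUDINAL_VARIABLES}


def default_sigma_b(specs: List[LongitudinalSpec] | None = None) -> np.ndarray:
    """Random-effects covariance over the stacked (intercept, slope) pairs.

    Block-diagonal within variable plus a rank-1 loading across the titer
    slopes; returned in the canonical variable order.
    """
    if specs is None:
        specs = default_specs()
    dim = sum(s.n_random for s in specs)
    Sigma = np.zeros((dim, dim))
    loading = np.zeros(dim)
    off = 0
    for s in specs:
        sd_i, sd_s, rho = _LONGITUDINAL_TRUTH[s.variable][2:5]
        block = np.array(
            [[sd_i**2, rho * sd_i * sd_s], [rho * sd_i * sd_s, sd_s**2]]
        )
        Sigma[off : off + 2, off : off + 2] = block
        if s.variable in ("gada_z", "ia2a_z", "iaa_z", "znt8a_z"):
            loading[off + 1] = _TITER_SLOPE_LOADING
        off += 2
    return Sigma + np.outer(loading, loading)


def population_mean(variable: str) -> float:
    """Analysis-scale population intercept of a longitudinal variable."""
    return float(_LONGITUDINAL_TRUTH[variable][1][0])


# ---------------------------------------------------------------------------
# Transition truth (published log hazard ratios; zeros are LASSO exclusions)
# ---------------------------------------------------------------------------

TRANSITION_COEFS: Dict[Tuple[int, int], Tuple[Tuple[str, float], ...]] = {
    (1, 2): (
        ("gada_z", 0.995),
        ("fdr", 0.126),
        ("age", -0.124),
        ("dq8x", -0.0625),
        ("dq2x", -0.665),
    ),
    (1, 3): (
        ("gada_z", 1.27),
        ("fdr", 0.306),
        ("age", -0.121),
        ("dq8x", 0.0),
        ("dq2x", -0.615),
    ),
    (1, 4): (
        ("hba1c", 3.89),
        ("gada_z", 1.48),
        ("fdr", 0.678),
        ("age", -0.140),
        ("dq8x", 0.0),
        ("dq2x", 1.08),
    ),
    (2, 3): (
        ("fasting_glu", 0.0),
        ("glu_2h", 3.48),
        ("fasting_cp", 0.0),
        ("cp_2h", -1.14),
        ("hba1c", 0.0),
        ("gada_z", 0.156),
        ("iaa_z", 0.616),
        ("znt8a_z", 1.28),
        ("fdr", 0.216),
        ("age", 0.0),
        ("dq8x", 0.0556),
        ("dq2x", -1.22),
    ),
    (2, 4): (
        ("fasting_glu", 8.66),
        ("glu_2h", 1.51),
        ("fasting_cp", 0.0),
        ("cp_2h", -2.68),
        ("hba1c", 7.14),
        ("gada_z", 0.0),
        ("iaa_z", 0.389),
        ("znt8a_z", 0.655),
        ("fdr", -0.678),
        ("age", 0.0),
        ("dq8x", 0.0),
        ("dq2x", 0.830),
    ),
    (3, 4): (
        ("fasting_glu", 2.13),
        ("glu_2h", 4.71),
        ("fasting_cp", -0.00169),
        ("cp_2h", 0.0),
        ("hba1c", 2.01),
        ("gada_z", -0.224),
        ("ia2a_z", 0.0),
        ("iaa_z", 0.0),
        ("znt8a_z", -0.260),
        ("fdr", 1.17),
        ("age", -0.0702),
        ("dq8x", 0.0),
        ("dq2x", 0.0),
    ),
}

#: Default piecewise-constant baseline hazards: (interior cut points, levels),
#: per year, at the covariate reference point.  Levels chosen once so that all
#: four states are occupied at 10 years and every transition accrues events.
BASELINE_HAZARDS: Dict[Tuple[int, int], Tuple[Tuple[float, ...], Tuple[float, ...]]] = {
    (1, 2): ((3.0,), (0.12, 0.10)),
    (1, 3): ((3.0,), (0.03, 0.025)),
    (1, 4): ((3.0,), (0.003, 0.005)),
    (2, 3): ((3.0,), (0.22, 0.18)),
    (2, 4): ((3.0,), (0.012, 0.02)),
    (3, 4): ((3.0,), (0.05, 0.08)),
}


def transition_center(roster: Tuple[str, ...]) -> np.ndarray:
    """Reference covariate values: longitudinal intercepts, age at 5.1, 0 else."""
    out = []
    for name in roster:
        if name in LONGITUDINAL_VARIABLES:
            out.append(population_mean(name))
        elif name == "age":
            out.append(AGE_REFERENCE)
        else:
            out.append(0.0)
    return np.asarray(out)
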