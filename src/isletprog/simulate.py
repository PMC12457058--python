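"""Synthetic GADA-first cohort generator with known ground truth.

The generator emulates a prospective high-risk birth-cohort follow-up:
children enter at confirmed GADA positivity (t = 0), their nine longitudinal
variables follow spline mixed-effects trajectories with correlated random
effects, and progression through the four autoimmunity states is driven by
transition-specific proportional hazards evaluated on the *latent* (noise
free) trajectories.  Event times are drawn by Lewis-Shedler thinning against
a piecewise dominating rate.  Observation is sparse and scheduled: quarterly
visits (titers and HbA1c at every visit), OGTT measures biannually once the
child has multiple autoantibodies and is at least 3 years old, nothing after
diabetes onset, and transitions are detected at the first visit at or after
they truly occur (right-endpoint interval convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import truth as truth_mod
from .datamodel import (
    LONGITUDINAL_VARIABLES,
    OGTT_VARIABLES,
    BaselineCovariates,
    Cohort,
    LongitudinalRecord,
    StateRecord,
    Subject,
)
from .multistate import CovariatePath, PiecewiseConstantHazard, TransitionModel
from .splines import LongitudinalSpec
from .states import DEFAULT_STATE_SPACE, StateSpace, Transition

__all__ = [
    "SimulationConfig",
    "LatentTrajectories",
    "sample_baseline",
    "simulate_trajectories",
    "simulate_transitions",
    "apply_observation_scheme",
    "simulate_cohort",
    "default_config",
    "truth_transition_models",
    "sample_event_time_inverse_cdf",
]

JITTER_HALF_WIDTH = 14.0 / 365.25  # +/- two weeks around scheduled visits


@dataclass
class SimulationConfig:
    n_subjects: int = 379
    seed: int = 0
    covariate_freqs: Dict[str, float] = field(default_factory=lambda: dict(truth_mod.COVARIATE_FREQS))
    age_quantile_anchors: Tuple[Tuple[float, float], ...] = truth_mod.AGE_QUANTILE_ANCHORS
    specs: List[LongitudinalSpec] = field(default_factory=truth_mod.default_specs)
    beta: Dict[str, np.ndarray] = field(default_factory=truth_mod.default_beta)
    sigma_b: np.ndarray = field(default_factory=truth_mod.default_sigma_b)
    sigma: Dict[str, float] = field(default_factory=truth_mod.default_sigma)
    transition_coefs: Dict[Transition, Tuple[Tuple[str, float], ...]] = field(
        default_factory=lambda: dict(truth_mod.TRANSITION_COEFS)
    )
    baseline_hazards: Dict[Transition, Tuple[Tuple[float, ...], Tuple[float, ...]]] = field(
        default_factory=lambda: dict(truth_mod.BASELINE_HAZARDS)
    )
    visit_interval: float = 0.25
    visit_jitter: bool = True
    ogtt_interval: float = 0.5
    ogtt_min_age: float = 3.0
    max_followup_age: float = truth_mod.MAX_FOLLOWUP_AGE
    state_space: StateSpace = field(default_factory=lambda: DEFAULT_STATE_SPACE)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        f = self.covariate_freqs
        for key, v in f.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"covariate frequency {key}={v} outside [0,1]")
        dq = f["dq2_8"] + f["dq8_x"] + f["dq2_x"]
        if abs(dq - 1.0) > 1e-9:
            raise ValueError(f"DQ group frequencies must sum to 1, got {dq}")
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        ev = np.linalg.eigvalsh(self.sigma_b)
        if ev.min() < -1e-10:
            raise ValueError("sigma_b must be positive semidefinite")

    @property
    def rand_slices(self) -> Dict[str, slice]:
        out, off = {}, 0
        for s in self.specs:
            out[s.variable] = slice(off, off + s.n_random)
            off += s.n_random
        return out


def default_config(n_subjects: int = 379, seed: int = 0, **kwargs) -> SimulationConfig:
    return SimulationConfig(n_subjects=n_subjects, seed=seed, **kwargs)


def truth_transition_models(config: SimulationConfig) -> Dict[Transition, TransitionModel]:
    """The generating TransitionModel set (centered at the reference point)."""
    models = {}
    for k, rows in config.transition_coefs.items():
        roster = tuple(name for name, _ in rows)
        coef = np.asarray([c for _, c in rows])
        cuts, levels = config.baseline_hazards[k]
        models[k] = TransitionModel(
            transition=k,
            covariates=roster,
            coef=coef,
            baseline=PiecewiseConstantHazard(cuts=tuple(cuts), levels=tuple(levels)),
            center=truth_mod.transition_center(roster),
        )
    return models


# ---------------------------------------------------------------------------
# Baseline covariates
# ---------------------------------------------------------------------------

def sample_age_at_gada(config: SimulationConfig, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Quantile-anchored sampler: piecewise-linear quantile function in
    log-age through the target (median, quartile) anchors."""
    anchors = np.asarray(config.age_quantile_anchors)
    u = rng.uniform(size=n)
    log_age = np.interp(u, anchors[:, 0], np.log(anchors[:, 1]))
    return np.exp(log_age)


def sample_baseline(config: SimulationConfig, rng: np.random.Generator) -> BaselineCovariates:
    f = config.covariate_freqs
    sex = "female" if rng.uniform() < f["female"] else "male"
    fdr = int(rng.uniform() < f["fdr"])
    dq = rng.choice(
        ["DQ2/8", "DQ8/X", "DQ2/X"], p=[f["dq2_8"], f["dq8_x"], f["dq2_x"]]
    )
    age = float(sample_age_at_gada(config, rng, 1)[0])
    return BaselineCovariates(sex=sex, age_at_gada=age, fdr=fdr, dq_group=str(dq))


# ---------------------------------------------------------------------------
# Latent trajectories
# ---------------------------------------------------------------------------

@dataclass
class LatentTrajectories:
    """Noise-free trajectories m_j(t) = x_j(t)' beta_j + z_j(t)' b_j."""

    specs: List[LongitudinalSpec]
    beta: Dict[str, np.ndarray]
    b: np.ndarray  # stacked random effects, config.rand_slices layout
    rand_slices: Dict[str, slice]

    def value(self, variable: str, times) -> np.ndarray:
        spec = next(s for s in self.specs if s.variable == variable)
        t = np.atleast_1d(np.asarray(times, dtype=float))
        X = spec.design(t)
        Z = X[:, list(spec.random_terms)]
        return X @ self.beta[variable] + Z @ self.b[self.rand_slices[variable]]

    def covariate_path(self, baseline: BaselineCovariates) -> CovariatePath:
        return CovariatePath(baseline, trajectory=self.value)


def simulate_trajectories(
    baseline: BaselineCovariates, config: SimulationConfig, rng: np.random.Generator
) -> LatentTrajectories:
    dim = config.sigma_b.shape[0]
    # eigen-decomposition draw: valid for any PSD sigma_b (cholesky would
    # reject the rank-deficient cases used in degenerate tests)
    w, V = np.linalg.eigh(config.sigma_b)
    w = np.clip(w, 0.0, None)
    b = V @ (np.sqrt(w) * rng.standard_normal(dim))
    return LatentTrajectories(
        specs=config.specs, beta=config.beta, b=b, rand_slices=config.rand_slices
    )


# ---------------------------------------------------------------------------
# Transition simulation (thinning)
# ---------------------------------------------------------------------------

_LP_CAP = 30.0


class DominatingRateOverflow(RuntimeError):
    pass


class _HazardEvaluator:
    """Fast per-subject intensity evaluation.

    Groups the longitudinal variables by their (shared) spline bases and
    folds each transition's coefficients into one combined coefficient vector
    per basis, so evaluating all intensities at a vector of times costs one
    basis build per distinct spline plus a handful of dot products.
    """

    def __init__(
        self,
        baseline: BaselineCovariates,
        trajectories: "LatentTrajectories",
        models: Dict[Transition, TransitionModel],
        state_space: StateSpace,
    ):
        from .datamodel import LONGITUDINAL_VARIABLES as LV

        specs = {s.variable: s for s in trajectories.specs}
        splines = []  # distinct SplineSpec objects
        spline_idx = {}
        for s in trajectories.specs:
            if s.spline not in spline_idx:
                spline_idx[s.spline] = len(splines)
                splines.append(s.spline)
        self.splines = splines
        self.state_space = state_space
        self.models = models
        # per-variable full coefficient vector (fixed + scattered random effects)
        var_coef = {}
        for v, s in specs.items():
            c = np.array(trajectories.beta[v], dtype=float)
            c[list(s.random_terms)] += trajectories.b[trajectories.rand_slices[v]]
            var_coef[v] = (spline_idx[s.spline], c)
        # per-transition: constant part + combined basis coefficients
        self.parts: Dict[Transition, Tuple[float, list]] = {}
        for k, m in models.items():
            const = 0.0
            comb = [np.zeros(sp.dimension) for sp in splines]
            for c, name in zip(m.coef, m.covariates):
                if c == 0.0:
                    continue
                if name in LV:
                    si, vc = var_coef[name]
                    comb[si] = comb[si] + c * vc
                    const -= c * m.center[list(m.covariates).index(name)]
                else:
                    const += c * (baseline.covariate(name) - m.center[list(m.covariates).index(name)])
            self.parts[k] = (const, comb)

    def rates(self, state: int, times: np.ndarray) -> Dict[Transition, np.ndarray]:
        from .splines import build_basis

        ks = [k for k in self.state_space.transitions_from(state) if k in self.models]
        if not ks:
            return {}
        bases = [build_basis(times, sp) for sp in self.splines]
        out = {}
        for k in ks:
            const, comb = self.parts[k]
            lp = np.full(times.size, const)
            for Xb, cb in zip(bases, comb):
                if np.any(cb):
                    lp += Xb @ cb
            if np.any(lp > _LP_CAP):
                raise DominatingRateOverflow(
                    f"linear predictor overflow on transition {k}: max lp = {lp.max():.2f}"
                )
            out[k] = self.models[k].baseline.rate(times) * np.exp(lp)
        return out


def simulate_transitions(
    baseline: BaselineCovariates,
    trajectories: LatentTrajectories,
    config: SimulationConfig,
    rng: np.random.Generator,
    models: Optional[Dict[Transition, TransitionModel]] = None,
    start_state: int = 1,
    start_time: float = 0.0,
    censor_time: Optional[float] = None,
) -> List[StateRecord]:
    """Exact-time state path drawn by thinning the competing intensities.

    Returns contiguous sojourn records from ``start_time`` until absorption in
    state 4 or censoring at ``censor_time`` (default: age ``max_followup_age``).
    """
    space = config.state_space
    if models is None:
        models = truth_transition_models(config)
    if censor_time is None:
        censor_time = max(config.max_followup_age - baseline.age_at_gada, 0.0)
    ev = _HazardEvaluator(baseline, trajectories, models, space)

    records: List[StateRecord] = []
    state = start_state
    t = start_time
    entry = start_time
    grid_step = 0.05
    while True:
        if state in space.absorbing or t >= censor_time:
            break
        grid = np.arange(t, censor_time + grid_step, grid_step)
        grid = np.clip(grid, t, censor_time)
        rates = ev.rates(state, grid)
        if not rates:
            records.append(StateRecord(state, entry, censor_time, None))
            return records
        total_on_grid = np.sum(list(rates.values()), axis=0)
        if total_on_grid.max() <= 0.0:
            records.append(StateRecord(state, entry, censor_time, None))
            return records
        # piecewise dominating rate: 1.2 * running max of the total intensity
        # over ~1-year windows of the dense grid
        chunk = max(int(round(1.0 / grid_step)), 1)
        moved = False
        i = 0
        while i < grid.size - 1 and not moved:
            j = min(i + chunk, grid.size - 1)
            seg_end = float(grid[j])
            M = 1.2 * float(total_on_grid[i : j + 1].max())
            if M <= 0.0:
                t = seg_end
                i = j
                continue
            while t < seg_end:
                t = t + rng.exponential(1.0 / M)
                if t >= seg_end:
                    t = seg_end
                    break
                rr = ev.rates(state, np.asarray([t]))
                hk = {k: float(v[0]) for k, v in rr.items()}
                h_tot = sum(hk.values())
                if rng.uniform() < min(h_tot / M, 1.0):
                    ks = sorted(hk)
                    probs = np.asarray([hk[k] for k in ks]) / h_tot
                    k = ks[rng.choice(len(ks), p=probs)]
                    records.append(StateRecord(state, entry, t, k[1]))
                    state = k[1]
                    entry = t
                    moved = True
                    break
            i = j
        if not moved:
            records.append(StateRecord(state, entry, censor_time, None))
            return records
    if state in space.absorbing and records:
        return records
    if not records:
        records.append(StateRecord(state, entry, censor_time, None))
    return records


def sample_event_time_inverse_cdf(
    hazard: PiecewiseConstantHazard, rng: np.random.Generator, t_max: float = np.inf
) -> float:
    """Reference inverse-CDF sampler for a piecewise-constant hazard.

    Returns the event time, or ``inf``/``t_max``-censored values untouched
    (caller decides).  Used as the distributional oracle for the thinning
    sampler in tests.
    """
    target = rng.exponential(1.0)
    edges = [0.0, *hazard.cuts, np.inf]
    acc = 0.0
    for a, b, level in zip(edges[:-1], edges[1:], hazard.levels):
        seg = (b - a) * level
        if acc + seg >= target:
            if level == 0:
                break
            return min(a + (target - acc) / level, t_max)
        acc += seg
    return t_max


# ---------------------------------------------------------------------------
# Observation scheme
# ---------------------------------------------------------------------------

def _visit_times(config: SimulationConfig, censor_time: float, rng: np.random.Generator) -> np.ndarray:
    scheduled = np.arange(0.0, censor_time, config.visit_interval)
    if config.visit_jitter and scheduled.size > 1:
        jitter = rng.uniform(-JITTER_HALF_WIDTH, JITTER_HALF_WIDTH, size=scheduled.size - 1)
        scheduled[1:] = scheduled[1:] + jitter
        scheduled = np.maximum.accumulate(scheduled)
    scheduled = scheduled[scheduled < censor_time - 1e-9]
    return np.append(scheduled, censor_time)  # end-of-study assessment


def observe_path(
    true_path: List[StateRecord], visits: np.ndarray, censor_time: float
) -> List[StateRecord]:
    """Interval-observed path: each transition is recorded at the first visit
    at or after it truly occurred; passages fully contained between two visits
    collapse into the direct observed transition."""

    def true_state_at(t: float) -> int:
        for rec in true_path:
            if rec.entry_time <= t < rec.exit_time:
                return rec.state
        last = true_path[-1]
        if t >= last.exit_time and last.next_state is not None:
            return last.next_state
        return last.state

    observed: List[StateRecord] = []
    cur_state = true_path[0].state
    entry = true_path[0].entry_time
    for v in visits[1:]:
        s = true_state_at(v)
        if s != cur_state:
            observed.append(StateRecord(cur_state, entry, v, s))
            cur_state = s
            entry = v
            if s == 4:
                return observed
    observed.append(StateRecord(cur_state, entry, float(visits[-1]), None))
    return observed


def apply_observation_scheme(
    baseline: BaselineCovariates,
    trajectories: LatentTrajectories,
    observed_path: List[StateRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
    visits: np.ndarray,
) -> List[LongitudinalRecord]:
    """Noisy scheduled observations of the latent trajectories.

    Titers and HbA1c at every visit; OGTT measures biannually while the
    observed state is 2 or 3 and age >= the OGTT age floor; no records after
    entry into state 4.
    """
    absorb_time = np.inf
    last = observed_path[-1]
    if last.next_state == 4:
        absorb_time = last.exit_time

    def observed_state_at(t: float) -> int:
        for rec in observed_path:
            if rec.entry_time <= t < rec.exit_time:
                return rec.state
        if last.next_state is not None and t >= last.exit_time:
            return last.next_state
        return last.state

    keep = visits[visits <= absorb_time]
    ogtt_mask = np.zeros(keep.size, dtype=bool)
    next_ogtt = -np.inf
    for i, v in enumerate(keep):
        state_v = observed_state_at(min(v, absorb_time - 1e-12) if np.isfinite(absorb_time) else v)
        age_v = baseline.age_at_gada + v
        if state_v in (2, 3) and age_v >= config.ogtt_min_age and v >= next_ogtt:
            ogtt_mask[i] = True
            next_ogtt = v + config.ogtt_interval

    records: List[LongitudinalRecord] = []
    always = ("gada_z", "ia2a_z", "iaa_z", "znt8a_z", "hba1c")
    for var in (*always, *OGTT_VARIABLES):
        times = keep if var in always else keep[ogtt_mask]
        if times.size == 0:
            continue
        m = trajectories.value(var, times)
        sd = config.sigma[var]
        noise = rng.normal(0.0, sd, size=times.size) if sd > 0 else np.zeros(times.size)
        for t, val in zip(times, m + noise):
            records.append(LongitudinalRecord(variable=var, time=float(t), value=float(val)))
    return records


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectLatent:
    trajectories: LatentTrajectories
    true_path: List[StateRecord]


def simulate_subject(
    config: SimulationConfig,
    index: int,
    models: Dict[Transition, TransitionModel],
    master_seed: Optional[int] = None,
) -> Subject:
    seed = config.seed if master_seed is None else master_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
    baseline = sample_baseline(config, rng)
    traj = simulate_trajectories(baseline, config, rng)
    censor = max(config.max_followup_age - baseline.age_at_gada, 1e-6)
    true_path = simulate_transitions(
        baseline, traj, config, rng, models=models, censor_time=censor
    )
    visits = _visit_times(config, censor, rng)
    observed = observe_path(true_path, visits, censor)
    records = apply_observation_scheme(baseline, traj, observed, config, rng, visits)
    return Subject(
        id=f"S{index:05d}",
        baseline=baseline,
        longitudinal=records,
        path=observed,
        latent=SubjectLatent(trajectories=traj, true_path=true_path),
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full cohort; fully reproducible from ``config.seed``."""
    models = truth_transition_models(config)
    subjects = [simulate_subject(config, i, models) for i in range(config.n_subjects)]
    metadata = {
        "generator": "isletprog.simulate",
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "covariate_freqs": dict(config.covariate_freqs),
        "baseline_hazards": {f"{q}->{r}": v for (q, r), v in config.baseline_hazards.items()},
        "transition_coefs": {
            f"{q}->{r}": {name: c for name, c in rows}
            for (q, r), rows in config.transition_coefs.items()
        },
    }
    return Cohort(subjects=subjects, metadata=metadata)


def latent_paths(cohort: Cohort) -> Dict[str, CovariatePath]:
    """Covariate paths built from the simulator's latent trajectories."""
    out = {}
    for s in cohort:
        if s.latent is None:
            raise ValueError(f"subject {s.id} carries no latent trajectories")
        out[s.id] = s.latent.trajectories.covariate_path(s.baseline)
    return out
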