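"""Joint longitudinal-multistate estimation and dynamic prediction.

The hazard of each transition depends on the *current value* of the fitted
longitudinal trajectories, so the subject-level random effects b are shared
between the two submodels.  The marginal likelihood of one subject,

    L_i = Int [ prod_j N(y_ij | m_ij(b), sigma_j^2) ]
              * L_ms(path_i | m_i(.; b)) * N(b | 0, Sigma_b) db,

is evaluated by a Laplace approximation (default), adaptive Gauss-Hermite
quadrature (1-D random effects), or antithetic Monte Carlo (reference).

Dynamic prediction conditions on a subject's history up to a landmark time s:
random effects are drawn by importance sampling (proposal = the closed-form
Gaussian longitudinal posterior, weights = the multistate likelihood of the
observed state history, i.e. "still in state q at s" plus any earlier
transitions), trajectories and state-occupation probabilities are then
averaged over the weighted draws, and everything is recomputed from scratch
when new data arrive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .datamodel import (
    LONGITUDINAL_VARIABLES,
    BaselineCovariates,
    Cohort,
    LongitudinalRecord,
    StateRecord,
    Subject,
)
from .longitudinal import (
    LongitudinalFit,
    PosteriorRandomEffects,
    _subject_design,
    fit_mixed,
    posterior_random_effects,
)
from .multistate import (
    CovariatePath,
    TransitionModel,
    fit_multistate,
    transition_probability_matrix,
)
from .states import DEFAULT_STATE_SPACE, StateSpace, Transition

__all__ = [
    "IntegrationSettings",
    "JointModelFit",
    "SubjectHistory",
    "DynamicPrediction",
    "joint_log_likelihood",
    "fit_joint",
    "sample_posterior_random_effects",
    "predict_trajectory",
    "predict_occupancy",
    "update_prediction",
    "truth_joint_fit",
]


@dataclass(frozen=True)
class IntegrationSettings:
    method: str = "laplace"  # "laplace" | "gh" | "mc"
    n_nodes: int = 30  # gh
    n_draws: int = 10_000  # mc
    seed: int = 0
    subgrid: float = 1.0 / 12.0
    lam: float = 0.0  # multistate penalty in the two-stage fit
    joint_refine: bool = True
    refine_params: str = "hazard"  # "hazard" | "all"
    refine_maxiter: int = 50


@dataclass
class JointModelFit:
    longitudinal: LongitudinalFit
    transitions: Dict[Transition, TransitionModel]
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)
    log_likelihood: float = np.nan
    stagewise: Optional[dict] = None  # pre-refinement estimates
    state_space: StateSpace = field(default_factory=lambda: DEFAULT_STATE_SPACE)
    converged: bool = True

    def trajectory_fn(self, b: np.ndarray) -> Callable[[str, np.ndarray], np.ndarray]:
        fit = self.longitudinal
        slices = fit.rand_slices

        def value(variable: str, t: np.ndarray) -> np.ndarray:
            spec = fit.spec(variable)
            X = spec.design(t)
            return X @ fit.beta[variable] + X[:, list(spec.random_terms)] @ b[slices[variable]]

        return value

    def covariate_path(self, baseline: BaselineCovariates, b: np.ndarray) -> CovariatePath:
        return CovariatePath(baseline, trajectory=self.trajectory_fn(b))


@dataclass
class SubjectHistory:
    """A subject's data up to a landmark time s: the observed longitudinal
    records and the observed state path ending censored in the current state
    at s."""

    baseline: BaselineCovariates
    records: List[LongitudinalRecord]
    state_path: List[StateRecord]

    def __post_init__(self) -> None:
        if not self.state_path:
            raise ValueError("history needs at least one state record")
        s = self.landmark
        if any(r.time > s + 1e-9 for r in self.records):
            raise ValueError("longitudinal records must end at or before the landmark")

    @property
    def landmark(self) -> float:
        return self.state_path[-1].exit_time

    @property
    def current_state(self) -> int:
        last = self.state_path[-1]
        return last.state if last.next_state is None else last.next_state


@dataclass
class DynamicPrediction:
    times: np.ndarray
    occupancy: np.ndarray  # (len(times), 4)
    mc_se: np.ndarray
    landmark: float
    current_state: int
    n_draws: int
    seed: int
    ess: float


# ---------------------------------------------------------------------------
# Vectorized likelihood pieces given random-effect draws
# ---------------------------------------------------------------------------

@dataclass
class _MsStructure:
    """Precomputed exposure cells of one history under one joint fit.

    For draws B (D x Q):  lp = lp0 + B @ W.T  (per cell), and the multistate
    log-likelihood is  sum(events) - sum(cells) level*exp(lp)*dt.
    """

    lp0: np.ndarray  # (G,)
    W: np.ndarray  # (G, Q)
    lvl_dt: np.ndarray  # (G,)
    ev_lp0: np.ndarray  # (E,)
    ev_W: np.ndarray  # (E, Q)
    ev_log_level: np.ndarray  # (E,)


def _cell_edges(a: float, b: float, cuts: Sequence[float], step: float) -> np.ndarray:
    edges = {a, b}
    edges.update(c for c in cuts if a < c < b)
    n = int(np.ceil((b - a) / step))
    if n > 1:
        edges.update(a + (b - a) * np.arange(1, n) / n)
    return np.asarray(sorted(edges))


def _roster_parts(fit: JointModelFit, model: TransitionModel, baseline: BaselineCovariates, t: np.ndarray):
    """(lp0(t), W(t)) of the linear predictor for one transition."""
    lfit = fit.longitudinal
    Q = lfit.sigma_b.shape[0]
    lp0 = np.zeros(t.size)
    W = np.zeros((t.size, Q))
    for c, name in enumerate(model.covariates):
        coef = model.coef[c]
        if coef == 0.0:
            continue
        if name in LONGITUDINAL_VARIABLES:
            spec = lfit.spec(name)
            X = spec.design(t)
            lp0 += coef * (X @ lfit.beta[name] - model.center[c])
            W[:, lfit.rand_slices[name]] += coef * X[:, list(spec.random_terms)]
        else:
            lp0 += coef * (baseline.covariate(name) - model.center[c])
    return lp0, W


def _ms_structure(fit: JointModelFit, history: SubjectHistory, subgrid: float) -> _MsStructure:
    Q = fit.longitudinal.sigma_b.shape[0]
    lp0_parts, W_parts, lvl_parts = [], [], []
    ev_lp0, ev_W, ev_lvl = [], [], []
    for rec in history.state_path:
        for k in fit.state_space.transitions_from(rec.state):
            model = fit.transitions.get(k)
            if model is None:
                continue
            if rec.exit_time > rec.entry_time:
                edges = _cell_edges(rec.entry_time, rec.exit_time, model.baseline.cuts, subgrid)
                mids = 0.5 * (edges[:-1] + edges[1:])
                lp0, W = _roster_parts(fit, model, history.baseline, mids)
                lp0_parts.append(lp0)
                W_parts.append(W)
                lvl_parts.append(model.baseline.rate(mids) * np.diff(edges))
            if rec.next_state == k[1]:
                te = np.asarray([rec.exit_time])
                lp0, W = _roster_parts(fit, model, history.baseline, te)
                ev_lp0.append(lp0[0])
                ev_W.append(W[0])
                ev_lvl.append(np.log(model.baseline.rate(te)[0]))
    z = np.zeros((0, Q))
    return _MsStructure(
        lp0=np.concatenate(lp0_parts) if lp0_parts else np.zeros(0),
        W=np.vstack(W_parts) if W_parts else z,
        lvl_dt=np.concatenate(lvl_parts) if lvl_parts else np.zeros(0),
        ev_lp0=np.asarray(ev_lp0),
        ev_W=np.vstack(ev_W) if ev_W else z,
        ev_log_level=np.asarray(ev_lvl),
    )


def _ms_loglik_draws(st: _MsStructure, B: np.ndarray) -> np.ndarray:
    """Multistate log-likelihood of the history for each draw row of B."""
    B = np.atleast_2d(B)
    out = np.zeros(B.shape[0])
    if st.lp0.size:
        lp = st.lp0[None, :] + B @ st.W.T
        out -= np.exp(lp) @ st.lvl_dt
    if st.ev_lp0.size:
        out += (st.ev_log_level + st.ev_lp0)[None, :].sum(axis=1) + (B @ st.ev_W.T).sum(axis=1)
    return out


def _ms_grad(st: _MsStructure, b: np.ndarray) -> np.ndarray:
    g = np.zeros_like(b)
    if st.lp0.size:
        lam = np.exp(st.lp0 + st.W @ b) * st.lvl_dt
        g -= st.W.T @ lam
    if st.ev_W.size:
        g += st.ev_W.sum(axis=0)
    return g


def _long_parts(fit: LongitudinalFit, records: Sequence[LongitudinalRecord]):
    y, X, Z, v = _subject_design(list(records), fit.specs)
    beta_vec = np.concatenate([fit.beta[s.variable] for s in fit.specs])
    sig2 = np.asarray([fit.sigma[s.variable] ** 2 for s in fit.specs])
    resid0 = y - X @ beta_vec if y.size else y
    return y, Z, v, sig2, resid0


def _long_loglik_draws(parts, B: np.ndarray) -> np.ndarray:
    y, Z, v, sig2, resid0 = parts
    B = np.atleast_2d(B)
    if y.size == 0:
        return np.zeros(B.shape[0])
    E = resid0[None, :] - B @ Z.T
    const = -0.5 * np.sum(np.log(2 * np.pi * sig2[v]))
    return const - 0.5 * (E**2 / sig2[v][None, :]).sum(axis=1)


def _long_grad(parts, b: np.ndarray) -> np.ndarray:
    y, Z, v, sig2, resid0 = parts
    if y.size == 0:
        return np.zeros_like(b)
    return Z.T @ ((resid0 - Z @ b) / sig2[v])


def _prior_terms(sigma_b: np.ndarray):
    Q = sigma_b.shape[0]
    G = sigma_b + 1e-10 * np.eye(Q)
    Gi = np.linalg.inv(G)
    _, logdet = np.linalg.slogdet(G)
    const = -0.5 * (Q * np.log(2 * np.pi) + logdet)
    return Gi, const


# ---------------------------------------------------------------------------
# Joint likelihood of one subject
# ---------------------------------------------------------------------------

def _history_of(subject: Subject) -> SubjectHistory:
    return SubjectHistory(
        baseline=subject.baseline,
        records=list(subject.longitudinal),
        state_path=list(subject.path),
    )


def _integrand_mode(fit: JointModelFit, history: SubjectHistory, subgrid: float):
    """Laplace mode and curvature of log integrand over b."""
    st = _ms_structure(fit, history, subgrid)
    parts = _long_parts(fit.longitudinal, history.records)
    Gi, prior_const = _prior_terms(fit.longitudinal.sigma_b)
    Q = Gi.shape[0]

    def neg(b):
        ll = (
            _long_loglik_draws(parts, b[None, :])[0]
            + _ms_loglik_draws(st, b[None, :])[0]
            + prior_const
            - 0.5 * b @ Gi @ b
        )
        return -ll

    def neg_grad(b):
        return -(_long_grad(parts, b) + _ms_grad(st, b) - Gi @ b)

    res = minimize(neg, np.zeros(Q), jac=neg_grad, method="BFGS", options={"gtol": 1e-8})
    if not np.isfinite(res.fun):
        raise FloatingPointError(f"non-finite joint integrand at b={res.x}")
    # Hessian of the negative log integrand by central differences of the gradient
    eps = 1e-5
    H = np.zeros((Q, Q))
    for i in range(Q):
        e = np.zeros(Q)
        e[i] = eps
        H[:, i] = (neg_grad(res.x + e) - neg_grad(res.x - e)) / (2 * eps)
    H = 0.5 * (H + H.T)
    return res.x, -res.fun, H, st, parts, Gi, prior_const


def joint_log_likelihood(
    fit: JointModelFit, subject: Subject | SubjectHistory, settings: Optional[IntegrationSettings] = None
) -> float:
    """Marginal log-likelihood log Int p(y | b) p(path | b) p(b) db."""
    settings = fit.settings if settings is None else settings
    history = subject if isinstance(subject, SubjectHistory) else _history_of(subject)
    Q = fit.longitudinal.sigma_b.shape[0]

    if settings.method == "laplace":
        mode, g_mode, H, *_ = _integrand_mode(fit, history, settings.subgrid)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            warnings.warn("non-PD curvature at the Laplace mode; clipping eigenvalues")
            w = np.clip(np.linalg.eigvalsh(H), 1e-10, None)
            logdet = float(np.sum(np.log(w)))
        return float(g_mode + 0.5 * Q * np.log(2 * np.pi) - 0.5 * logdet)

    if settings.method == "gh":
        if Q != 1:
            raise ValueError("adaptive Gauss-Hermite integration is implemented for 1-D random effects")
        mode, _, H, st, parts, Gi, prior_const = _integrand_mode(fit, history, settings.subgrid)
        shat = 1.0 / np.sqrt(max(float(H[0, 0]), 1e-12))
        x, w = np.polynomial.hermite.hermgauss(settings.n_nodes)
        nodes = mode[0] + np.sqrt(2.0) * shat * x
        B = nodes[:, None]
        logf = (
            _long_loglik_draws(parts, B)
            + _ms_loglik_draws(st, B)
            + prior_const
            - 0.5 * Gi[0, 0] * nodes**2
        )
        return float(logsumexp(logf + x**2 + np.log(w)) + np.log(np.sqrt(2.0) * shat))

    if settings.method == "mc":
        st = _ms_structure(fit, history, settings.subgrid)
        parts = _long_parts(fit.longitudinal, history.records)
        rng = np.random.default_rng(settings.seed)
        half = max(settings.n_draws // 2, 1)
        w_, V = np.linalg.eigh(fit.longitudinal.sigma_b)
        L = V * np.sqrt(np.clip(w_, 0.0, None))
        Z = rng.standard_normal((half, Q))
        B = np.vstack([Z, -Z]) @ L.T  # antithetic prior draws
        logf = _long_loglik_draws(parts, B) + _ms_loglik_draws(st, B)
        return float(logsumexp(logf) - np.log(B.shape[0]))

    raise ValueError(f"unknown integration method {settings.method!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def posterior_mean_paths(fit: LongitudinalFit, cohort: Cohort) -> Dict[str, CovariatePath]:
    """Covariate paths from each subject's posterior-mean trajectory."""
    out = {}
    for s in cohort:
        post = posterior_random_effects(fit, s.longitudinal)
        mu = post.mean
        slices = fit.rand_slices

        def value(variable: str, t: np.ndarray, mu=mu) -> np.ndarray:
            spec = fit.spec(variable)
            X = spec.design(t)
            return X @ fit.beta[variable] + X[:, list(spec.random_terms)] @ mu[slices[variable]]

        out[s.id] = CovariatePath(s.baseline, trajectory=value)
    return out


def _pack_hazard_params(transitions: Dict[Transition, TransitionModel]):
    ks = sorted(transitions)
    theta, layout = [], []
    for k in ks:
        m = transitions[k]
        free = np.flatnonzero(~(m.lasso_zero if m.lasso_zero is not None else np.zeros(len(m.coef), bool)))
        layout.append((k, free, len(m.baseline.levels)))
        theta.extend(m.coef[free])
        theta.extend(np.log(np.maximum(m.baseline.levels, 1e-12)))
    return np.asarray(theta), layout


def _unpack_hazard_params(theta: np.ndarray, layout, transitions: Dict[Transition, TransitionModel]):
    out = {}
    i = 0
    for k, free, n_lvl in layout:
        m = transitions[k]
        coef = m.coef.copy()
        coef[free] = theta[i : i + len(free)]
        i += len(free)
        levels = tuple(np.exp(theta[i : i + n_lvl]))
        i += n_lvl
        out[k] = replace(m, coef=coef, baseline=replace(m.baseline, levels=levels), lasso_zero=m.lasso_zero)
    return out


def fit_joint(
    cohort: Cohort,
    specs,
    settings: Optional[IntegrationSettings] = None,
    rosters=None,
    structure: str = "blockdiag",
) -> JointModelFit:
    """Two-stage initialization followed by joint Laplace-likelihood refinement.

    Stage 1 fits the longitudinal mixed model; stage 2 fits the multistate
    model on posterior-mean trajectories; stage 3 (``settings.joint_refine``)
    maximizes the summed Laplace marginal likelihood over the hazard
    parameters (transition coefficients and baseline levels), keeping
    LASSO-zeroed coefficients at zero.  Both stage-wise and joint estimates
    are recorded.  On non-convergence the best iterate is returned flagged.
    """
    settings = IntegrationSettings() if settings is None else settings
    lfit = fit_mixed(cohort, specs, structure=structure)
    paths = posterior_mean_paths(lfit, cohort)
    models, table = fit_multistate(cohort, paths, lam=settings.lam, rosters=rosters, subgrid=settings.subgrid)
    fit = JointModelFit(longitudinal=lfit, transitions=models, settings=settings)
    fit.stagewise = {
        "transitions": {k: m.coef.copy() for k, m in models.items()},
        "inference_table": table,
    }
    if not settings.joint_refine:
        fit.log_likelihood = float(
            sum(joint_log_likelihood(fit, s, replace(settings, method="laplace")) for s in cohort)
        )
        return fit

    histories = [_history_of(s) for s in cohort]
    theta0, layout = _pack_hazard_params(models)
    laplace = replace(settings, method="laplace")

    def negtotal(theta):
        trans = _unpack_hazard_params(theta, layout, models)
        cand = JointModelFit(longitudinal=lfit, transitions=trans, settings=settings)
        try:
            return -sum(joint_log_likelihood(cand, h, laplace) for h in histories)
        except FloatingPointError:
            return 1e12

    res = minimize(
        negtotal,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": settings.refine_maxiter, "ftol": 1e-10},
    )
    fit.transitions = _unpack_hazard_params(res.x, layout, models)
    fit.log_likelihood = float(-res.fun)
    fit.converged = bool(res.success) or res.status == 1  # status 1 = maxiter
    if not res.success and res.status != 1:
        warnings.warn(f"joint refinement did not converge: {res.message}")
    return fit


# ---------------------------------------------------------------------------
# Dynamic prediction
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    draws: np.ndarray  # (D, Q) proposal draws
    log_weights: np.ndarray
    ess: float
    proposal: PosteriorRandomEffects

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - self.log_weights.max())
        return w / w.sum()


def sample_posterior_random_effects(
    fit: JointModelFit,
    history: SubjectHistory,
    n_draws: int = 500,
    seed: int = 0,
    subgrid: Optional[float] = None,
) -> PosteriorDraws:
    """Importance-sampled draws from p(b | records, state history up to s).

    Proposal: the exact Gaussian posterior given the longitudinal records
    only; weights: the multistate likelihood of the observed state history
    (survival in the current state, plus earlier observed transitions).
    """
    subgrid = fit.settings.subgrid if subgrid is None else subgrid
    prop = posterior_random_effects(fit.longitudinal, history.records)
    rng = np.random.default_rng(seed)
    w_, V = np.linalg.eigh(prop.cov)
    L = V * np.sqrt(np.clip(w_, 0.0, None))
    B = prop.mean[None, :] + rng.standard_normal((n_draws, prop.mean.size)) @ L.T
    st = _ms_structure(fit, history, subgrid)
    logw = _ms_loglik_draws(st, B)
    logw = logw - logw.max()
    w = np.exp(logw)
    ess = float(w.sum() ** 2 / (w**2).sum())
    if ess < 0.05 * n_draws:
        warnings.warn(
            f"importance-sampling ESS {ess:.0f} < 5% of {n_draws} draws; increase n_draws"
        )
    return PosteriorDraws(draws=B, log_weights=logw, ess=ess, proposal=prop)


def predict_trajectory(
    fit: JointModelFit,
    history: SubjectHistory,
    horizon: float,
    n_draws: int = 500,
    seed: int = 0,
    n_grid: int = 61,
) -> Dict[str, dict]:
    """Per-variable posterior mean and 95% band of m_j(u) on [s, s+horizon]."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    pd_draws = sample_posterior_random_effects(fit, history, n_draws=n_draws, seed=seed)
    w = pd_draws.weights
    s = history.landmark
    grid = np.linspace(s, s + horizon, n_grid)
    lfit = fit.longitudinal
    out = {}
    for spec in lfit.specs:
        X = spec.design(grid)
        base = X @ lfit.beta[spec.variable]
        Zr = X[:, list(spec.random_terms)]
        M = base[None, :] + pd_draws.draws[:, lfit.rand_slices[spec.variable]] @ Zr.T
        mean = w @ M
        order = np.argsort(M, axis=0)
        lo = np.empty(grid.size)
        hi = np.empty(grid.size)
        for g in range(grid.size):
            mg = M[order[:, g], g]
            cw = np.cumsum(w[order[:, g]])
            lo[g] = mg[np.searchsorted(cw, 0.025)]
            hi[g] = mg[min(np.searchsorted(cw, 0.975), n_draws - 1)]
        out[spec.variable] = {"times": grid, "mean": mean, "lower": lo, "upper": hi}
    return out


def _occupancy_given_draws(
    fit: JointModelFit,
    baseline: BaselineCovariates,
    B: np.ndarray,
    s: float,
    grid: np.ndarray,
    start_state: int,
    step: float,
) -> np.ndarray:
    """(D, len(grid), 4) occupancy per draw by the vectorized product integral."""
    D = B.shape[0]
    t_end = float(grid[-1])
    n = max(int(np.ceil((t_end - s) / step)), 1)
    edges = np.linspace(s, t_end, n + 1)
    lefts = edges[:-1]
    dts = np.diff(edges)
    rates = {}
    for k, model in fit.transitions.items():
        lp0, W = _roster_parts(fit, model, baseline, lefts)
        rates[k] = model.baseline.rate(lefts)[None, :] * np.exp(lp0[None, :] + B @ W.T)
    p = np.zeros((D, 4))
    p[:, start_state - 1] = 1.0
    snap = np.searchsorted(edges, grid - 1e-12)
    out = np.empty((D, grid.size, 4))
    gi = 0
    while gi < grid.size and snap[gi] == 0:
        out[:, gi] = p
        gi += 1
    for i in range(n):
        dt = dts[i]
        # total outflow rate per source state and draw; when h*dt is not
        # small the Euler step could remove more mass than the state holds,
        # so the outflow is scaled to its exact within-step exponential
        tot = {q: np.zeros(D) for q in (1, 2, 3)}
        for (q, _), r in rates.items():
            tot[q] += r[:, i]
        scale = {}
        for q, h in tot.items():
            x = h * dt
            scale[q] = np.where(x > 0.05, -np.expm1(-x) / np.maximum(x, 1e-300), 1.0)
        flows = {k: p[:, k[0] - 1] * r[:, i] * dt * scale[k[0]] for k, r in rates.items()}
        for (q, r_), f in flows.items():
            p[:, q - 1] -= f
            p[:, r_ - 1] += f
        np.clip(p, 0.0, 1.0, out=p)
        while gi < grid.size and snap[gi] == i + 1:
            out[:, gi] = p
            gi += 1
    while gi < grid.size:
        out[:, gi] = p
        gi += 1
    return out


def predict_occupancy(
    fit: JointModelFit,
    history: SubjectHistory,
    grid,
    n_draws: int = 500,
    seed: int = 0,
    step: float = 1.0 / 120.0,
) -> DynamicPrediction:
    """State-occupation probabilities P(state(u) = r | history up to s).

    For each posterior draw of b the product-integral is started from unit
    mass at the current state; the weighted average over draws is returned
    with a Monte-Carlo standard error per state and time.
    """
    if history.current_state == 4:
        raise ValueError("prediction is undefined from the absorbing diabetes state")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    s = history.landmark
    if np.any(grid < s - 1e-9):
        raise ValueError("prediction grid must start at or after the landmark")
    pd_draws = sample_posterior_random_effects(fit, history, n_draws=n_draws, seed=seed)
    w = pd_draws.weights
    occ_draws = _occupancy_given_draws(
        fit, history.baseline, pd_draws.draws, s, grid, history.current_state, step
    )
    occupancy = np.einsum("d,dgs->gs", w, occ_draws)
    centered = occ_draws - occupancy[None, :, :]
    mc_se = np.sqrt(np.einsum("d,dgs->gs", w**2, centered**2))
    return DynamicPrediction(
        times=grid,
        occupancy=occupancy,
        mc_se=mc_se,
        landmark=s,
        current_state=history.current_state,
        n_draws=n_draws,
        seed=seed,
        ess=pd_draws.ess,
    )


def update_prediction(
    fit: JointModelFit,
    old_history: SubjectHistory,
    new_records: Sequence[LongitudinalRecord],
    new_state_info: Sequence[StateRecord],
    grid,
    n_draws: int = 500,
    seed: int = 0,
    step: float = 1.0 / 120.0,
) -> DynamicPrediction:
    """Recompute the prediction on the concatenated history (no incremental
    state is kept)."""
    s_old = old_history.landmark
    if any(r.time < s_old - 1e-9 for r in new_records):
        raise ValueError("new longitudinal records overlap the old history")
    state_path = list(old_history.state_path)
    if new_state_info:
        first = new_state_info[0]
        if first.entry_time < s_old - 1e-9:
            raise ValueError("new state info overlaps the old history")
        last = state_path[-1]
        if first.state != (last.state if last.next_state is None else last.next_state):
            raise ValueError("new state info contradicts the current state")
        if last.next_state is None and first.state == last.state:
            # the old censoring was just the landmark: merge the sojourns
            state_path[-1] = replace(first, entry_time=last.entry_time)
            state_path.extend(new_state_info[1:])
        else:
            state_path.extend(new_state_info)
    history = SubjectHistory(
        baseline=old_history.baseline,
        records=list(old_history.records) + list(new_records),
        state_path=state_path,
    )
    return predict_occupancy(fit, history, grid, n_draws=n_draws, seed=seed, step=step)


def truth_joint_fit(config) -> JointModelFit:
    """JointModelFit assembled from a simulator config's ground truth."""
    from .simulate import truth_transition_models

    lfit = LongitudinalFit(
        specs=list(config.specs),
        beta={k: np.asarray(v, dtype=float) for k, v in config.beta.items()},
        sigma=dict(config.sigma),
        sigma_b=np.asarray(config.sigma_b, dtype=float),
        log_likelihood=np.nan,
        converged=True,
        n_iter=0,
        loglik_trace=np.zeros(0),
    )
    return JointModelFit(longitudinal=lfit, transitions=truth_transition_models(config))
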