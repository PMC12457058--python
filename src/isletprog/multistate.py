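"""Transition-specific proportional hazards over the four-state graph.

Each transition k = (q, r) has intensity

    h_k(t) = h0_k(t) * exp( coef_k . (x(t) - center_k) )

with a piecewise-constant baseline h0_k and a covariate vector x(t) mixing
time-invariant baseline covariates and the *current values* of longitudinal
variables.  The likelihood is a full (not partial) likelihood; sojourn
exposure is split into cells on the baseline cut points and a configurable
sub-grid, on which the longitudinal covariates are treated as constant, so the
integrated intensity is exact for piecewise-constant covariate paths.

L1 (LASSO) selection of covariates is an own FISTA proximal-gradient solver
on the exposure-split Poisson representation with penalties applied on the
standardized-covariate scale; unpenalized fits and Wald inference go through
statsmodels GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import LONGITUDINAL_VARIABLES, BaselineCovariates, Cohort, Subject
from .states import DEFAULT_STATE_SPACE, StateSpace, Transition
from .truth import TRANSITION_COEFS

__all__ = [
    "PiecewiseConstantHazard",
    "TransitionModel",
    "CovariatePath",
    "hazard",
    "multistate_log_likelihood",
    "fit_multistate",
    "cv_select_lambda",
    "transition_probability_matrix",
    "DEFAULT_ROSTERS",
]

#: Default covariate rosters per transition (the published proposal sets).
DEFAULT_ROSTERS: Dict[Transition, Tuple[str, ...]] = {
    k: tuple(name for name, _ in rows) for k, rows in TRANSITION_COEFS.items()
}


@dataclass(frozen=True)
class PiecewiseConstantHazard:
    """Piecewise-constant baseline hazard; the last level extends beyond the
    final cut point."""

    cuts: Tuple[float, ...]
    levels: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.cuts) + 1:
            raise ValueError("need len(levels) == len(cuts) + 1")
        if any(lv < 0 for lv in self.levels):
            raise ValueError("hazard levels must be non-negative")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    def rate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts), t, side="right")
        return np.asarray(self.levels)[idx]

    def segment_edges(self, a: float, b: float) -> np.ndarray:
        """Sorted breakpoints of [a, b] at the interior cut points."""
        inner = [c for c in self.cuts if a < c < b]
        return np.asarray([a, *inner, b])


@dataclass
class TransitionModel:
    transition: Transition
    covariates: Tuple[str, ...]
    coef: np.ndarray
    baseline: PiecewiseConstantHazard
    center: np.ndarray = None  # type: ignore[assignment]
    lasso_zero: Optional[np.ndarray] = None
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.center is None:
            self.center = np.zeros(len(self.covariates))
        self.center = np.asarray(self.center, dtype=float)
        if len(self.coef) != len(self.covariates) or len(self.center) != len(self.covariates):
            raise ValueError("coefficient/center length must match the covariate roster")
        if self.lasso_zero is not None:
            self.lasso_zero = np.asarray(self.lasso_zero, dtype=bool)
            if np.any(self.coef[self.lasso_zero] != 0.0):
                raise ValueError("zero-flagged coefficients must be exactly 0")

    @property
    def gamma(self) -> Dict[str, float]:
        """Coefficients of time-invariant covariates."""
        return {
            c: float(b)
            for c, b in zip(self.covariates, self.coef)
            if c not in LONGITUDINAL_VARIABLES
        }

    @property
    def alpha(self) -> Dict[str, float]:
        """Coefficients of longitudinal current values."""
        return {
            c: float(b)
            for c, b in zip(self.covariates, self.coef)
            if c in LONGITUDINAL_VARIABLES
        }


class CovariatePath:
    """Per-subject covariate paths: fixed covariates plus longitudinal current
    values as a function of time since GADA positivity.

    ``trajectory`` maps (variable, times array) -> values array; ``None`` is
    acceptable when no roster uses longitudinal variables.
    """

    def __init__(
        self,
        baseline: BaselineCovariates,
        trajectory: Optional[Callable[[str, np.ndarray], np.ndarray]] = None,
    ):
        self.baseline = baseline
        self.trajectory = trajectory

    def values(self, names: Sequence[str], times) -> np.ndarray:
        """Array of shape (len(names), len(times))."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((len(names), t.size))
        for i, name in enumerate(names):
            if name in LONGITUDINAL_VARIABLES:
                if self.trajectory is None:
                    raise ValueError(f"no trajectory available for covariate {name!r}")
                out[i] = np.asarray(self.trajectory(name, t), dtype=float)
            else:
                out[i] = self.baseline.covariate(name)
        return out


def hazard(model: TransitionModel, path: CovariatePath, t, state_space: StateSpace = DEFAULT_STATE_SPACE):
    """Transition intensity h_k(t) (per year) for one subject."""
    if model.transition not in state_space.allowed_transitions:
        raise ValueError(f"transition {model.transition} is not allowed")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = model.baseline.rate(t) * np.exp(_lp(model, path, t))
    return out if out.size > 1 else float(out[0])


def _lp(model: TransitionModel, path: CovariatePath, t: np.ndarray) -> np.ndarray:
    """Linear predictor; covariates with zero coefficient are never evaluated."""
    lp = np.zeros(t.size)
    for c, name, ctr in zip(model.coef, model.covariates, model.center):
        if c != 0.0:
            lp += c * (path.values([name], t)[0] - ctr)
    return lp


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _sojourns(subject: Subject):
    """(state, entry, exit, next_state) tuples of a subject's observed path."""
    for rec in subject.path:
        yield rec.state, rec.entry_time, rec.exit_time, rec.next_state


def _cell_grid(a: float, b: float, cuts: Sequence[float], step: float) -> np.ndarray:
    """Breakpoints of [a,b] refined by the baseline cuts and a sub-grid step."""
    edges = {a, b}
    edges.update(c for c in cuts if a < c < b)
    n = int(np.ceil((b - a) / step))
    if n > 1:
        edges.update(a + (b - a) * np.arange(1, n) / n)
    return np.asarray(sorted(edges))


def multistate_log_likelihood(
    models: Dict[Transition, TransitionModel],
    cohort: Cohort,
    paths: Dict[str, CovariatePath],
    subgrid: float = 1.0 / 12.0,
    state_space: StateSpace = DEFAULT_STATE_SPACE,
) -> float:
    """Full log-likelihood of the observed state paths.

    Sum over subjects and transitions of event log-intensities minus the
    integrated intensity over the at-risk sojourns; integrals are exact per
    cell with covariates evaluated at cell midpoints on the sub-grid.
    """
    total = 0.0
    for subject in cohort:
        path = paths[subject.id]
        for state, a, b, next_state in _sojourns(subject):
            for k in state_space.transitions_from(state):
                if k not in models:
                    continue
                model = models[k]
                if b > a:
                    edges = _cell_grid(a, b, model.baseline.cuts, subgrid)
                    mids = 0.5 * (edges[:-1] + edges[1:])
                    dts = np.diff(edges)
                    rates = model.baseline.rate(mids) * np.exp(_lp(model, path, mids))
                    total -= float(rates @ dts)
                if next_state == k[1]:
                    h = model.baseline.rate(np.asarray([b]))[0] * np.exp(
                        _lp(model, path, np.asarray([b]))[0]
                    )
                    total += float(np.log(h))
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class _TransitionData:
    """Exposure-split Poisson representation of one transition's risk set."""

    transition: Transition
    covariates: Tuple[str, ...]
    X: np.ndarray  # centered covariate values at cell midpoints
    seg: np.ndarray  # baseline segment index per cell
    n_seg: int
    dt: np.ndarray
    d: np.ndarray  # event indicator per cell
    center: np.ndarray
    subject_idx: np.ndarray
    cuts: Tuple[float, ...]


def _default_cuts(event_times: np.ndarray, n_pieces: int = 3) -> Tuple[float, ...]:
    """Interior cut points at tertiles of observed transition times."""
    if event_times.size < n_pieces + 1:
        return ()
    qs = np.quantile(event_times, np.linspace(0, 1, n_pieces + 1)[1:-1])
    qs = np.unique(np.round(qs, 6))
    return tuple(float(q) for q in qs)


def _build_transition_data(
    cohort: Cohort,
    paths: Dict[str, CovariatePath],
    k: Transition,
    roster: Tuple[str, ...],
    cuts: Optional[Tuple[float, ...]],
    subgrid: float,
) -> Optional[_TransitionData]:
    q, r = k
    event_times = []
    sojourns = []
    for idx, subject in enumerate(cohort):
        for state, a, b, next_state in _sojourns(subject):
            if state != q or b <= a:
                continue
            ev = next_state == r
            sojourns.append((idx, subject.id, a, b, ev))
            if ev:
                event_times.append(b)
    if not event_times:
        return None
    if cuts is None:
        cuts = _default_cuts(np.asarray(event_times))
    seg_edges = np.asarray(cuts)

    X_parts, seg_parts, dt_parts, d_parts, subj_parts = [], [], [], [], []
    for idx, sid, a, b, ev in sojourns:
        edges = _cell_grid(a, b, cuts, subgrid)
        mids = 0.5 * (edges[:-1] + edges[1:])
        dts = np.diff(edges)
        X_parts.append(paths[sid].values(roster, mids).T)
        seg_parts.append(np.searchsorted(seg_edges, mids, side="right"))
        dt_parts.append(dts)
        d = np.zeros(len(mids))
        if ev:
            d[-1] = 1.0
        d_parts.append(d)
        subj_parts.append(np.full(len(mids), idx))

    X = np.vstack(X_parts)
    dt = np.concatenate(dt_parts)
    center = (X * dt[:, None]).sum(axis=0) / dt.sum()
    return _TransitionData(
        transition=k,
        covariates=roster,
        X=X - center,
        seg=np.concatenate(seg_parts).astype(int),
        n_seg=len(cuts) + 1,
        dt=dt,
        d=np.concatenate(d_parts),
        center=center,
        subject_idx=np.concatenate(subj_parts).astype(int),
        cuts=tuple(cuts),
    )


def _poisson_loglik(data: _TransitionData, coef: np.ndarray, log_levels: np.ndarray) -> float:
    eta = data.X @ coef + log_levels[data.seg]
    mu = np.exp(eta) * data.dt
    return float(data.d @ eta - mu.sum())


def _profile_log_levels(data: _TransitionData, coef: np.ndarray) -> np.ndarray:
    """Closed-form baseline levels maximizing the likelihood given coef."""
    w = np.exp(data.X @ coef) * data.dt
    D = np.bincount(data.seg, weights=data.d, minlength=data.n_seg)
    E = np.bincount(data.seg, weights=w, minlength=data.n_seg)
    with np.errstate(divide="ignore"):
        return np.where(D > 0, np.log(np.maximum(D, 1e-300) / E), np.log(1e-10 / E))


def _fista_lasso(
    data: _TransitionData,
    lam: float,
    penalty_scale: np.ndarray,
    coef0: Optional[np.ndarray] = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> np.ndarray:
    """FISTA on the profiled penalized Poisson log-likelihood.

    Maximizes  ell(coef) - lam * sum_j penalty_scale_j * |coef_j|  with the
    baseline levels profiled out in closed form at each step.
    """
    p = data.X.shape[1]
    coef = np.zeros(p) if coef0 is None else coef0.copy()
    z = coef.copy()
    t_acc = 1.0
    L = 1.0  # local Lipschitz estimate, adapted by backtracking

    # profiled-likelihood constants: per-segment event counts
    D = np.bincount(data.seg, weights=data.d, minlength=data.n_seg)
    pos = D > 0
    const = float(np.sum(D[pos] * np.log(D[pos])) - D.sum())

    def value_grad(c, need_grad=True):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            xc = data.X @ c
            w = np.exp(xc) * data.dt
            E = np.bincount(data.seg, weights=w, minlength=data.n_seg)
            ll = float(data.d @ xc) + const - float(np.sum(D[pos] * np.log(E[pos])))
            if not need_grad:
                return ll, None
            lv = np.where(E > 0, D / np.maximum(E, 1e-300), 0.0)
            mu = lv[data.seg] * w
            grad = data.X.T @ (data.d - mu)
        return ll, grad

    f_old = -np.inf
    for _ in range(max_iter):
        ll_z, grad_z = value_grad(z)
        while True:
            step = 1.0 / L
            cand = z + step * grad_z
            thresh = lam * penalty_scale * step
            new = np.sign(cand) * np.maximum(np.abs(cand) - thresh, 0.0)
            ll_new, _ = value_grad(new, need_grad=False)
            dz = new - z
            # backtracking on the majorization of -ll
            if np.isfinite(ll_new) and -ll_new <= -ll_z - grad_z @ dz + 0.5 * L * (dz @ dz) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        z = new + ((t_acc - 1.0) / t_new) * (new - coef)
        coef, t_acc = new, t_new
        f = ll_new - lam * float(penalty_scale @ np.abs(new))
        if abs(f - f_old) < tol * (1.0 + abs(f)):
            break
        f_old = f
        L = max(L / 1.5, 1e-6)
    coef[np.abs(coef) < 1e-8] = 0.0
    return coef


def _glm_fit(data: _TransitionData, cols: np.ndarray):
    """Unpenalized Poisson GLM on selected covariate columns + segment dummies."""
    import statsmodels.api as sm

    n = data.X.shape[0]
    seg_dummies = np.zeros((n, data.n_seg))
    seg_dummies[np.arange(n), data.seg] = 1.0
    design = np.hstack([seg_dummies, data.X[:, cols]])
    model = sm.GLM(data.d, design, family=sm.families.Poisson(), offset=np.log(data.dt))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return res


_COEF_CAP = 50.0


def fit_multistate(
    cohort: Cohort,
    paths: Dict[str, CovariatePath],
    lam: float | Dict[Transition, float] = 0.0,
    rosters: Optional[Dict[Transition, Tuple[str, ...]]] = None,
    cuts: Optional[Dict[Transition, Tuple[float, ...]]] = None,
    subgrid: float = 1.0 / 12.0,
    state_space: StateSpace = DEFAULT_STATE_SPACE,
) -> Tuple[Dict[Transition, TransitionModel], pd.DataFrame]:
    """Fit all transitions; returns the fitted models and an inference table.

    With ``lam == 0`` this is a plain ML fit with Wald standard errors.  With
    ``lam > 0`` covariates are selected by L1 penalization (standardized
    scale), exact zeros are reported for excluded covariates, and SEs/p-values
    come from an unpenalized refit on the selected set (post-selection); the SE
    shown for an excluded covariate comes from a one-at-a-time re-entry refit
    and is descriptive, not inferential.
    """
    rosters = dict(DEFAULT_ROSTERS) if rosters is None else rosters
    models: Dict[Transition, TransitionModel] = {}
    rows = []

    for k in sorted(state_space.allowed_transitions):
        roster = rosters.get(k)
        if roster is None:
            continue
        data = _build_transition_data(
            cohort, paths, k, tuple(roster), None if cuts is None else cuts.get(k), subgrid
        )
        if data is None:
            continue  # no events: transition reported as unfit
        sd = np.sqrt(np.average(data.X**2, axis=0, weights=data.dt))
        sd = np.where(sd > 1e-12, sd, 1.0)

        lam_k = float(lam[k]) if isinstance(lam, dict) else float(lam)
        if lam_k > 0:
            coef = _fista_lasso(data, lam_k, penalty_scale=sd)
            selected = coef != 0.0
        else:
            selected = np.ones(len(roster), dtype=bool)

        res = _glm_fit(data, np.flatnonzero(selected))
        n_seg = data.n_seg
        log_levels = res.params[:n_seg]
        coef_full = np.zeros(len(roster))
        se_full = np.full(len(roster), np.nan)
        p_full = np.full(len(roster), np.nan)
        coef_full[selected] = res.params[n_seg:]
        se_full[selected] = res.bse[n_seg:]
        p_full[selected] = res.pvalues[n_seg:]
        if np.any(np.abs(coef_full) > _COEF_CAP):
            warnings.warn(
                f"transition {k}: divergent coefficient capped at +/-{_COEF_CAP} (possible separation)"
            )
            coef_full = np.clip(coef_full, -_COEF_CAP, _COEF_CAP)

        # one-at-a-time re-entry SEs for LASSO-excluded covariates (descriptive)
        for j in np.flatnonzero(~selected):
            cols = np.flatnonzero(selected | (np.arange(len(roster)) == j))
            try:
                res_j = _glm_fit(data, cols)
                pos = n_seg + int(np.searchsorted(cols, j))
                se_full[j] = res_j.bse[pos]
            except Exception:  # pragma: no cover - degenerate refit
                pass

        baseline = PiecewiseConstantHazard(cuts=data.cuts, levels=tuple(np.exp(log_levels)))
        models[k] = TransitionModel(
            transition=k,
            covariates=tuple(roster),
            coef=coef_full,
            baseline=baseline,
            center=data.center,
            lasso_zero=~selected,
            lam=lam_k,
        )
        for j, name in enumerate(roster):
            rows.append(
                {
                    "transition": f"{k[0]}->{k[1]}",
                    "variable": name,
                    "coefficient": coef_full[j],
                    "std_err": se_full[j],
                    "p_value": p_full[j] if selected[j] else np.nan,
                    "selected": bool(selected[j]),
                }
            )

    table = pd.DataFrame(rows, columns=["transition", "variable", "coefficient", "std_err", "p_value", "selected"])
    return models, table


def _held_out_loglik(data: _TransitionData, mask: np.ndarray, coef: np.ndarray, log_levels: np.ndarray) -> float:
    eta = data.X[mask] @ coef + log_levels[data.seg[mask]]
    mu = np.exp(eta) * data.dt[mask]
    return float(data.d[mask] @ eta - mu.sum())


def _lambda_path(data: _TransitionData, sd: np.ndarray, n: int = 8, ratio: float = 3e-3) -> np.ndarray:
    """glmnet-style grid: from the smallest all-zero lambda down ``ratio``-fold.

    lambda_max is the largest standardized null-score component, i.e. the
    penalty at which the first covariate would enter.
    """
    log_lv = _profile_log_levels(data, np.zeros(data.X.shape[1]))
    mu = np.exp(data.X @ np.zeros(data.X.shape[1]) + log_lv[data.seg]) * data.dt
    score = data.X.T @ (data.d - mu)
    lam_max = float(np.max(np.abs(score) / sd)) * 1.05
    return np.geomspace(lam_max, lam_max * ratio, n)


def cv_select_lambda(
    cohort: Cohort,
    paths: Dict[str, CovariatePath],
    grid: Optional[Sequence[float]] = None,
    folds: int = 5,
    seed: int = 0,
    rule: str = "1se",
    rosters: Optional[Dict[Transition, Tuple[str, ...]]] = None,
    subgrid: float = 1.0 / 12.0,
    state_space: StateSpace = DEFAULT_STATE_SPACE,
) -> Dict[Transition, float]:
    """Per-transition penalty selection by subject-level K-fold CV.

    The CV score is the held-out unpenalized log-likelihood.  ``rule`` is
    ``"min"`` (score-maximizing lambda) or ``"1se"`` (largest lambda whose
    score is within one standard error of the maximum; the default, favouring
    parsimonious selection).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grid is not None:
        grid = np.asarray(sorted(grid, reverse=True), dtype=float)
        if np.any(grid <= 0):
            raise ValueError("lambda grid must be positive")
    rosters = dict(DEFAULT_ROSTERS) if rosters is None else rosters

    rng = np.random.default_rng(seed)
    n = len(cohort)
    fold_of = rng.permutation(n) % folds

    out: Dict[Transition, float] = {}
    for k in sorted(state_space.allowed_transitions):
        roster = rosters.get(k)
        if roster is None:
            continue
        data = _build_transition_data(cohort, paths, k, tuple(roster), None, subgrid)
        if data is None:
            continue
        sd = np.sqrt(np.average(data.X**2, axis=0, weights=data.dt))
        sd = np.where(sd > 1e-12, sd, 1.0)
        grid_k = _lambda_path(data, sd) if grid is None else grid
        scores = np.zeros((folds, len(grid_k)))
        cell_fold = fold_of[data.subject_idx]
        for f in range(folds):
            test = cell_fold == f
            train = ~test
            if data.d[train].sum() == 0 or data.d[test].sum() == 0:
                raise ValueError(f"degenerate fold {f} for transition {k}: a fold has no events")
            sub = _TransitionData(
                transition=k,
                covariates=data.covariates,
                X=data.X[train],
                seg=data.seg[train],
                n_seg=data.n_seg,
                dt=data.dt[train],
                d=data.d[train],
                center=data.center,
                subject_idx=data.subject_idx[train],
                cuts=data.cuts,
            )
            coef = None
            for gi, lamv in enumerate(grid_k):
                coef = _fista_lasso(sub, lamv, penalty_scale=sd, coef0=coef)
                log_levels = _profile_log_levels(sub, coef)
                scores[f, gi] = _held_out_loglik(data, test, coef, log_levels)
        mean = scores.mean(axis=0)
        if len(grid_k) == 1:
            out[k] = float(grid_k[0])
            continue
        best = int(np.argmax(mean))
        if rule == "min":
            out[k] = float(grid_k[best])
        elif rule == "1se":
            se = scores.std(axis=0, ddof=1) / np.sqrt(folds)
            ok = mean >= mean[best] - se[best]
            out[k] = float(grid_k[: best + 1][ok[: best + 1]].max())  # largest qualifying lambda
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return out


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def transition_probability_matrix(
    models: Dict[Transition, TransitionModel],
    path: CovariatePath,
    s: float,
    t: float,
    step: float = 1e-3,
    state_space: StateSpace = DEFAULT_STATE_SPACE,
) -> np.ndarray:
    """4x4 matrix P(s, t) by the product integral prod (I + A(u) du).

    Rows index the starting state; rows sum to 1; unreachable entries are 0.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if t < s:
        raise ValueError("need s <= t")
    n_states = len(state_space.states)
    P = np.eye(n_states)
    if t == s:
        return P
    n = int(np.ceil((t - s) / step))
    edges = np.linspace(s, t, n + 1)
    lefts = edges[:-1]
    dts = np.diff(edges)
    # precompute hazards on the grid per transition
    rates = {}
    for k, model in models.items():
        rates[k] = model.baseline.rate(lefts) * np.exp(_lp(model, path, lefts))
    for i in range(n):
        A = np.zeros((n_states, n_states))
        for (q, r), rv in rates.items():
            A[q - 1, r - 1] = rv[i]
        np.fill_diagonal(A, -A.sum(axis=1))
        P = P + (P @ A) * dts[i]
    return P
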