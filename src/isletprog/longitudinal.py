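"""Multivariate linear mixed-effects model for the longitudinal variables.

All variables of a subject are stacked into one Gaussian model

    y_i = X_i beta + Z_i b_i + eps_i,   b_i ~ N(0, Sigma_b),
    eps_i ~ N(0, diag(sigma_j^2))

where X_i block-stacks each variable's spline basis, Z_i the random-effect
columns, and Sigma_b couples random effects within (and optionally across)
variables.  Estimation is maximum likelihood by an ECM algorithm with exact
conditional M-steps, which makes the log-likelihood provably non-decreasing
across iterations.  Two Sigma_b structures are supported:

* ``"blockdiag"`` (default): unstructured within each variable's random
  terms, independent across variables;
* ``"unstructured"``: one full covariance coupling all variables.

The exact Gaussian posterior of b_i given a subject's observed records (used
for trajectory inference and as the proposal of the dynamic predictor) is
available in closed form via :func:`posterior_random_effects`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import Cohort, LongitudinalRecord, Subject
from .splines import LongitudinalSpec

__all__ = [
    "LongitudinalFit",
    "PosteriorRandomEffects",
    "fit_mixed",
    "predict_mean",
    "posterior_random_effects",
]

_SIGMA_FLOOR = 1e-6
_RIDGE = 1e-10


@dataclass
class LongitudinalFit:
    specs: List[LongitudinalSpec]
    beta: Dict[str, np.ndarray]
    sigma: Dict[str, float]
    sigma_b: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    beta_cov: Optional[np.ndarray] = None  # GLS covariance of stacked beta
    structure: str = "blockdiag"

    @property
    def variables(self) -> List[str]:
        return [s.variable for s in self.specs]

    @property
    def fixed_slices(self) -> Dict[str, slice]:
        out, off = {}, 0
        for s in self.specs:
            out[s.variable] = slice(off, off + s.spline.dimension)
            off += s.spline.dimension
        return out

    @property
    def rand_slices(self) -> Dict[str, slice]:
        out, off = {}, 0
        for s in self.specs:
            out[s.variable] = slice(off, off + s.n_random)
            off += s.n_random
        return out

    def spec(self, variable: str) -> LongitudinalSpec:
        for s in self.specs:
            if s.variable == variable:
                return s
        raise KeyError(variable)

    def beta_se(self, variable: str) -> np.ndarray:
        if self.beta_cov is None:
            raise ValueError("fit carries no beta covariance")
        sl = self.fixed_slices[variable]
        return np.sqrt(np.diag(self.beta_cov)[sl])

    def mean_value(self, variable: str, times) -> np.ndarray:
        """Population mean trajectory x(t)' beta_j (no random effects)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if t.size == 0:
            return np.zeros(0)
        return self.spec(variable).design(t) @ self.beta[variable]


@dataclass
class PosteriorRandomEffects:
    mean: np.ndarray
    cov: np.ndarray


def _subject_design(
    subject_records: Sequence[LongitudinalRecord],
    specs: List[LongitudinalSpec],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stacked (y, X, Z, var_index) for one subject's records."""
    P = sum(s.spline.dimension for s in specs)
    Q = sum(s.n_random for s in specs)
    names = [s.variable for s in specs]
    unknown = {r.variable for r in subject_records} - set(names)
    if unknown:
        raise KeyError(f"records for unknown variable(s) {sorted(unknown)}")
    rows_y, rows_X, rows_Z, rows_v = [], [], [], []
    f_off = np.cumsum([0] + [s.spline.dimension for s in specs])
    r_off = np.cumsum([0] + [s.n_random for s in specs])
    for j, spec in enumerate(specs):
        recs = [r for r in subject_records if r.variable == spec.variable]
        if not recs:
            continue
        t = np.asarray([r.time for r in recs])
        y = np.asarray([r.value for r in recs])
        Xj = spec.design(t)
        Zj = Xj[:, list(spec.random_terms)]
        X = np.zeros((len(t), P))
        Z = np.zeros((len(t), Q))
        X[:, f_off[j] : f_off[j + 1]] = Xj
        Z[:, r_off[j] : r_off[j + 1]] = Zj
        rows_y.append(y)
        rows_X.append(X)
        rows_Z.append(Z)
        rows_v.append(np.full(len(t), j))
    if not rows_y:
        return np.zeros(0), np.zeros((0, P)), np.zeros((0, Q)), np.zeros(0, dtype=int)
    return (
        np.concatenate(rows_y),
        np.vstack(rows_X),
        np.vstack(rows_Z),
        np.concatenate(rows_v).astype(int),
    )


def _posterior(y, X, Z, vidx, beta_vec, sig2, G) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form Gaussian posterior of b given one subject's records."""
    Q = G.shape[0]
    if y.size == 0:
        return np.zeros(Q), G.copy()
    rinv = 1.0 / sig2[vidx]
    Gi = np.linalg.inv(G + _RIDGE * np.eye(Q))
    A = Gi + (Z * rinv[:, None]).T @ Z
    C = np.linalg.inv(A)
    resid = y - X @ beta_vec
    mu = C @ ((Z * rinv[:, None]).T @ resid)
    return mu, 0.5 * (C + C.T)


def _marginal_loglik(y, X, Z, vidx, beta_vec, sig2, G) -> float:
    if y.size == 0:
        return 0.0
    Q = G.shape[0]
    rinv = 1.0 / sig2[vidx]
    Gi = np.linalg.inv(G + _RIDGE * np.eye(Q))
    A = Gi + (Z * rinv[:, None]).T @ Z
    resid = y - X @ beta_vec
    rr = rinv * resid
    u = Z.T @ rr
    sol = np.linalg.solve(A, u)
    quad = resid @ rr - u @ sol
    sign_g, logdet_g = np.linalg.slogdet(G + _RIDGE * np.eye(Q))
    sign_a, logdet_a = np.linalg.slogdet(A)
    logdet_v = np.sum(np.log(sig2[vidx])) + logdet_g + logdet_a
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet_v + quad)


def _project_structure(S: np.ndarray, specs: List[LongitudinalSpec], structure: str) -> np.ndarray:
    if structure == "unstructured":
        return 0.5 * (S + S.T)
    if structure == "blockdiag":
        out = np.zeros_like(S)
        off = 0
        for s in specs:
            q = s.n_random
            out[off : off + q, off : off + q] = S[off : off + q, off : off + q]
            off += q
        return 0.5 * (out + out.T)
    raise ValueError(f"unknown sigma_b structure {structure!r}")


class _Stats:
    """Per-variable sufficient statistics stacked across subjects.

    Because each variable's observation rows touch only that variable's
    fixed and random columns, the whole ECM iteration runs on (N, p_j, p_j)
    arrays and one batched (N, Q, Q) inverse — no per-subject Python work.
    """

    def __init__(self, cohort: Cohort, specs: List[LongitudinalSpec]):
        N = len(cohort)
        self.N = N
        self.specs = specs
        known = {s.variable for s in specs}
        self.SXX, self.SXZ, self.SXy = [], [], []
        self.SZZ, self.SZy, self.Syy, self.n_obs = [], [], [], []
        for j, spec in enumerate(specs):
            p, q = spec.spline.dimension, spec.n_random
            sxx = np.zeros((N, p, p))
            sxz = np.zeros((N, p, q))
            sxy = np.zeros((N, p))
            szz = np.zeros((N, q, q))
            szy = np.zeros((N, q))
            syy = np.zeros(N)
            cnt = np.zeros(N)
            for i, subj in enumerate(cohort):
                for r in subj.longitudinal:
                    if r.variable not in known:
                        raise KeyError(f"record for unknown variable {r.variable!r}")
                recs = [r for r in subj.longitudinal if r.variable == spec.variable]
                if not recs:
                    continue
                t = np.asarray([r.time for r in recs])
                y = np.asarray([r.value for r in recs])
                X = spec.design(t)
                Z = X[:, list(spec.random_terms)]
                sxx[i] = X.T @ X
                sxz[i] = X.T @ Z
                sxy[i] = X.T @ y
                szz[i] = Z.T @ Z
                szy[i] = Z.T @ y
                syy[i] = float(y @ y)
                cnt[i] = len(t)
            self.SXX.append(sxx)
            self.SXZ.append(sxz)
            self.SXy.append(sxy)
            self.SZZ.append(szz)
            self.SZy.append(szy)
            self.Syy.append(syy)
            self.n_obs.append(cnt)


def fit_mixed(
    cohort: Cohort,
    specs: List[LongitudinalSpec],
    structure: str = "blockdiag",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LongitudinalFit:
    """Maximum-likelihood fit of the multivariate mixed model by ECM.

    Raises on rank-deficient fixed-effect designs (naming the variable); on
    non-convergence the best iterate is returned with ``converged=False`` and
    the full log-likelihood trace for inspection.
    """
    names = [s.variable for s in specs]
    J = len(specs)
    P = sum(s.spline.dimension for s in specs)
    Q = sum(s.n_random for s in specs)
    st = _Stats(cohort, specs)
    N = st.N
    f_off = np.cumsum([0] + [s.spline.dimension for s in specs])
    r_off = np.cumsum([0] + [s.n_random for s in specs])
    r_sl = [slice(r_off[j], r_off[j + 1]) for j in range(J)]

    # rank check per variable over pooled times
    for j, s in enumerate(specs):
        blk = st.SXX[j].sum(axis=0)
        if np.any(np.diag(blk) > 0) and np.linalg.matrix_rank(blk) < s.spline.dimension:
            raise np.linalg.LinAlgError(
                f"rank-deficient design for variable {s.variable!r}: need at least "
                f"{s.spline.dimension} distinct observation times"
            )

    # --- initialization: per-variable OLS, residual variances from OLS fits
    betas = []
    sig2 = np.ones(J)
    for j, s in enumerate(specs):
        A = st.SXX[j].sum(axis=0)
        b = st.SXy[j].sum(axis=0)
        bj = np.linalg.lstsq(A + _RIDGE * np.eye(A.shape[0]), b, rcond=None)[0]
        betas.append(bj)
        n_tot = st.n_obs[j].sum()
        if n_tot:
            rss = st.Syy[j].sum() - 2 * bj @ b + bj @ A @ bj
            sig2[j] = max(rss / n_tot, _SIGMA_FLOOR**2)
    G = np.eye(Q) * max(np.mean(sig2), 1e-4)

    trace = []
    ll_old = -np.inf
    converged = False
    eyeQ = np.eye(Q)
    for it in range(max_iter):
        # ---- E-step (batched over subjects)
        Gi = np.linalg.inv(G + _RIDGE * eyeQ)
        M = np.broadcast_to(Gi, (N, Q, Q)).copy()
        r = np.zeros((N, Q))
        quad0 = np.zeros(N)  # resid' R^-1 resid with current beta
        nlog = 0.0
        for j in range(J):
            bj = betas[j]
            M[:, r_sl[j], r_sl[j]] += st.SZZ[j] / sig2[j]
            r[:, r_sl[j]] = (st.SZy[j] - np.einsum("ipq,p->iq", st.SXZ[j], bj)) / sig2[j]
            quad0 += (
                st.Syy[j]
                - 2 * st.SXy[j] @ bj
                + np.einsum("p,ipq,q->i", bj, st.SXX[j], bj)
            ) / sig2[j]
            nlog += st.n_obs[j].sum() * np.log(sig2[j])
        C = np.linalg.inv(M)
        mu = np.einsum("iqp,ip->iq", C, r)
        # marginal log-likelihood at current parameters
        sign, logdet_M = np.linalg.slogdet(M)
        _, logdet_G = np.linalg.slogdet(G + _RIDGE * eyeQ)
        quad = quad0 - np.einsum("iq,iq->i", r, mu)
        n_total = sum(s_.sum() for s_ in st.n_obs)
        ll = float(
            -0.5 * (n_total * np.log(2 * np.pi) + nlog + N * logdet_G + logdet_M.sum() + quad.sum())
        )
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
        # ---- CM-step: beta per variable (GLS given mu)
        for j in range(J):
            A = st.SXX[j].sum(axis=0)
            rhs = st.SXy[j].sum(axis=0) - np.einsum("ipq,iq->p", st.SXZ[j], mu[:, r_sl[j]])
            betas[j] = np.linalg.solve(A + _RIDGE * np.eye(A.shape[0]), rhs)
        # ---- CM-step: sigma_b
        S = np.einsum("iq,ip->qp", mu, mu) + C.sum(axis=0)
        G = _project_structure(S / N, specs, structure) + _RIDGE * eyeQ
        # ---- CM-step: residual variances
        for j in range(J):
            bj = betas[j]
            muj = mu[:, r_sl[j]]
            Cj = C[:, r_sl[j], r_sl[j]]
            Ebb = np.einsum("iq,ip->iqp", muj, muj) + Cj
            acc = (
                st.Syy[j]
                - 2 * st.SXy[j] @ bj
                + np.einsum("p,ipq,q->i", bj, st.SXX[j], bj)
                - 2 * np.einsum("iq,iq->i", muj, st.SZy[j] - np.einsum("ipq,p->iq", st.SXZ[j], bj))
                + np.einsum("iqp,iqp->i", st.SZZ[j], Ebb)
            )
            n_tot = st.n_obs[j].sum()
            if n_tot:
                sig2[j] = max(float(acc.sum()) / n_tot, _SIGMA_FLOOR**2)

    beta_vec = np.concatenate(betas)

    # GLS covariance of beta at the optimum (block assembly)
    Gi = np.linalg.inv(G + _RIDGE * eyeQ)
    M = np.broadcast_to(Gi, (N, Q, Q)).copy()
    for j in range(J):
        M[:, r_sl[j], r_sl[j]] += st.SZZ[j] / sig2[j]
    C = np.linalg.inv(M)
    info = np.zeros((P, P))
    for j in range(J):
        info[f_off[j] : f_off[j + 1], f_off[j] : f_off[j + 1]] += st.SXX[j].sum(axis=0) / sig2[j]
    for j in range(J):
        for l in range(J):
            Cjl = C[:, r_sl[j], r_sl[l]]
            blk = np.einsum("ipq,iqr,isr->ps", st.SXZ[j], Cjl, st.SXZ[l]) / (sig2[j] * sig2[l])
            info[f_off[j] : f_off[j + 1], f_off[l] : f_off[l + 1]] -= blk
    beta_cov = np.linalg.inv(info + _RIDGE * np.eye(P))

    r_off = np.cumsum([0] + [s.n_random for s in specs])
    return LongitudinalFit(
        specs=list(specs),
        beta={name: beta_vec[f_off[j] : f_off[j + 1]].copy() for j, name in enumerate(names)},
        sigma={name: float(np.sqrt(sig2[j])) for j, name in enumerate(names)},
        sigma_b=G,
        log_likelihood=float(ll_old),
        converged=converged,
        n_iter=len(trace),
        loglik_trace=np.asarray(trace),
        beta_cov=beta_cov,
        structure=structure,
    )


def predict_mean(fit: LongitudinalFit, times, variables: Optional[Sequence[str]] = None) -> Dict[str, np.ndarray]:
    """Per-variable population mean trajectories evaluated at ``times``."""
    variables = fit.variables if variables is None else list(variables)
    return {v: fit.mean_value(v, times) for v in variables}


def posterior_random_effects(
    fit: LongitudinalFit, subject_records: Sequence[LongitudinalRecord]
) -> PosteriorRandomEffects:
    """Exact Gaussian posterior of b given a subject's observed records.

    With zero records this is the prior N(0, Sigma_b).
    """
    y, X, Z, v = _subject_design(list(subject_records), fit.specs)
    beta_vec = np.concatenate([fit.beta[s.variable] for s in fit.specs])
    sig2 = np.asarray([fit.sigma[s.variable] ** 2 for s in fit.specs])
    mu, C = _posterior(y, X, Z, v, beta_vec, sig2, fit.sigma_b)
    return PosteriorRandomEffects(mean=mu, cov=C)
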