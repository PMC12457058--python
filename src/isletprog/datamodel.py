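"""Domain containers: subjects, cohorts, transforms, and cohort validation.

All longitudinal values are stored on the *analysis scale*: OGTT measures and
autoantibody titer z-scores are log(1+x) transformed, HbA1c stays on its raw
NGSP percent scale.  Time is decimal years since confirmed GADA positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .states import DEFAULT_STATE_SPACE, StateSpace

#: The nine longitudinal variables of the model, in canonical order.
LONGITUDINAL_VARIABLES = (
    "fasting_glu",
    "glu_2h",
    "fasting_cp",
    "cp_2h",
    "hba1c",
    "gada_z",
    "ia2a_z",
    "iaa_z",
    "znt8a_z",
)

#: Which variables are log(1+x) transformed before analysis (HbA1c is not).
LOG_TRANSFORMED = frozenset(v for v in LONGITUDINAL_VARIABLES if v != "hba1c")

#: OGTT-derived variables, observable only under the OGTT eligibility rule.
OGTT_VARIABLES = ("fasting_glu", "glu_2h", "fasting_cp", "cp_2h")

#: Autoantibody titer z-score variables, measured at every visit.
TITER_VARIABLES = ("gada_z", "ia2a_z", "iaa_z", "znt8a_z")

DQ_GROUPS = ("DQ2/8", "DQ8/X", "DQ2/X")


class TransformDomainError(ValueError):
    """Raised when log(1+x) is requested for x <= -1."""


def log1p_transform(x: float, variable: str = "") -> float:
    """Map a raw value to the analysis scale, ``log(1 + x)``.

    Raises :class:`TransformDomainError` for ``x <= -1`` (outside the domain),
    naming the offending variable when given.
    """
    x = float(x)
    if x <= -1.0:
        name = f" for variable {variable!r}" if variable else ""
        raise TransformDomainError(f"log(1+x) undefined at x={x}{name}")
    return math.log1p(x)


def inverse_log1p(y: float) -> float:
    """Exact inverse of :func:`log1p_transform`."""
    return math.expm1(float(y))


@dataclass(frozen=True)
class BaselineCovariates:
    """Time-invariant covariates fixed at confirmed GADA positivity.

    ``dq_group`` is one of DQ2/8 (reference), DQ8/X, DQ2/X and encodes to the
    two indicator covariates ``dq8x`` and ``dq2x``.
    """

    sex: str  # "male" | "female"
    age_at_gada: float  # years, > 0
    fdr: int  # first-degree relative with T1D, 0/1
    dq_group: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if not (np.isfinite(self.age_at_gada) and self.age_at_gada > 0):
            raise ValueError(f"age_at_gada must be finite and positive, got {self.age_at_gada}")
        if self.fdr not in (0, 1):
            raise ValueError(f"fdr must be 0/1, got {self.fdr!r}")
        if self.dq_group not in DQ_GROUPS:
            raise ValueError(f"dq_group must be one of {DQ_GROUPS}, got {self.dq_group!r}")

    @property
    def dq8x(self) -> int:
        return int(self.dq_group == "DQ8/X")

    @property
    def dq2x(self) -> int:
        return int(self.dq_group == "DQ2/X")

    def covariate(self, name: str) -> float:
        """Value of a named fixed covariate as used in hazard rosters."""
        if name == "age":
            return self.age_at_gada
        if name == "fdr":
            return float(self.fdr)
        if name == "dq8x":
            return float(self.dq8x)
        if name == "dq2x":
            return float(self.dq2x)
        if name == "female":
            return float(self.sex == "female")
        raise KeyError(f"unknown baseline covariate {name!r}")


@dataclass(frozen=True)
class LongitudinalRecord:
    variable: str
    time: float  # years since confirmed GADA positivity
    value: float  # analysis scale

    def __post_init__(self) -> None:
        if self.variable not in LONGITUDINAL_VARIABLES:
            raise ValueError(f"unknown longitudinal variable {self.variable!r}")


@dataclass(frozen=True)
class StateRecord:
    """One sojourn: the subject occupied ``state`` on [entry_time, exit_time].

    ``next_state`` is None when follow-up was censored in ``state``.
    """

    state: int
    entry_time: float
    exit_time: float
    next_state: Optional[int] = None


@dataclass
class Subject:
    id: str
    baseline: BaselineCovariates
    longitudinal: List[LongitudinalRecord] = field(default_factory=list)
    path: List[StateRecord] = field(default_factory=list)
    #: Simulator-only payload (random effects / latent trajectories); not
    #: serialized by the I/O layer.
    latent: Optional[object] = None

    def records_for(self, variable: str) -> List[LongitudinalRecord]:
        return [r for r in self.longitudinal if r.variable == variable]

    def state_at(self, t: float) -> int:
        """Occupied state at time t (right-continuous in the sojourn records)."""
        for rec in self.path:
            if rec.entry_time <= t < rec.exit_time:
                return rec.state
        last = self.path[-1]
        if t >= last.exit_time:
            return last.next_state if last.next_state is not None else last.state
        return self.path[0].state

    @property
    def visited_states(self) -> List[int]:
        states = [rec.state for rec in self.path]
        if self.path and self.path[-1].next_state is not None:
            states.append(self.path[-1].next_state)
        return states


@dataclass
class Cohort:
    subjects: List[Subject]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)


@dataclass
class ValidationIssue:
    subject_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.subject_id}] {self.message}"


def validate_subject(
    subject: Subject, state_space: StateSpace = DEFAULT_STATE_SPACE, tol: float = 1e-9
) -> List[ValidationIssue]:
    issues: List[ValidationIssue] = []
    sid = subject.id

    for rec in subject.longitudinal:
        if rec.time < -tol:
            issues.append(ValidationIssue(sid, f"longitudinal record at negative time {rec.time}"))
        if not np.isfinite(rec.value):
            issues.append(ValidationIssue(sid, f"non-finite value for {rec.variable} at t={rec.time}"))
    seen = set()
    for rec in subject.longitudinal:
        key = (rec.variable, round(rec.time, 9))
        if key in seen:
            issues.append(ValidationIssue(sid, f"duplicate record for {rec.variable} at t={rec.time}"))
        seen.add(key)

    path = subject.path
    if not path:
        issues.append(ValidationIssue(sid, "empty state path"))
        return issues
    if path[0].state != 1 or abs(path[0].entry_time) > tol:
        issues.append(ValidationIssue(sid, "path must start in state 1 at time 0"))
    for rec in path:
        if rec.exit_time < rec.entry_time - tol:
            issues.append(ValidationIssue(sid, f"sojourn in state {rec.state} has exit before entry"))
    for a, b in zip(path, path[1:]):
        if abs(a.exit_time - b.entry_time) > tol:
            issues.append(ValidationIssue(sid, "sojourns are not contiguous"))
        if a.next_state != b.state:
            issues.append(ValidationIssue(sid, "next_state does not match following sojourn"))
    for a in path:
        if a.next_state is not None and not state_space.is_allowed(a.state, a.next_state):
            issues.append(
                ValidationIssue(sid, f"disallowed transition ({a.state},{a.next_state})")
            )
    if path[-1].next_state is not None and path[-1].next_state not in state_space.absorbing:
        issues.append(ValidationIssue(sid, "path ends with a transition into a non-absorbing state"))
    return issues


def validate_cohort(
    cohort: Cohort, state_space: StateSpace = DEFAULT_STATE_SPACE
) -> List[ValidationIssue]:
    """Collect all invariant violations; an empty list means the cohort is valid."""
    issues: List[ValidationIssue] = []
    for s in cohort:
        issues.extend(validate_subject(s, state_space))
    return issues
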