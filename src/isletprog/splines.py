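"""Spline bases for longitudinal trajectories.

Smooth metabolic trajectories use natural cubic splines (linear beyond the
boundary knots, C2 at interior knots); autoantibody titers use piecewise
linear splines (hinge terms) so abrupt post-seroconversion shifts are not
oversmoothed.  A plain polynomial basis is also available.

Basis dimensions (including the intercept column):

* ``piecewise_linear`` with m interior knots: 2 + m  (1, t, hinges)
* ``natural_cubic`` with m interior knots: 2 + m    (1, t, curvature terms)
* ``polynomial`` of degree d: d + 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class SplineSpec:
    kind: str  # "natural_cubic" | "piecewise_linear" | "polynomial"
    interior_knots: Tuple[float, ...] = ()
    degree: int = 3  # polynomial kind only
    boundary: Tuple[float, float] = (0.0, 15.0)

    def __post_init__(self) -> None:
        if self.kind not in ("natural_cubic", "piecewise_linear", "polynomial"):
            raise ValueError(f"unknown spline kind {self.kind!r}")
        knots = tuple(float(k) for k in self.interior_knots)
        object.__setattr__(self, "interior_knots", knots)
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("interior knots must be strictly increasing")
        lo, hi = self.boundary
        if knots and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary")

    @property
    def dimension(self) -> int:
        if self.kind == "polynomial":
            return self.degree + 1
        return 2 + len(self.interior_knots)


def _natural_cubic(times: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Natural cubic basis on the full knot sequence (boundary + interior).

    Truncated-power construction: columns [1, t, d_1 - d_{K-1}, ...] where
    d_k(t) = ((t-xi_k)+^3 - (t-xi_K)+^3) / (xi_K - xi_k).  Linear outside the
    boundary knots by construction.
    """
    xi = np.asarray(knots, dtype=float)
    K = len(xi)
    t = times

    def d(k: int) -> np.ndarray:
        return (
            np.maximum(t - xi[k], 0.0) ** 3 - np.maximum(t - xi[K - 1], 0.0) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [np.ones_like(t), t]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def build_basis(times: Sequence[float], spec: SplineSpec) -> np.ndarray:
    """Design matrix with one row per time point, columns per basis function.

    Piecewise-linear and natural-cubic bases extrapolate linearly beyond the
    boundary; the polynomial basis is evaluated as-is.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if spec.kind == "polynomial":
        return np.vander(t, spec.degree + 1, increasing=True)
    if spec.kind == "piecewise_linear":
        cols = [np.ones_like(t), t]
        for k in spec.interior_knots:
            cols.append(np.maximum(t - k, 0.0))
        return np.column_stack(cols)
    # natural cubic: boundary knots at the boundary itself
    lo, hi = spec.boundary
    if not spec.interior_knots:
        return np.column_stack([np.ones_like(t), t])
    knots = (lo, *spec.interior_knots, hi)
    return _natural_cubic(t, knots)


@dataclass(frozen=True)
class LongitudinalSpec:
    """Model specification for one longitudinal variable.

    ``random_terms`` indexes the basis columns that carry subject-level random
    effects (default: intercept and slope, columns 0 and 1).
    """

    variable: str
    spline: SplineSpec
    log_transformed: bool = True
    random_terms: Tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if any(j < 0 or j >= self.spline.dimension for j in self.random_terms):
            raise ValueError("random_terms must index fixed basis columns")

    @property
    def n_random(self) -> int:
        return len(self.random_terms)

    def design(self, times: Sequence[float]) -> np.ndarray:
        return build_basis(times, self.spline)

    def random_design(self, times: Sequence[float]) -> np.ndarray:
        X = self.design(times)
        return X[:, list(self.random_terms)]
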