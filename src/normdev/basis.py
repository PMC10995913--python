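"""Age basis: clamped cubic B-splines plus sex and intercept columns.

The age trajectory of each regional measure is modelled with a cubic
B-spline with a small number of interior knots placed at quantiles of the
reference ages.  Clamped (repeated) boundary knots make the basis a
partition of unity on the knot span, which keeps the spline block on the
same scale as the intercept and sex columns.

Ages outside the reference span are clipped to the boundary with a
warning rather than extrapolated: a clamped cubic spline extrapolates
linearly at best and wildly at worst, and a normative model should not
pretend to know trajectories outside the ages it saw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ParameterError


@dataclass(frozen=True)
class BasisSpec:
    """Knot locations and degree of the age spline."""

    lo: float
    hi: float
    interior_knots: tuple[float, ...] = ()
    degree: int = 3

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"basis support must satisfy lo < hi, got ({self.lo}, {self.hi})")
        if any(not (self.lo < k < self.hi) for k in self.interior_knots):
            raise ParameterError("interior knots must lie strictly inside (lo, hi)")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ParameterError("interior knots must be sorted")

    @property
    def knot_vector(self) -> np.ndarray:
        k = self.degree
        return np.r_[[self.lo] * (k + 1), list(self.interior_knots), [self.hi] * (k + 1)]

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    @classmethod
    def from_ages(cls, ages, n_interior: int = 3, degree: int = 3) -> "BasisSpec":
        """Place ``n_interior`` knots at evenly spaced quantiles of ``ages``."""
        ages = np.asarray(ages, dtype=float)
        lo, hi = float(ages.min()), float(ages.max())
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(ages, qs)
        # drop knots that collide with each other or the boundaries
        knots = [float(k) for k in np.unique(knots) if lo < k < hi]
        return cls(lo=lo, hi=hi, interior_knots=tuple(knots), degree=degree)

    def spline_block(self, ages) -> np.ndarray:
        """Evaluate the clamped B-spline basis at ``ages`` (rows sum to 1)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if ages.min() < self.lo or ages.max() > self.hi:
            warnings.warn(
                f"ages outside the basis span [{self.lo}, {self.hi}] were clipped",
                stacklevel=2,
            )
            ages = np.clip(ages, self.lo, self.hi)
        return BSpline.design_matrix(ages, self.knot_vector, self.degree).toarray()


def build_design_matrix(age, sex, spec: BasisSpec) -> np.ndarray:
    """Covariate rows ``[spline(age), sex, 1]`` for a normative regression.

    ``sex`` is coded 0/1.  Out-of-span ages are clipped (with a warning)
    by :meth:`BasisSpec.spline_block`.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    sex = np.atleast_1d(np.asarray(sex, dtype=float))
    if age.shape != sex.shape:
        raise ParameterError("age and sex must have the same length")
    B = spec.spline_block(age)
    return np.column_stack([B, sex, np.ones_like(age)])
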