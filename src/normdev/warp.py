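"""Two-parameter sinh-arcsinh likelihood warp.

The warp maps a (standardized) response ``y`` to

    warp(y) = sinh(delta * asinh(y) - eps)

``eps`` controls skew (positive eps pushes mass to the right tail of the
*unwarped* response) and ``delta`` controls tail weight; ``eps = 0,
delta = 1`` is the identity.  The warp is strictly increasing for every
``delta > 0``, so it is a bijection on the real line and the inverse has
the closed form ``sinh((asinh(t) + eps) / delta)``.

Fitting a Gaussian regression to ``warp(y)`` (plus the log-Jacobian of the
transform) is what lets a Bayesian linear model describe skewed and
heavy/light-tailed response distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class WarpParams:
    """Sinh-arcsinh warp parameters (dimensionless)."""

    eps: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.eps):
            raise ParameterError("warp eps must be finite")
        if not (np.isfinite(self.delta) and self.delta > 0):
            raise ParameterError(f"warp delta must be > 0, got {self.delta}")

    @property
    def is_identity(self) -> bool:
        return self.eps == 0.0 and self.delta == 1.0


def warp(y, p: WarpParams):
    """Forward warp: ``sinh(delta * asinh(y) - eps)``."""
    y = np.asarray(y, dtype=float)
    return np.sinh(p.delta * np.arcsinh(y) - p.eps)


def inverse_warp(t, p: WarpParams):
    """Inverse of :func:`warp`: ``sinh((asinh(t) + eps) / delta)``."""
    t = np.asarray(t, dtype=float)
    return np.sinh((np.arcsinh(t) + p.eps) / p.delta)


def warp_derivative(y, p: WarpParams):
    """d warp / d y = delta * cosh(delta*asinh(y) - eps) / sqrt(1 + y^2).

    Strictly positive everywhere, which is what makes the warp monotone.
    """
    y = np.asarray(y, dtype=float)
    return p.delta * np.cosh(p.delta * np.arcsinh(y) - p.eps) / np.sqrt(1.0 + y * y)


def log_warp_derivative(y, p: WarpParams):
    """Numerically safe ``log(warp_derivative(y, p))``."""
    y = np.asarray(y, dtype=float)
    u = p.delta * np.arcsinh(y) - p.eps
    # log cosh(u) = |u| + log1p(exp(-2|u|)) - log 2, stable for large |u|
    log_cosh = np.abs(u) + np.log1p(np.exp(-2.0 * np.abs(u))) - np.log(2.0)
    return np.log(p.delta) + log_cosh - 0.5 * np.log1p(y * y)
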