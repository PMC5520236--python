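"""L^p-norm utility (desirability) contours for efficacy-toxicity trade-offs.

A dose with posterior efficacy probability ``pi_E`` and toxicity
probability ``pi_T`` has utility

    u(pi_E, pi_T) = 1 - ( ((1-pi_E)/(1-pi1E))^p + (pi_T/pi2T)^p )^(1/p)

where ``pi1E`` is the minimum acceptable efficacy probability when
toxicity is impossible, ``pi2T`` the maximum acceptable toxicity
probability when efficacy is certain, and ``p >= 1`` controls the
curvature of the indifference contours (p = 1 gives straight lines,
larger p bows the contours towards the ideal point (1, 0)).

The neutral (zero-utility) contour passes through (pi1E, 0) and
(1, pi2T); a third, interior, equal-utility point pins down p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "UtilityContour",
    "utility",
    "solve_contour_p",
    "solve_equal_utility_points",
    "ContourSolveError",
]


class ContourSolveError(RuntimeError):
    """Raised when no contour exponent/parameters satisfy the constraints."""


@dataclass(frozen=True)
class UtilityContour:
    """Trade-off contour family parameters.

    Attributes
    ----------
    pi1E : float
        Minimum efficacy probability acceptable at zero toxicity.
    pi2T : float
        Maximum toxicity probability acceptable at certain efficacy.
    p : float
        Contour exponent, >= 1.
    """

    pi1E: float
    pi2T: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1E < 1.0:
            raise ValueError("pi1E must be in (0, 1)")
        if not 0.0 < self.pi2T < 1.0:
            raise ValueError("pi2T must be in (0, 1)")
        if not self.p >= 1.0:
            raise ValueError("contour exponent p must be >= 1")


def utility(pi_E, pi_T, contour: UtilityContour):
    """Utility of (efficacy, toxicity) probability pairs under a contour.

    Accepts scalars or numpy arrays (broadcast); returns the same shape.
    Increasing in ``pi_E``, decreasing in ``pi_T``; u(1, 0) = 1 and the
    contour's defining points have utility 0.
    """
    pi_E = np.asarray(pi_E, dtype=float)
    pi_T = np.asarray(pi_T, dtype=float)
    if np.any(pi_E < 0) or np.any(pi_E > 1) or np.any(pi_T < 0) or np.any(pi_T > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    a = (1.0 - pi_E) / (1.0 - contour.pi1E)
    b = pi_T / contour.pi2T
    u = 1.0 - (a**contour.p + b**contour.p) ** (1.0 / contour.p)
    return u if u.ndim else float(u)


def solve_contour_p(
    point1: tuple[float, float],
    point2: tuple[float, float],
    point3: tuple[float, float],
    rtol: float = 1e-8,
) -> UtilityContour:
    """Solve for the contour exponent given the three defining points.

    ``point1 = (pi1E, 0)`` and ``point2 = (1, pi2T)`` fix the axis
    intercepts of the neutral contour; ``point3`` is a strictly interior
    point of equal (zero) utility. The exponent p solves

        ((1 - e3)/(1 - pi1E))^p + (t3/pi2T)^p = 1

    by bracketed root finding.
    """
    pi1E, t1 = point1
    e2, pi2T = point2
    if t1 != 0.0:
        raise ValueError("point1 must lie on the toxicity-free axis: (pi1E, 0)")
    if e2 != 1.0:
        raise ValueError("point2 must lie at certain efficacy: (1, pi2T)")
    e3, t3 = point3
    if not (0.0 < e3 < 1.0 and 0.0 < t3 < 1.0):
        raise ValueError("point3 must be strictly interior")
    a = (1.0 - e3) / (1.0 - pi1E)
    b = t3 / pi2T
    if a >= 1.0 or b >= 1.0:
        raise ContourSolveError(
            "interior point lies outside the axis points' rectangle; "
            "the root equation a^p + b^p = 1 has no solution"
        )

    def g(p: float) -> float:
        return a**p + b**p - 1.0

    # g is strictly decreasing, g(0+) = 1 > 0, g(inf) = -1 < 0
    lo, hi = 1e-6, 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for valid a, b
            raise ContourSolveError("failed to bracket the contour exponent")
    p = optimize.brentq(g, lo, hi, rtol=rtol)
    return UtilityContour(pi1E=pi1E, pi2T=pi2T, p=float(p))


def solve_equal_utility_points(
    interior_points: Sequence[tuple[float, float]],
    residual_tol: float = 1e-6,
) -> UtilityContour:
    """Recover (pi1E, pi2T, p) from three interior equal-utility points.

    Solves the simultaneous equations u(e_k, t_k) = 0, k = 1..3, for the
    axis intercepts and the exponent via multivariate root finding on an
    unconstrained reparameterisation (logits for the intercepts, log for
    the exponent).
    """
    pts = [(float(e), float(t)) for e, t in interior_points]
    if len(pts) != 3:
        raise ValueError("exactly three interior points are required")
    for e, t in pts:
        if not (0.0 < e < 1.0 and 0.0 < t < 1.0):
            raise ValueError("points must be strictly interior")
    effs = np.array([e for e, _ in pts])
    toxs = np.array([t for _, t in pts])

    def residuals(z: np.ndarray) -> np.ndarray:
        pi1E, pi2T = expit(z[0]), expit(z[1])
        p = np.exp(z[2])
        a = (1.0 - effs) / (1.0 - pi1E)
        b = toxs / pi2T
        return a**p + b**p - 1.0

    # start from intercepts slightly beyond the extreme points, p = 2
    z0 = np.array([logit(min(effs) * 0.8), logit(max(toxs) * 1.2 if max(toxs) < 0.8 else 0.9), np.log(2.0)])
    sol = optimize.root(residuals, z0, method="hybr", tol=1e-12)
    res = residuals(sol.x)
    if not sol.success or np.max(np.abs(res)) > residual_tol:
        raise ContourSolveError(
            f"equal-utility solve did not converge; final residuals {res.tolist()}"
        )
    pi1E, pi2T = float(expit(sol.x[0])), float(expit(sol.x[1]))
    p = float(np.exp(sol.x[2]))
    contour = UtilityContour(pi1E=pi1E, pi2T=pi2T, p=p)
    # self-consistency: the inputs must sit on the recovered zero contour
    check = utility(effs, toxs, contour)
    if np.max(np.abs(check)) > residual_tol:
        raise ContourSolveError(
            f"recovered contour fails self-check; utilities {np.asarray(check).tolist()}"
        )
    return contour
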