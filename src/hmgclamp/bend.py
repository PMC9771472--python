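"""DNA bend-angle inference from circular-permutation gel mobilities.

In a circular-permutation assay the same protein-binding site is placed
at different fractional positions ``x`` along DNA fragments of fixed
length ``L``; the mobility of the complex is minimal when the bend sits
mid-fragment.  This module models the fragment as two rigid arms of
length ``xL`` and ``(1-x)L`` joined at the bend with interior angle
``180° - alpha`` (``alpha`` = bend angle), so the end-to-end distance is

    R(x, alpha)^2 = (xL)^2 + ((1-x)L)^2 + 2 x (1-x) L^2 cos(alpha)

and relative mobility is taken as affine in R/L:  m = c0 + c1 * R/L.
The calibration constants (c0, c1) absorb gel conditions, so inferred
angles are comparable within this model rather than absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PermutationLane",
    "BendFit",
    "flexure_position",
    "end_to_end",
    "fit_bend_angle",
    "min_rigid_length_bp",
]

#: Canonical B-DNA helical rise, nm per base pair.
BDNA_RISE_NM = 0.34


@dataclass(frozen=True)
class PermutationLane:
    """One gel lane: fragment length, bend position and relative mobility."""

    fragment_length: float  # bp
    bend_locus: float       # fractional position x in (0, 1)
    rel_mobility: float     # complex mobility / free-DNA mobility
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bend_locus < 1.0:
            raise ValueError("bend_locus must lie in (0, 1)")
        if not 0.0 < self.rel_mobility < 1.5:
            raise ValueError("rel_mobility must lie in (0, 1.5)")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")


@dataclass(frozen=True)
class BendFit:
    """Fitted bend angle with its affine mobility calibration."""

    angle: float       # degrees
    c0: float
    c1: float
    se_alpha: float
    residuals: np.ndarray
    converged: bool

    def to_dict(self) -> dict:
        return {"angle_deg": self.angle, "c0": self.c0, "c1": self.c1,
                "se_alpha_deg": self.se_alpha,
                "rss": float(np.sum(self.residuals ** 2)),
                "converged": self.converged}


def flexure_position(distance_to_site: float, fragment_length: float) -> float:
    """Fractional bend position x = d/L from a probe distance in bp."""
    if not 0 < distance_to_site < fragment_length:
        raise ValueError("distance must lie strictly inside the fragment")
    return distance_to_site / fragment_length


def end_to_end(x, alpha_deg: float, L: float = 1.0):
    """End-to-end distance of a two-arm bent rod.

    Symmetric in x <-> 1-x; equals L when alpha=0 and L*cos(alpha/2)
    at the central placement x=0.5.
    """
    if not 0.0 <= alpha_deg < 180.0:
        raise ValueError("alpha must lie in [0, 180) degrees")
    x = np.asarray(x, dtype=float)
    c = math.cos(math.radians(alpha_deg))
    r2 = (x * L) ** 2 + ((1 - x) * L) ** 2 + 2 * x * (1 - x) * L * L * c
    out = np.sqrt(np.clip(r2, 0.0, None))
    return out.item() if out.ndim == 0 else out


def fit_bend_angle(lanes: list[PermutationLane],
                   intercept: float | None = None) -> BendFit:
    """Least-squares fit of the bend angle to permutation lanes.

    Requires >= 4 lanes.  With ``intercept=None`` the full calibration
    (alpha, c0, c1) is fit jointly; beware that the angle is then only
    weakly identified, because the affine calibration absorbs nearly all
    of the angle dependence of R(x)/L over typical probe grids — the
    reported ``se_alpha`` is correspondingly large.  When the mobility
    intercept c0 is known from an external calibration, pass it to fit
    only (alpha, c1); the angle is then resolved to a few degrees at
    realistic gel noise.

    A flat mobility profile gives alpha near zero with a wide standard
    error but still converges.
    """
    if len(lanes) < 4:
        raise ValueError("need at least 4 lanes to fit a bend angle")
    x = np.array([ln.bend_locus for ln in lanes])
    m = np.array([ln.rel_mobility for ln in lanes])
    fixed_c0 = intercept

    # profile alpha on a grid: the calibration is linear at fixed alpha,
    # so each grid point is an exact linear solve; then polish jointly
    def design(alpha):
        R = end_to_end(x, alpha, 1.0)
        if fixed_c0 is None:
            return np.column_stack([np.ones_like(x), R]), m
        return R.reshape(-1, 1), m - fixed_c0

    def profile(alpha):
        A, target = design(alpha)
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        r = A @ coef - target
        return float(np.dot(r, r)), coef

    grid = np.linspace(0.0, 179.0, 180)
    costs = np.array([profile(a)[0] for a in grid])
    # tie-break toward the smallest angle: a flat profile fits every
    # alpha equally well and should report no bend
    tol = costs.min() + 1e-12 * max(costs.max(), 1.0)
    a_best = grid[np.flatnonzero(costs <= tol)[0]]
    _, coef = profile(a_best)

    if fixed_c0 is None:
        def resid(p):
            alpha, c0, c1 = p
            return c0 + c1 * end_to_end(x, alpha, 1.0) - m
        x0 = [float(a_best), float(coef[0]), float(coef[1])]
        lb, ub = [0.0, -np.inf, -np.inf], [179.999, np.inf, np.inf]
    else:
        def resid(p):
            alpha, c1 = p
            return fixed_c0 + c1 * end_to_end(x, alpha, 1.0) - m
        x0 = [float(a_best), float(coef[0])]
        lb, ub = [0.0, -np.inf], [179.999, np.inf]

    res = least_squares(resid, x0=x0, bounds=(lb, ub),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(2.0 * res.cost)
    dof = max(len(lanes) - len(x0), 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        se_alpha = float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_alpha = math.inf
    c0 = float(res.x[1]) if fixed_c0 is None else float(fixed_c0)
    c1 = float(res.x[2]) if fixed_c0 is None else float(res.x[1])
    return BendFit(angle=float(res.x[0]), c0=c0, c1=c1, se_alpha=se_alpha,
                   residuals=resid(res.x), converged=bool(res.success))


def min_rigid_length_bp(persistence_length_nm: float,
                        rise_nm_per_bp: float = BDNA_RISE_NM) -> float:
    """Base pairs spanned by a persistence length, at the canonical rise.

    A lower persistence-length bound of 45 nm corresponds to >130 bp of
    effectively rigid B-DNA — far beyond a 15-bp duplex, which is why
    the free-DNA end-to-end width is dominated by probe flexibility.
    """
    if persistence_length_nm <= 0 or rise_nm_per_bp <= 0:
        raise ValueError("lengths must be positive")
    return persistence_length_nm / rise_nm_per_bp
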