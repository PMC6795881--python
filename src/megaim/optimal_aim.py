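"""Expected gain under Gaussian motor noise and the maximising aim point.

For an aim point E and endpoint noise sigma, the expected gain is

    EG(E) = integral G(e) * Normal(e; E, sigma^2) de,

with G the asymmetric gain function.  Because G vanishes outside
[zero_floor, boundary], the integral is evaluated by Gauss-Legendre
quadrature restricted to that interval (further truncated to aim +/- 8 sigma,
where the neglected Gaussian mass is < 1e-15).  The optimal aim point E_opt
maximises EG; under the linear ramp EG is unimodal in E, and the optimiser
(coarse grid scan + bounded scalar refinement) stays agnostic about the ramp
shape so that reconfigured gain functions remain supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats

from .task_model import DEFAULT_GAIN, GainFunction, gain

__all__ = [
    "expected_gain",
    "optimal_aim_gaussian",
    "miss_probability",
    "expected_gain_curve",
    "ExpectedGainCurve",
]

_TRUNC_SIGMAS = 8.0  # Gaussian mass beyond 8 sigma is < 1e-15


@lru_cache(maxsize=8)
def _leggauss(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


def _check_sd(sd_cm: float) -> float:
    sd = float(sd_cm)
    if not (sd > 0 and math.isfinite(sd)):
        raise ValueError(f"sd_cm must be positive and finite, got {sd_cm!r}")
    return sd


def _eg_fixed(aims: np.ndarray, sd: float, gf: GainFunction, order: int) -> np.ndarray:
    """Gauss-Legendre EG for an array of aim points (one interval per aim)."""
    x, w = _leggauss(order)
    lo = np.maximum(gf.zero_floor_cm, aims - _TRUNC_SIGMAS * sd)
    hi = np.minimum(gf.boundary_cm, aims + _TRUNC_SIGMAS * sd)
    half = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    nodes = mid[:, None] + half[:, None] * x[None, :]
    z = (nodes - aims[:, None]) / sd
    pdf = np.exp(-0.5 * z * z) / (sd * math.sqrt(2.0 * math.pi))
    vals = half * ((gain(nodes, gf) * pdf) @ w)
    return np.where(half > 0, vals, 0.0)


def expected_gain(aim_cm: float, sd_cm: float, gf: GainFunction = DEFAULT_GAIN) -> float:
    """Expected gain EG(aim) in points for Gaussian noise of SD ``sd_cm``.

    Fixed-order Gauss-Legendre quadrature with an adaptive fallback: if two
    quadrature orders disagree by more than 1e-9 points, the integral is
    recomputed with :func:`scipy.integrate.quad`.
    """
    sd = _check_sd(sd_cm)
    aim = float(aim_cm)
    if not math.isfinite(aim):
        raise ValueError("aim_cm must be finite")
    aims = np.array([aim])
    v64 = _eg_fixed(aims, sd, gf, 64)[0]
    v128 = _eg_fixed(aims, sd, gf, 128)[0]
    if abs(v128 - v64) <= 1e-9:
        return float(v128)
    lo = max(gf.zero_floor_cm, aim - _TRUNC_SIGMAS * sd)
    hi = min(gf.boundary_cm, aim + _TRUNC_SIGMAS * sd)
    if hi <= lo:
        return 0.0
    val, _ = integrate.quad(
        lambda e: gain(e, gf) * stats.norm.pdf(e, loc=aim, scale=sd),
        lo,
        hi,
        epsabs=1e-12,
        limit=200,
    )
    return float(val)


def miss_probability(aim_cm: float, sd_cm: float, gf: GainFunction = DEFAULT_GAIN) -> float:
    """Probability that an endpoint overshoots the penalty boundary.

    For Gaussian noise this is ``1 - Phi((boundary - aim) / sd)``.
    """
    sd = _check_sd(sd_cm)
    return float(stats.norm.sf((gf.boundary_cm - float(aim_cm)) / sd))


def optimal_aim_gaussian(
    sd_cm: float,
    gf: GainFunction = DEFAULT_GAIN,
    *,
    grid_step_cm: float = 0.01,
    xatol: float = 1e-7,
) -> tuple[float, float]:
    """Aim point maximising expected gain, and the maximum itself.

    A coarse grid scan over [zero_floor, boundary] seeds a bounded scalar
    maximisation, so the result is robust even if the user reconfigures the
    gain function into something less well behaved than the linear ramp.

    Returns
    -------
    (e_opt_cm, eg_max_points)
    """
    sd = _check_sd(sd_cm)
    if grid_step_cm <= 0:
        raise ValueError("grid_step_cm must be positive")
    grid = np.arange(gf.zero_floor_cm, gf.boundary_cm + grid_step_cm / 2, grid_step_cm)
    eg = _eg_fixed(grid, sd, gf, 64)
    k = int(np.argmax(eg))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi <= lo:  # single-point grid
        return float(grid[k]), float(eg[k])
    res = optimize.minimize_scalar(
        lambda a: -_eg_fixed(np.array([a]), sd, gf, 128)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    e_opt = float(res.x)
    return e_opt, float(-res.fun)


@dataclass(frozen=True)
class ExpectedGainCurve:
    """EG(E) sampled on a grid of candidate aim points, with its maximiser."""

    aim_grid_cm: np.ndarray
    eg_points: np.ndarray
    e_opt_cm: float
    eg_max_points: float

    def is_unimodal(self) -> bool:
        """True when the sampled curve rises to a single peak then falls
        (no interior local minimum between two local maxima)."""
        d = np.sign(np.diff(self.eg_points))
        d = d[d != 0]
        # after the first descent there must be no further ascent
        down = np.nonzero(d < 0)[0]
        if down.size == 0:
            return True
        return not np.any(d[down[0]:] > 0)


def expected_gain_curve(
    sd_cm: float,
    gf: GainFunction = DEFAULT_GAIN,
    grid_step_cm: float = 0.1,
) -> ExpectedGainCurve:
    """Expected-gain curve over [zero_floor, boundary] plus refined optimum."""
    sd = _check_sd(sd_cm)
    if not (grid_step_cm > 0 and grid_step_cm < gf.ramp_width_cm):
        raise ValueError("grid_step_cm must be in (0, ramp width)")
    grid = np.arange(gf.zero_floor_cm, gf.boundary_cm + grid_step_cm / 2, grid_step_cm)
    eg = _eg_fixed(grid, sd, gf, 64)
    e_opt, eg_max = optimal_aim_gaussian(sd, gf)
    return ExpectedGainCurve(
        aim_grid_cm=grid, eg_points=eg, e_opt_cm=e_opt, eg_max_points=eg_max
    )
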