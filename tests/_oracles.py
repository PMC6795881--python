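"""Independent oracles used by the test suite.

These deliberately avoid the production code paths: the optimal aim point is
recovered from the first-order condition of the linear-ramp expected gain by
bisection, expected gains are recomputed by brute-force Riemann sums, and
the uniform-stimulus optimum by grid search plus bounded refinement over a
quadrature objective.
"""

import numpy as np
from scipy import optimize, stats

from megaim.full_information import expected_gain_uniform
from megaim.task_model import GainFunction, gain


def foc_root_e_opt(sd: float, gf: GainFunction) -> float:
    """Optimal aim from the first-order condition Phi(z) = (w/sigma) phi(z),
    z = (boundary - E)/sigma, w the ramp width (zero floor ignored)."""
    w = gf.ramp_width_cm

    def f(z):
        return stats.norm.cdf(z) - (w / sd) * stats.norm.pdf(z)

    z = optimize.brentq(f, 1e-9, 8.0, xtol=1e-13)
    return gf.boundary_cm - sd * z


def riemann_eg(aim: float, sd: float, gf: GainFunction, n: int = 10**6) -> float:
    """Brute-force trapezoidal expected gain over [zero_floor, boundary]."""
    e = np.linspace(gf.zero_floor_cm, gf.boundary_cm, n)
    integrand = gain(e, gf) * stats.norm.pdf(e, loc=aim, scale=sd)
    return float(np.trapezoid(integrand, e))


def maximize_uniform_eg(sigma_v: float, gf: GainFunction) -> float:
    """Numerically maximise the uniform-density expected gain over the mean."""
    grid = np.linspace(gf.zero_floor_cm, gf.boundary_cm, 2000)
    vals = [expected_gain_uniform(m, sigma_v, gf) for m in grid]
    k = int(np.argmax(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda m: -expected_gain_uniform(m, sigma_v, gf),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-9},
    )
    return float(res.x)
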