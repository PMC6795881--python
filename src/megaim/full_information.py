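"""Full-information stimuli and their theoretical optimal placements.

In the full-information task the endpoint distribution is shown explicitly —
as a large dot sample from an anisotropic bivariate Gaussian, as a Gaussian
probability-density curve, or as a uniform density — and the participant
places its mean where they believe expected gain is maximal.  The vertical
SD sigma_V of the *narrow* stimulus equals the participant's own endpoint SD
pooled over the last three decision-task blocks (12-14); the *wide* stimulus
doubles it.

Theoretical optima: for Gaussian stimuli the optimum coincides with the
decision task's E_opt(sigma_V) and tolerates a small overshoot probability;
for a uniform density of half-width sqrt(3)*sigma_V the optimum places the
upper edge exactly on the boundary, so the overshoot probability is 0 —
there is no reward/risk trade-off to resolve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .optimal_aim import _eg_fixed, optimal_aim_gaussian
from .task_model import DEFAULT_GAIN, GainFunction, gain

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian_sample", "gaussian_pdf", "uniform_pdf")
WIDTHS = ("narrow", "wide")
SQRT3 = math.sqrt(3.0)

#: Dots drawn per cm of sigma_V; with participant SDs spanning roughly
#: 2-3.5 cm this maps into the 930-1635 dot envelope.
DOTS_PER_CM = 465.0
DOT_RANGE = (930, 1635)

FULLINFO_COLUMNS = [
    "participant_id", "family", "width", "sigma_v_cm", "trial",
    "set_mean_cm", "theoretical_opt_cm", "signed_dev_cm", "abs_dev_cm",
]


@dataclass(frozen=True)
class StimulusSpec:
    """One full-information stimulus.

    ``uniform_bounds`` are the uniform support endpoints relative to the
    stimulus mean, constrained by sigma_V = (b - a) / (2 * sqrt(3));
    ``n_dots`` applies to the dot-sample family only, where the horizontal
    variance is sigma_V^2 / 2.
    """

    family: str
    width: str
    sigma_v_cm: float
    n_dots: Optional[int] = None
    uniform_bounds: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.width not in WIDTHS:
            raise ValueError(f"width must be one of {WIDTHS}, got {self.width!r}")
        if not (self.sigma_v_cm > 0 and math.isfinite(self.sigma_v_cm)):
            raise ValueError("sigma_v_cm must be positive and finite")
        if self.family == "gaussian_sample":
            if self.n_dots is None or self.n_dots < 2:
                raise ValueError("gaussian_sample needs n_dots >= 2")
        if self.family == "uniform_pdf":
            a, b = self.uniform_bounds if self.uniform_bounds is not None else \
                (-SQRT3 * self.sigma_v_cm, SQRT3 * self.sigma_v_cm)
            if abs((b - a) / (2 * SQRT3) - self.sigma_v_cm) > 1e-9:
                raise ValueError(
                    "uniform_bounds inconsistent with sigma_v_cm: "
                    f"(b-a)/(2*sqrt(3)) = {(b - a) / (2 * SQRT3)!r}"
                )
            object.__setattr__(self, "uniform_bounds", (float(a), float(b)))


def default_n_dots(sigma_v_cm: float, *, dots_per_cm: float = DOTS_PER_CM,
                   dot_range: tuple = DOT_RANGE) -> int:
    """Dot count proportional to sigma_V, clipped to the configured envelope."""
    return int(np.clip(round(dots_per_cm * sigma_v_cm), *dot_range))


def make_stimulus(family: str, width: str, narrow_sigma_cm: float) -> StimulusSpec:
    """Convenience constructor applying the narrow/wide doubling rule."""
    sigma = narrow_sigma_cm * (2.0 if width == "wide" else 1.0)
    n_dots = default_n_dots(sigma) if family == "gaussian_sample" else None
    return StimulusSpec(family=family, width=width, sigma_v_cm=sigma, n_dots=n_dots)


def narrow_sigma(trials: pd.DataFrame, *, blocks: tuple = (12, 13, 14)) -> float:
    """Participant's sigma_V for the narrow condition: SD (n-1 denominator)
    of the endpoints pooled over the last three decision-task blocks."""
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("narrow_sigma expects trials of a single participant")
    present = set(trials["block"].unique())
    missing = sorted(set(blocks) - present)
    if missing:
        raise ValueError(f"participant {pids[0]}: missing blocks {missing}")
    sub = trials[trials["block"].isin(blocks) & ~trials["timeout"].astype(bool)]
    endpoints = sub["endpoint_cm"].to_numpy(float)
    if endpoints.size < 2:
        raise ValueError("need >= 2 valid trials in blocks 12-14")
    return float(np.std(endpoints, ddof=1))


def theoretical_optimum(spec: StimulusSpec, gf: GainFunction = DEFAULT_GAIN) -> float:
    """Mean placement maximising expected gain for the stimulus distribution.

    Gaussian families reuse the decision-task optimiser; the uniform family
    has the closed form ``boundary - sqrt(3) * sigma_V`` (upper edge exactly
    on the boundary).
    """
    if spec.family in ("gaussian_sample", "gaussian_pdf"):
        e_opt, _ = optimal_aim_gaussian(spec.sigma_v_cm, gf)
        if e_opt <= gf.zero_floor_cm + 1e-9:
            raise ValueError(
                f"sigma_V = {spec.sigma_v_cm} cm is so large that the optimum "
                f"degenerates onto the zero floor ({gf.zero_floor_cm} cm)"
            )
        return e_opt
    half_width = SQRT3 * spec.sigma_v_cm
    if 2 * half_width >= gf.ramp_width_cm:
        raise ValueError(
            f"uniform support width {2 * half_width:.3f} cm exceeds the ramp "
            f"width {gf.ramp_width_cm} cm; edge-on-boundary placement would "
            "spill below the zero floor"
        )
    return gf.boundary_cm - half_width


def miss_probability_stimulus(spec: StimulusSpec, mean_cm: float,
                              gf: GainFunction = DEFAULT_GAIN) -> float:
    """Probability mass of the stimulus distribution beyond the boundary."""
    from scipy import stats
    if spec.family in ("gaussian_sample", "gaussian_pdf"):
        return float(stats.norm.sf((gf.boundary_cm - mean_cm) / spec.sigma_v_cm))
    half = SQRT3 * spec.sigma_v_cm
    upper = mean_cm + half
    return float(np.clip((upper - gf.boundary_cm) / (2 * half), 0.0, 1.0))


def expected_gain_uniform(mean_cm: float, sigma_v_cm: float,
                          gf: GainFunction = DEFAULT_GAIN, *, order: int = 256) -> float:
    """Expected gain of a uniform endpoint density of SD sigma_V at a given
    mean placement (Gauss-Legendre over the in-range part of the support)."""
    if not sigma_v_cm > 0:
        raise ValueError("sigma_v_cm must be positive")
    half = SQRT3 * sigma_v_cm
    lo = max(mean_cm - half, gf.zero_floor_cm)
    hi = min(mean_cm + half, gf.boundary_cm)
    if hi <= lo:
        return 0.0
    x, w = np.polynomial.legendre.leggauss(order)
    nodes = (hi + lo) / 2 + (hi - lo) / 2 * x
    dens = 1.0 / (2 * half)
    return float((hi - lo) / 2 * np.sum(gain(nodes, gf) * dens * w))


def sample_dots(spec: StimulusSpec, seed) -> np.ndarray:
    """Draw the dot cloud for a gaussian_sample stimulus: ``n_dots`` i.i.d.
    points, mean (0, 0), diagonal covariance (sigma_V^2 / 2, sigma_V^2).

    Returns an (n_dots, 2) array of (x, y) coordinates; reproducible for a
    fixed seed.
    """
    if spec.family != "gaussian_sample":
        raise ValueError(f"sample_dots requires family 'gaussian_sample', "
                         f"got {spec.family!r}")
    rng = np.random.default_rng(seed)
    sx = spec.sigma_v_cm / math.sqrt(2.0)
    x = rng.normal(0.0, sx, size=spec.n_dots)
    y = rng.normal(0.0, spec.sigma_v_cm, size=spec.n_dots)
    return np.column_stack([x, y])


def score_setpoints(trials: pd.DataFrame, gf: GainFunction = DEFAULT_GAIN) -> pd.DataFrame:
    """Fill theoretical_opt_cm / signed_dev_cm / abs_dev_cm for a table of
    set points (columns participant_id, family, width, sigma_v_cm, trial,
    set_mean_cm)."""
    df = trials.copy()
    opts = []
    for _, row in df.iterrows():
        spec = StimulusSpec(
            family=row["family"], width=row["width"], sigma_v_cm=row["sigma_v_cm"],
            n_dots=default_n_dots(row["sigma_v_cm"])
            if row["family"] == "gaussian_sample" else None,
        )
        opts.append(theoretical_optimum(spec, gf))
    df["theoretical_opt_cm"] = opts
    df["signed_dev_cm"] = df["set_mean_cm"] - df["theoretical_opt_cm"]
    df["abs_dev_cm"] = df["signed_dev_cm"].abs()
    return df[FULLINFO_COLUMNS]


def deviations(trials: pd.DataFrame, *, n_warmup: int = 2) -> pd.DataFrame:
    """Per-condition (family x width) mean signed and absolute deviation of
    the set point from the theoretical optimum.

    The first ``n_warmup`` trials of each condition are dropped (by default
    the last 6 of 8 trials enter the analysis).
    """
    required = {"family", "width", "trial", "signed_dev_cm", "abs_dev_cm"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"full-information table missing columns {sorted(missing)}")
    bad = set(trials["family"].unique()) - set(FAMILIES)
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    bad = set(trials["width"].unique()) - set(WIDTHS)
    if bad:
        raise ValueError(f"unknown width label(s): {sorted(bad)}")
    kept = trials[trials["trial"] > n_warmup]
    rows = []
    for (family, width), sub in kept.groupby(["family", "width"], sort=True):
        rows.append({
            "family": family,
            "width": width,
            "n": len(sub),
            "mean_signed_dev_cm": float(sub["signed_dev_cm"].mean()),
            "mean_abs_dev_cm": float(sub["abs_dev_cm"].mean()),
        })
    return pd.DataFrame(rows)
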