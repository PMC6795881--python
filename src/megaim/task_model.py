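"""Task geometry, asymmetric gain function, motor-noise model and trial schema.

The speeded-reaching task rewards movement endpoints that stop close to a
penalty boundary placed 30 cm forward of the start position: points rise
from 0 at a floor distance (7 cm) to the maximum (100) for an endpoint
exactly on the boundary, and drop to 0 for any endpoint beyond it.  All
distances are centimetres measured forward from the start; all other modules
share the :class:`GainFunction`, :class:`MotorModel` and the trial-table
schema defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Column order of the canonical tidy trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "day",
    "block",
    "trial",
    "endpoint_cm",
    "timeout",
    "points",
]

GROUPS = ("display", "no_display")


class SchemaError(ValueError):
    """A trial table violates the documented schema."""


@dataclass(frozen=True)
class GainFunction:
    """Asymmetric payoff mapping an endpoint (cm) to points.

    Under the default ``linear`` shape the score ramps from 0 at
    ``zero_floor_cm`` to ``max_points`` on ``boundary_cm`` and is 0 for any
    endpoint beyond the boundary (a *mistrial*) or at/below the floor.
    """

    boundary_cm: float = 30.0
    zero_floor_cm: float = 7.0
    max_points: float = 100.0
    shape: str = "linear"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.boundary_cm) and math.isfinite(self.zero_floor_cm)):
            raise ValueError("gain-function geometry must be finite")
        if self.zero_floor_cm >= self.boundary_cm:
            raise ValueError(
                f"zero_floor_cm ({self.zero_floor_cm}) must lie below "
                f"boundary_cm ({self.boundary_cm})"
            )
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")
        if self.shape != "linear":
            raise ValueError(f"unsupported gain shape: {self.shape!r}")

    @property
    def ramp_width_cm(self) -> float:
        return self.boundary_cm - self.zero_floor_cm

    def __call__(self, endpoint_cm):
        return gain(endpoint_cm, self)

    @classmethod
    def from_config(cls, config: Mapping) -> "GainFunction":
        """Build from a ``{boundary_cm, zero_floor_cm, max_points, shape}`` mapping."""
        allowed = {"boundary_cm", "zero_floor_cm", "max_points", "shape"}
        unknown = set(config) - allowed
        if unknown:
            raise ValueError(f"unknown gain-function keys: {sorted(unknown)}")
        return cls(**dict(config))


DEFAULT_GAIN = GainFunction()


def gain(endpoint_cm, gf: GainFunction = DEFAULT_GAIN):
    """Points awarded for an endpoint, vectorised over array input.

    The payoff is discontinuous at the boundary: ``gain(boundary) ==
    max_points`` while any endpoint strictly beyond scores 0.
    """
    e = np.asarray(endpoint_cm, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("endpoint_cm must be finite")
    ramp = gf.max_points * (e - gf.zero_floor_cm) / gf.ramp_width_cm
    out = np.where((e > gf.zero_floor_cm) & (e <= gf.boundary_cm), ramp, 0.0)
    if np.isscalar(endpoint_cm) or np.ndim(endpoint_cm) == 0:
        return float(out)
    return out


def display_points(points) -> np.ndarray:
    """Integer points as shown to a participant (banker's rounding)."""
    return np.asarray(np.round(np.asarray(points, dtype=float)), dtype=int)


@dataclass(frozen=True)
class MotorModel:
    """Gaussian motor-noise model: endpoints ~ Normal(aim_cm, sd_cm**2)."""

    aim_cm: float
    sd_cm: float

    def __post_init__(self) -> None:
        if not (self.sd_cm > 0 and math.isfinite(self.sd_cm)):
            raise ValueError("sd_cm must be a positive finite number")
        if not math.isfinite(self.aim_cm):
            raise ValueError("aim_cm must be finite")

    def pdf(self, endpoint_cm):
        return stats.norm.pdf(endpoint_cm, loc=self.aim_cm, scale=self.sd_cm)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.aim_cm, self.sd_cm, size=n)


@dataclass(frozen=True)
class TrialRecord:
    """One reaching trial. ``endpoint_cm``/``points`` are None iff ``timeout``."""

    participant_id: str
    group: str
    day: int
    block: int
    trial: int
    endpoint_cm: Optional[float]
    timeout: bool = False
    points: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timeout != (self.endpoint_cm is None):
            raise SchemaError(
                f"trial {self.participant_id}/b{self.block}/t{self.trial}: "
                "timeout must hold exactly when endpoint_cm is absent"
            )
        if self.timeout and self.points is not None:
            raise SchemaError("timeout trials carry no points")


@dataclass(frozen=True)
class BlockSummary:
    """Per-block estimates feeding the risk-sensitivity analysis.

    ``rs_cm`` is the signed risk-sensitivity E_obs − E_opt: positive values
    mean the participant aimed closer to the penalty boundary than optimal
    (risk-seeking), negative values farther (risk-averse).
    """

    participant_id: str
    group: str
    day: int
    block: int
    n_valid: int
    n_timeout: int
    e_obs_cm: float
    sd_cm: float
    e_opt_cm: float
    eg_max_points: float
    rs_cm: float
    abs_rs_cm: float
    miss_rate: float

    def __post_init__(self) -> None:
        assert abs(self.abs_rs_cm - abs(self.rs_cm)) < 1e-12
        assert 0.0 <= self.miss_rate <= 1.0
        assert self.sd_cm >= 0


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Assemble TrialRecords into the canonical tidy table."""
    rows = [asdict(t) for t in trials]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["endpoint_cm"] = df["endpoint_cm"].astype(float)
    df["points"] = df["points"].astype(float)
    return df


def validate_trials(trials: pd.DataFrame, *, scored: bool = False) -> pd.DataFrame:
    """Validate a trial table against the schema, naming offending rows.

    Parameters
    ----------
    scored
        If True, additionally require that every non-timeout trial carries a
        ``points`` value.
    """
    if not isinstance(trials, pd.DataFrame):
        raise SchemaError("trial table must be a pandas DataFrame")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    df = trials.copy()

    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"row {row}: field 'group' = {df.loc[row, 'group']!r} "
                          f"not in {GROUPS}")
    for col, lo, hi in (("day", 1, 2), ("block", 1, 14), ("trial", 1, 10**9)):
        vals = df[col]
        bad = ~vals.between(lo, hi) | (vals != vals.astype(int))
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"row {row}: field {col!r} = {vals[row]!r} "
                              f"outside integer range [{lo}, {hi}]")
    # day/block consistency: blocks 1-7 are day 1, 8-14 day 2
    implied_day = np.where(df["block"] <= 7, 1, 2)
    bad = df["day"].to_numpy() != implied_day
    if bad.any():
        row = int(df.index[bad.nonzero()[0][0]])
        raise SchemaError(
            f"row {row}: field 'day' = {df.loc[row, 'day']} inconsistent with "
            f"block {df.loc[row, 'block']} (blocks 1-7 are day 1, 8-14 day 2)"
        )

    timeout = df["timeout"].astype(bool)
    has_endpoint = df["endpoint_cm"].notna()
    bad = timeout & has_endpoint
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"row {row}: field 'endpoint_cm' present on a timeout trial")
    bad = ~timeout & ~has_endpoint
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"row {row}: field 'endpoint_cm' absent on a non-timeout trial")
    bad = timeout & df["points"].notna()
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"row {row}: field 'points' present on a timeout trial")
    if scored:
        bad = ~timeout & df["points"].isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"row {row}: field 'points' absent on a scored trial")
    ok_points = df["points"].dropna()
    if (ok_points < 0).any():
        row = int(ok_points.index[ok_points < 0][0])
        raise SchemaError(f"row {row}: field 'points' is negative")
    df["timeout"] = timeout
    return df


def score_trials(trials: pd.DataFrame, gf: GainFunction = DEFAULT_GAIN) -> pd.DataFrame:
    """Populate ``points`` for every non-timeout trial; idempotent.

    Timeout trials are left without points.  Endpoints beyond the boundary
    score 0 (mistrial), matching the gain function's hard cutoff.
    """
    df = validate_trials(trials)
    valid = ~df["timeout"]
    df.loc[valid, "points"] = gain(df.loc[valid, "endpoint_cm"].to_numpy(), gf)
    df.loc[~valid, "points"] = np.nan
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the trial table as CSV (empty endpoint for timeouts, booleans
    lower-case true/false)."""
    df = validate_trials(trials)
    df = df.copy()
    df["timeout"] = np.where(df["timeout"], "true", "false")
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV produced by :func:`write_trials`
    (or any file following the documented schema)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "group": str},
        true_values=["true", "True"],
        false_values=["false", "False"],
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["timeout"] = df["timeout"].astype(bool)
    return validate_trials(df)
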