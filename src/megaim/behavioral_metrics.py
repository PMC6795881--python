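"""Risk-sensitivity estimation from trial tables.

Each block of 50 reaches yields an observed mean endpoint E_obs and endpoint
SD sigma; the optimal aim point E_opt is recomputed from that block's own
sigma, and the signed risk-sensitivity is rs = E_obs - E_opt (positive =
risk-seeking, negative = risk-averse).  Day-level summaries average
block-level rs over blocks 2-7 (day 1) and 9-14 (day 2) — the first block of
each day is treated as (re)calibration and excluded.  The module also fits
the day1 -> day2 persistence regression and the pre/post-display window
comparison.

Estimation conventions: timeout trials are excluded everywhere; overshoot
(mistrial) endpoints are genuine endpoints and are *included* in E_obs and
sigma (excluding them would bias sigma downward) — set
``include_overshoots=False`` to probe sensitivity to that choice; sigma uses
the n-1 denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .optimal_aim import optimal_aim_gaussian
from .task_model import BlockSummary, DEFAULT_GAIN, GainFunction, validate_trials

logger = logging.getLogger(__name__)

DAY1_BLOCKS = tuple(range(2, 8))
DAY2_BLOCKS = tuple(range(9, 15))

SUMMARY_COLUMNS = [
    "participant_id", "group", "day", "block", "n_valid", "n_timeout",
    "e_obs_cm", "sd_cm", "e_opt_cm", "eg_max_points", "rs_cm", "abs_rs_cm",
    "miss_rate",
]


@dataclass(frozen=True)
class ParticipantDaySummary:
    participant_id: str
    group: str
    day: int
    mean_rs_cm: float
    mean_abs_rs_cm: float
    included_blocks: tuple

    def __post_init__(self) -> None:
        assert self.mean_abs_rs_cm >= 0


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of day-2 on day-1 values with a t-based 95% CI on the slope."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci_low: float
    slope_ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        assert self.slope_ci_low <= self.slope <= self.slope_ci_high
        assert -1e-12 <= self.r_squared <= 1 + 1e-12


def _endpoints(block_df: pd.DataFrame, gf: GainFunction, include_overshoots: bool):
    valid = block_df.loc[~block_df["timeout"].astype(bool), "endpoint_cm"].to_numpy(float)
    n_timeout = int(block_df["timeout"].astype(bool).sum())
    if not include_overshoots:
        valid = valid[valid <= gf.boundary_cm]
    return valid, n_timeout


def summarize_block(
    block_df: pd.DataFrame,
    gf: GainFunction = DEFAULT_GAIN,
    *,
    include_overshoots: bool = True,
    min_valid: int = 2,
) -> Optional[BlockSummary]:
    """Summarise one participant-block; None (with a warning) if degenerate.

    A block needs at least ``min_valid`` non-timeout trials and a strictly
    positive endpoint SD for E_opt to be defined.
    """
    key = block_df[["participant_id", "block"]].drop_duplicates()
    if len(key) != 1:
        raise ValueError("summarize_block expects trials of a single participant-block")
    pid = str(key.iloc[0, 0])
    block = int(key.iloc[0, 1])
    endpoints, n_timeout = _endpoints(block_df, gf, include_overshoots)
    if endpoints.size < min_valid:
        logger.warning("block %s/%d: only %d valid trials (< %d); flagged invalid",
                       pid, block, endpoints.size, min_valid)
        return None
    sd = float(np.std(endpoints, ddof=1))
    if not sd > 0:
        logger.warning("block %s/%d: zero endpoint variance; flagged invalid", pid, block)
        return None
    e_obs = float(np.mean(endpoints))
    e_opt, eg_max = optimal_aim_gaussian(sd, gf)
    all_valid = block_df.loc[~block_df["timeout"].astype(bool), "endpoint_cm"].to_numpy(float)
    rs = e_obs - e_opt
    return BlockSummary(
        participant_id=pid,
        group=str(block_df["group"].iloc[0]),
        day=int(block_df["day"].iloc[0]),
        block=block,
        n_valid=int(endpoints.size),
        n_timeout=n_timeout,
        e_obs_cm=e_obs,
        sd_cm=sd,
        e_opt_cm=e_opt,
        eg_max_points=eg_max,
        rs_cm=rs,
        abs_rs_cm=abs(rs),
        miss_rate=float(np.mean(all_valid > gf.boundary_cm)),
    )


def summarize_blocks(
    trials: pd.DataFrame,
    gf: GainFunction = DEFAULT_GAIN,
    *,
    include_overshoots: bool = True,
    min_valid: int = 2,
) -> pd.DataFrame:
    """Block summaries for a whole trial table (one row per valid block)."""
    df = validate_trials(trials)
    rows = []
    for (_, _), sub in df.groupby(["participant_id", "block"], sort=True):
        s = summarize_block(sub, gf, include_overshoots=include_overshoots,
                            min_valid=min_valid)
        if s is not None:
            rows.append(s.__dict__)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def default_blocks(day: int) -> tuple:
    if day == 1:
        return DAY1_BLOCKS
    if day == 2:
        return DAY2_BLOCKS
    raise ValueError(f"day must be 1 or 2, got {day!r}")


def day_summary(
    summaries: pd.DataFrame,
    day: int,
    included_blocks: Optional[Sequence[int]] = None,
) -> ParticipantDaySummary:
    """Average signed and absolute risk-sensitivity over a day's blocks for
    one participant.  Missing blocks are an error naming the gaps."""
    blocks = tuple(included_blocks) if included_blocks is not None else default_blocks(day)
    pids = summaries["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("day_summary expects summaries of a single participant")
    sub = summaries[summaries["block"].isin(blocks)]
    missing = sorted(set(blocks) - set(sub["block"]))
    if missing:
        raise ValueError(
            f"participant {pids[0]}: missing/invalid blocks {missing} for day {day}"
        )
    return ParticipantDaySummary(
        participant_id=str(pids[0]),
        group=str(sub["group"].iloc[0]),
        day=day,
        mean_rs_cm=float(sub["rs_cm"].mean()),
        mean_abs_rs_cm=float(sub["abs_rs_cm"].mean()),
        included_blocks=blocks,
    )


def day_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Both days' summaries for every participant, as a tidy table."""
    rows = []
    for pid, sub in summaries.groupby("participant_id", sort=True):
        for day in (1, 2):
            s = day_summary(sub, day)
            rows.append({
                "participant_id": s.participant_id,
                "group": s.group,
                "day": s.day,
                "mean_rs_cm": s.mean_rs_cm,
                "mean_abs_rs_cm": s.mean_abs_rs_cm,
                "included_blocks": ",".join(map(str, s.included_blocks)),
            })
    return pd.DataFrame(rows)


def persistence_regression(day1: Sequence[float], day2: Sequence[float]) -> RegressionFit:
    """OLS of day-2 values on day-1 values across participants.

    A slope near 1 indicates that individual risk-seeking / risk-averse
    tendencies persist across days.  The 95% CI uses the t distribution with
    n - 2 degrees of freedom; the p-value tests slope = 0 (two-sided).
    """
    x = np.asarray(day1, dtype=float)
    y = np.asarray(day2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("day1 and day2 must be paired 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    if np.var(x) == 0:
        raise ValueError("day-1 values have zero variance; slope undefined")
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_ci_low=float(fit.slope - tcrit * fit.stderr),
        slope_ci_high=float(fit.slope + tcrit * fit.stderr),
        p_value=float(fit.pvalue),
        n=int(n),
    )


def _window_abs_rs(window_df: pd.DataFrame, gf: GainFunction, min_valid: int):
    endpoints = window_df.loc[~window_df["timeout"].astype(bool),
                              "endpoint_cm"].to_numpy(float)
    if endpoints.size < min_valid:
        return None
    sd = float(np.std(endpoints, ddof=1))
    if not sd > 0:
        return None
    e_opt, _ = optimal_aim_gaussian(sd, gf)
    return abs(float(np.mean(endpoints)) - e_opt)


def pre_post_display(
    trials: pd.DataFrame,
    gf: GainFunction = DEFAULT_GAIN,
    *,
    window: int = 10,
    min_valid_per_window: int = 10,
) -> pd.DataFrame:
    """Pre/post window comparison around each day-2 block transition.

    For each transition 8->9 ... 13->14 the absolute risk-sensitivity is
    computed inside the last ``window`` trials of the earlier block (pre)
    and the first ``window`` trials of the later block (post), each using
    the window's own mean, SD and window-specific E_opt.  Windows left with
    fewer than ``min_valid_per_window`` valid trials after timeout removal
    skip the transition (with a warning).

    Returns a frame with columns pre_block, post_block, pre_abs_rs_cm,
    post_abs_rs_cm.
    """
    df = validate_trials(trials)
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("pre_post_display expects trials of a single participant")
    day2 = df[df["day"] == 2].sort_values(["block", "trial"])
    rows = []
    for pre_block in range(8, 14):
        post_block = pre_block + 1
        pre_df = day2[day2["block"] == pre_block].tail(window)
        post_df = day2[day2["block"] == post_block].head(window)
        if pre_df.empty or post_df.empty:
            continue
        pre = _window_abs_rs(pre_df, gf, min_valid_per_window)
        post = _window_abs_rs(post_df, gf, min_valid_per_window)
        if pre is None or post is None:
            logger.warning("participant %s: transition %d->%d skipped "
                           "(insufficient valid trials in a window)",
                           pids[0], pre_block, post_block)
            continue
        rows.append({
            "participant_id": str(pids[0]),
            "pre_block": pre_block,
            "post_block": post_block,
            "pre_abs_rs_cm": pre,
            "post_abs_rs_cm": post,
        })
    return pd.DataFrame(rows, columns=["participant_id", "pre_block", "post_block",
                                       "pre_abs_rs_cm", "post_abs_rs_cm"])


def group_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-block means and SEMs of rs, |rs| and sigma across
    participants (SEM = SD / sqrt(n), n-1 denominator)."""
    if summaries.empty:
        raise ValueError("no block summaries supplied")
    counts = summaries.groupby("group")["participant_id"].nunique()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups need >= 2 participants, got {small.to_dict()}")
    out = []
    for (grp, block), sub in summaries.groupby(["group", "block"], sort=True):
        n = len(sub)
        row = {"group": grp, "block": block, "n": n}
        for col, name in (("rs_cm", "rs"), ("abs_rs_cm", "abs_rs"), ("sd_cm", "sd")):
            vals = sub[col].to_numpy(float)
            row[f"mean_{name}_cm"] = float(np.mean(vals))
            row[f"sem_{name}_cm"] = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
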