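"""Synthetic two-group, two-day reaching cohorts.

The generator reproduces the statistical structure the analysis assumes, so
every pipeline stage is testable without human data:

* endpoints are Gaussian around a participant-specific aim point;
* the endpoint SD decays exponentially over blocks (practice effect),
  ``sigma_k = sd_inf + (sd0 - sd_inf) * exp(-learn_rate * (k - 1))``;
* the aim point tracks the block's own optimum plus a persistent signed
  risk offset — ``aim_k = E_opt(sigma_k) + offset_k`` — with the offset
  multiplied by ``offset_persistence`` on day 2 (individual risk attitudes
  carry over, attenuated);
* the display group's day-2 offset additionally shrinks by a factor
  ``(1 - display_responsiveness)`` per uncertainty display already seen
  (displays precede blocks 9-14); the default responsiveness of 0 encodes
  "the display has no effect";
* each trial independently times out with probability ``timeout_rate``.

Two groups of 11 (display) and 10 (no-display) participants, 7 blocks of 50
trials per day, boundary at 30 cm.  Reproducibility: one master seed; each
participant's stream is an independent child of ``SeedSequence(master)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import full_information
from .optimal_aim import optimal_aim_gaussian
from .task_model import DEFAULT_GAIN, GROUPS, GainFunction, TRIAL_COLUMNS, score_trials

__all__ = [
    "ParticipantProfile",
    "ExperimentDesign",
    "ProfileDistribution",
    "block_sigma",
    "simulate_participant",
    "draw_profiles",
    "simulate_experiment",
    "simulate_fullinfo_setpoints",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic participant."""

    participant_id: str
    group: str
    risk_offset_cm: float
    sd0_cm: float
    sd_inf_cm: float
    learn_rate: float
    offset_persistence: float = 0.7
    display_responsiveness: float = 0.0
    timeout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not (self.sd0_cm >= self.sd_inf_cm > 0):
            raise ValueError("need sd0_cm >= sd_inf_cm > 0")
        if self.learn_rate < 0:
            raise ValueError("learn_rate must be >= 0")
        if not 0 <= self.timeout_rate < 0.2:
            raise ValueError("timeout_rate must be in [0, 0.2)")
        if not 0 <= self.display_responsiveness <= 1:
            raise ValueError("display_responsiveness must be in [0, 1]")
        if not 0 <= self.offset_persistence:
            raise ValueError("offset_persistence must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    n_display: int = 11
    n_no_display: int = 10
    blocks_per_day: int = 7
    trials_per_block: int = 50
    boundary_cm: float = 30.0

    @property
    def n_blocks(self) -> int:
        return 2 * self.blocks_per_day

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class ProfileDistribution:
    """Sampling laws for the profile fields (uniform ranges).

    ``sd_drop`` is subtracted from the drawn sd0 to form sd_inf, keeping
    sd0 >= sd_inf by construction.
    """

    risk_offset_cm: tuple = (-0.8, 0.8)
    sd0_cm: tuple = (1.8, 2.8)
    sd_drop_cm: tuple = (0.3, 0.8)
    learn_rate: tuple = (0.1, 0.4)
    timeout_rate: tuple = (0.0, 0.05)
    offset_persistence: float = 0.7
    display_responsiveness: float = 0.0

    def __post_init__(self) -> None:
        for name in ("risk_offset_cm", "sd0_cm", "sd_drop_cm", "learn_rate",
                     "timeout_rate"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        lo_sd0, _ = self.sd0_cm
        _, hi_drop = self.sd_drop_cm
        if lo_sd0 - hi_drop <= 0:
            raise ValueError("sd0_cm - sd_drop_cm can reach a non-positive sd_inf")


def block_sigma(profile: ParticipantProfile, block: int) -> float:
    """True endpoint SD in a given block (1-based, continuing across days)."""
    return profile.sd_inf_cm + (profile.sd0_cm - profile.sd_inf_cm) * math.exp(
        -profile.learn_rate * (block - 1)
    )


def _block_offset(profile: ParticipantProfile, block: int) -> float:
    if block <= 7:
        return profile.risk_offset_cm
    offset = profile.risk_offset_cm * profile.offset_persistence
    if profile.group == "display" and block >= 9:
        # uncertainty displays precede day-2 blocks 9..14
        offset *= (1.0 - profile.display_responsiveness) ** (block - 8)
    return offset


def simulate_participant(
    profile: ParticipantProfile,
    design: ExperimentDesign = ExperimentDesign(),
    gf: GainFunction = DEFAULT_GAIN,
    seed=None,
) -> pd.DataFrame:
    """Simulate one participant's full trial table (scored)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for block in range(1, design.n_blocks + 1):
        sigma = block_sigma(profile, block)
        e_opt, _ = optimal_aim_gaussian(sigma, gf)
        aim = e_opt + _block_offset(profile, block)
        n = design.trials_per_block
        endpoints = rng.normal(aim, sigma, size=n)
        timeouts = rng.random(n) < profile.timeout_rate
        frames.append(pd.DataFrame({
            "participant_id": profile.participant_id,
            "group": profile.group,
            "day": 1 if block <= design.blocks_per_day else 2,
            "block": block,
            "trial": np.arange(1, n + 1),
            "endpoint_cm": np.where(timeouts, np.nan, endpoints),
            "timeout": timeouts,
            "points": np.nan,
        }))
    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return score_trials(trials, gf)


def draw_profiles(
    design: ExperimentDesign,
    dist: ProfileDistribution,
    rng: np.random.Generator,
) -> list:
    """Draw one cohort of participant profiles (display group first)."""
    profiles = []
    groups = ["display"] * design.n_display + ["no_display"] * design.n_no_display
    for i, group in enumerate(groups, start=1):
        sd0 = rng.uniform(*dist.sd0_cm)
        profiles.append(ParticipantProfile(
            participant_id=f"P{i:02d}",
            group=group,
            risk_offset_cm=rng.uniform(*dist.risk_offset_cm),
            sd0_cm=sd0,
            sd_inf_cm=sd0 - rng.uniform(*dist.sd_drop_cm),
            learn_rate=rng.uniform(*dist.learn_rate),
            timeout_rate=rng.uniform(*dist.timeout_rate),
            offset_persistence=dist.offset_persistence,
            display_responsiveness=dist.display_responsiveness,
        ))
    return profiles


def profiles_to_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in profiles])


def simulate_experiment(
    design: ExperimentDesign = ExperimentDesign(),
    dist: ProfileDistribution = ProfileDistribution(),
    master_seed: int = 0,
    gf: GainFunction = DEFAULT_GAIN,
) -> tuple:
    """Simulate the full cohort.

    Returns ``(trials, profiles)``: the scored trial table and the table of
    true generative parameters (for parameter-recovery checks).  Each
    participant consumes an independent child stream of
    ``SeedSequence(master_seed)``, so the output is reproducible and
    insensitive to participant order.
    """
    root = np.random.SeedSequence(master_seed)
    profile_ss, *child_ss = root.spawn(1 + design.n_display + design.n_no_display)
    profiles = draw_profiles(design, dist, np.random.default_rng(profile_ss))
    frames = [
        simulate_participant(p, design, gf, seed=np.random.default_rng(ss))
        for p, ss in zip(profiles, child_ss)
    ]
    trials = pd.concat(frames, ignore_index=True)
    return trials, profiles_to_frame(profiles)


_POLICIES = ("optimal", "constant_offset", "family_dependent")


def simulate_fullinfo_setpoints(
    sigma_narrow: Mapping[str, float],
    policy: str = "optimal",
    *,
    delta_cm: float = 0.0,
    delta_gauss_cm: float = 0.0,
    delta_unif_cm: float = 0.0,
    setting_noise_cm: float = 0.0,
    n_trials: int = 8,
    gf: GainFunction = DEFAULT_GAIN,
    seed=None,
) -> pd.DataFrame:
    """Simulate full-information set points for each participant/condition.

    ``sigma_narrow`` maps participant_id -> narrow-condition sigma_V.
    Policies: ``optimal`` sets the theoretical optimum, ``constant_offset``
    adds ``delta_cm`` everywhere, ``family_dependent`` adds
    ``delta_gauss_cm`` to Gaussian conditions and ``delta_unif_cm`` to the
    uniform condition.  Gaussian ``setting_noise_cm`` is added on top.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {_POLICIES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for pid in sorted(sigma_narrow):
        for family in full_information.FAMILIES:
            for width in full_information.WIDTHS:
                spec = full_information.make_stimulus(family, width, sigma_narrow[pid])
                opt = full_information.theoretical_optimum(spec, gf)
                if policy == "optimal":
                    offset = 0.0
                elif policy == "constant_offset":
                    offset = delta_cm
                else:
                    offset = delta_unif_cm if family == "uniform_pdf" else delta_gauss_cm
                noise = rng.normal(0.0, setting_noise_cm, size=n_trials) \
                    if setting_noise_cm > 0 else np.zeros(n_trials)
                for t in range(1, n_trials + 1):
                    rows.append({
                        "participant_id": pid,
                        "family": family,
                        "width": width,
                        "sigma_v_cm": spec.sigma_v_cm,
                        "trial": t,
                        "set_mean_cm": opt + offset + noise[t - 1],
                    })
    df = pd.DataFrame(rows)
    return full_information.score_setpoints(df, gf)
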