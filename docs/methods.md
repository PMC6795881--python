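# Methods

## Model

A reach endpoint is the maximum forward excursion of a speeded
out-and-back movement, in cm from the start. The gain function G is
asymmetric: with boundary b = 30 cm, floor f = 7 cm and maximum M = 100
points,

    G(e) = M · (e − f) / (b − f)   for f < e ≤ b,   0 otherwise.

The ramp is taken as linear; the task's published description fixes the
anchor points (0 at 7 cm, 100 on the line, 0 above) but not the exact
curve. The linear form is the simplest consistent choice and it
reproduces the known 3.9% optimal mistrial rate at σ = 2 cm, which
functions as an end-to-end check of the assumption. Points are kept
continuous internally; integer rounding (half-even, `display_points`) is
display-only. An endpoint exactly on the boundary scores M — a
measure-zero event under the continuous model, so the "to graphical
precision" tolerance of the real apparatus is irrelevant to expectations.

Motor noise is Gaussian with aim-independent variance: e ~ N(E, σ²).
Expected gain EG(E) = ∫ G·N de is computed by Gauss–Legendre quadrature
restricted to [f, b] ∩ [E − 8σ, E + 8σ] (G vanishes below f and above b;
Gaussian mass beyond 8σ is < 1e−15). Fixed orders 64 (vectorised grid
scans) and 128 (scalar refinement) are used; if orders 64 and 128 disagree
by more than 1e−9 points the routine falls back to adaptive quadrature.
E_opt maximises EG via a 0.01-cm grid scan that brackets the optimum for a
bounded scalar search (xatol 1e−7). The grid seeding keeps the optimiser
safe if a user reconfigures G into something non-unimodal. The first-order
condition of the linear ramp, Φ(z) = ((b − f)/σ)·φ(z) with
z = (b − E_opt)/σ, is implemented **only** as an independent test oracle
(bisection root), never as the production path, so non-linear gain shapes
remain supported. For σ ≤ 3 the floor lies > 7σ below the optimum and is
numerically irrelevant (tested to < 1e−6 cm); at σ = 4 it shifts E_opt by
≈ 1.6e−5 cm, still well inside the 1e−4 cm oracle-agreement tolerance.
Miss probability at an aim point is 1 − Φ((b − E)/σ).

## Estimation conventions

* Per block: E_obs = mean endpoint, σ̂ = SD with n−1 denominator, E_opt
  recomputed from that block's own σ̂; rs = E_obs − E_opt.
* Timeout trials are excluded everywhere (no endpoint is recorded for
  them). Overshoot endpoints are *included* in E_obs and σ̂ — they are
  genuine endpoints and dropping them would bias σ̂ downward; the choice
  is exposed as `include_overshoots` for sensitivity analysis.
* Blocks need ≥ 2 valid trials and σ̂ > 0; otherwise they are flagged
  invalid with a logged warning and excluded downstream.
* Day summaries average block-level rs over blocks 2–7 (day 1) and 9–14
  (day 2); the first block of each day is excluded as (re)calibration.
* Persistence: OLS of day-2 mean rs on day-1 mean rs across participants,
  95% CI from the t distribution with n−2 df, two-sided p for slope = 0.
* Pre/post display windows: last 10 trials of blocks 8–13 vs first 10 of
  blocks 9–14, each window using its own mean, SD and window-specific
  E_opt (10 observations is the information actually available in the
  window). A window with fewer than 10 valid trials after timeout removal
  (configurable `min_valid_per_window`) skips its transition with a
  warning.
* Group table: per group × block mean and SEM (SD/√n across participants)
  of rs, |rs| and σ̂.

## Full-information stimuli

σ_V in the narrow condition is the SD of a participant's endpoints pooled
over decision-task blocks 12–14; the wide condition doubles it. The dot
sample is bivariate Gaussian with diagonal covariance (σ_V²/2, σ_V²); the
dot count is round(465 · σ_V), clipped to [930, 1635] — the proportionality
constant is chosen so that plausible participant SDs of roughly 2–3.5 cm
span that envelope, since only proportionality and the envelope are given.
Theoretical optima: Gaussian families reuse E_opt(σ_V); the uniform
density of half-width √3·σ_V has the closed form b − √3·σ_V (upper edge
exactly on the boundary, penalty mass 0), with a grid + bounded-refinement
numerical maximiser as the test oracle, mirroring the Gaussian module's
structure. A uniform stimulus whose support is wider than the ramp
(2√3·σ_V ≥ 23 cm) is rejected: its edge-on-boundary placement would spill
below the zero floor and the closed form no longer holds. Deviation
analysis drops the first 2 of 8 trials per condition (warm-up) and reports
per-condition mean signed and absolute deviation.

## Evidence

The Bayes factor uses a normal (z-based) likelihood for the observed mean
difference, N(D; θ, se²) — not a t likelihood — matching the standard
usage of uniform-prior calculators for this design; the marginal
likelihood under H1 is the closed-form CDF difference averaged over the
uniform prior, evaluated via survival functions when the whole prior sits
in the upper tail (avoids catastrophic cancellation), and cross-checked
against adaptive quadrature at 1e−10 relative tolerance on every call.
Evidence categories use strict inequalities: BF > 3 substantial for H1,
BF < 1/3 substantial for H0, boundary values inconclusive. The effect
prior for the display comparison spans (0, reference), where the reference
is the control group's day-2 mean |rs| — from "no effect" to "feedback
restores optimality". The pipeline orients the difference as
no_display − display, so a positive value means the display helped.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated: two groups (11 display, 10 no-display), 2 days × 7 blocks × 50
trials, boundary 30 cm. Per participant:

* σ_k = sd_inf + (sd0 − sd_inf)·exp(−learn_rate·(k−1)) across blocks
  k = 1..14 — an exponential practice curve; the real effect is only known
  to be a monotone decline, so the functional form is a modelling choice
  exposed in config.
* aim_k = E_opt(σ_k) + offset_k, the simplest process consistent with
  persistent individual risk attitudes; offset_k equals the participant's
  risk offset on day 1 and offset × offset_persistence (default 0.7) on
  day 2, a value that makes the day-1 → day-2 regression land in the
  observed 0.6–0.8 slope range.
* Display group only: after each uncertainty display (displays precede
  day-2 blocks 9–14) the offset shrinks by a further factor
  (1 − display_responsiveness). The default responsiveness of 0 encodes
  the empirical null — displays do not change planning — and is raised
  above 0 only to power-test the group comparison.
* Each trial independently times out with probability timeout_rate.

Cohort defaults: risk_offset ~ U(−0.8, 0.8) cm, sd0 ~ U(1.8, 2.8) cm,
sd_inf = sd0 − U(0.3, 0.8) cm, learn_rate ~ U(0.1, 0.4), timeout_rate ~
U(0, 0.05). Under these, the no-display group's day-2 mean |rs| falls in
the 0.2–0.5 cm band that brackets published group-level values.
Reproducibility: one master seed; participant streams are independent
children of `numpy.random.SeedSequence(master)` (spawned), so output is
identical across runs and platforms for the same numpy PRNG family.

What the generator does **not** emulate: trajectory kinematics and
reaction times, within-block drift or serial dependence of endpoints,
non-Gaussian endpoint tails, aim-dependent variance, strategic
exploration, and the training task (it only motivates sd0). Passing
recovery tests therefore show the estimators are correct under the model's
own assumptions, not that human data satisfy those assumptions.

## Validation design and problem sizes

* Deterministic anchors: the 3.9% optimal mistrial rate at σ = 2, the
  0.30 worked-example Bayes factor, and the uniform stimulus's 0% penalty
  at its optimum.
* Oracle equivalence: production optimiser vs first-order-condition root
  (≤ 1e−4 cm for σ ∈ {0.5, 1, 2, 4}); uniform closed form vs numerical
  maximiser (≤ 1e−6 cm).
* Parameter recovery uses 50 default cohorts: the regression of estimated
  day-1 mean rs on the true generative offset (error in the response only,
  hence unbiased) must have slope in [0.9, 1.1]; the persistence
  regression's 95% CI must cover offset_persistence in ≥ 80% of cohorts.
  The coverage bound is below the nominal 95% on purpose: day-1 estimates
  enter as the regressor, and their estimation noise (errors-in-variables)
  attenuates the slope by roughly 10–15% under the default generator, which
  predicts ~90% coverage analytically.
* Null fidelity of the pre/post comparison uses 200 simulated stationary
  participants; the paired mean pre/post difference must lie within 3 SE
  of zero.

These sizes (50 cohorts, 200 participants) give the assertions ~3σ
headroom while keeping the full suite in the minutes range; they are the
package's standing validation conditions, not tunable knobs.

## Known limitations

* Only the linear ramp shape ships; the architecture keeps the optimiser
  shape-agnostic but `GainFunction` currently rejects other shapes rather
  than guessing.
* The Bayes factor offers no t-likelihood small-sample correction and no
  half-normal or point priors (flagged as a future option).
* Whether published analyses of this paradigm included overshoot
  endpoints in σ̂, and whether pre/post windows used window-local or
  block-level σ, is not documented; both choices here are explicit and
  configurable.
* `load_trials` accepts only the package's own CSV schema, not any
  externally deposited layout.
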