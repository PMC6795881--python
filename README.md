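# megaim

Bayesian decision-theoretic analysis of speeded reaching under risk:
optimal aim-point computation under an asymmetric gain function, trial-level
risk-sensitivity estimation, full-information stimulus optima, and
uniform-prior Bayes-factor evidence assessment — with a synthetic
participant simulator so the whole chain runs, and is tested, without human
data.

## The problem

In a speeded out-and-back reaching task, a participant aims at a penalty
boundary placed 30 cm forward of the start. The gain function is
asymmetric: the score rises linearly from 0 points at 7 cm to 100 points
for an endpoint exactly on the boundary, and collapses to 0 for any
endpoint beyond it (a *mistrial*). Motor noise makes the endpoint *e* a
random variable around the chosen aim point *E*, modelled as Gaussian,
*e* ~ N(*E*, σ²). The expected gain of an aim point is

```
EG(E) = ∫ G(e) · N(e; E, σ²) de
```

and the risk-neutral optimal strategy is the maximiser
*E*\_opt = argmax EG(*E*). Because the payoff is asymmetric, *E*\_opt sits
below the boundary and deliberately accepts a small overshoot probability
(3.9% when σ = 2 cm). A participant's **risk-sensitivity** in a block is

```
rs = E_obs − E_opt(σ̂)
```

where *E*\_obs and σ̂ are the mean and SD of that block's endpoints:
rs > 0 is risk-seeking (aiming too close to the boundary), rs < 0
risk-averse. The package estimates rs per block, averages it per day,
fits the day-1 → day-2 persistence regression, compares pre/post windows
around the uncertainty-display transitions, scores full-information
stimulus placements (dot samples, Gaussian PDFs, uniform PDFs) against
their theoretical optima — for a uniform density the optimum simply rests
the distribution's upper edge on the boundary, with 0% penalty — and
weighs group effects with a uniform-prior Bayes factor

```
BF = P(D | H1) / P(D | H0),   D ~ N(θ, se²),  θ ~ U(prior_low, prior_high) under H1.
```

Intended users: researchers in sensorimotor decision-making who want a
tested reference implementation of these computations, either to analyse
their own trial tables (CSV schema documented in
`megaim.task_model.TRIAL_COLUMNS`) or to run simulation studies.

## Worked example

Optimal aim point for σ = 2 cm:

```bash
$ megaim optimal --sd 2
{
  "e_opt_cm": 26.464227426711453,
  "eg_max_points": 80.63855004409014,
  "miss_probability": 0.038539957902653056
}
```

The optimum aims 3.5 cm short of the boundary, collects 80.6 expected
points per trial, and tolerates a 3.9% mistrial rate — aiming at the
boundary itself would miss half the time.

Bayes factor for an observed group difference of −0.09 cm (SE 0.12) under
an effect prior uniform on [0, 0.30] cm:

```bash
$ megaim bf --mean -0.09 --se 0.12 --prior-low 0 --prior-high 0.30
{
  "bf": 0.3002620108924522,
  "category": "substantial_H0"
}
```

BF < 1/3: the data are three times likelier under "no effect".

A full synthetic-cohort run (21 participants, 2 groups × 14 blocks × 50
trials):

```bash
$ megaim run --seed 1 --out demo_run
megaim run (seed=1)

Persistence of risk-sensitivity (day-2 mean rs ~ day-1 mean rs):
  display     slope=+0.643 95% CI [+0.469, +0.818] R^2=0.885 n=11
  no_display  slope=+0.685 95% CI [+0.343, +1.027] R^2=0.727 n=10

Day-2 mean absolute risk-sensitivity (blocks 9-14):
  no_display 0.388 cm, display 0.423 cm
  difference (no_display - display) -0.035 cm (SE 0.064)
  Bayes factor (uniform prior [0.00, 0.39] cm): 0.140 -> substantial_H0
```

The persistence slopes near 0.7 recover the generator's offset-persistence
parameter (attenuated slightly by day-1 estimation noise), and with the
default display-responsiveness of 0 the Bayes factor correctly lands on the
null. Artifacts (trials.csv, block_summaries.csv, day_summaries.csv,
group_table.csv, regression.json, report.json) are written to `demo_run/`.
Python users can do the same via `megaim.run({"seed": 1}, "demo_run")`;
`megaim analyze --trials your.csv --out dir` runs the estimation chain on
any conforming trial table.

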