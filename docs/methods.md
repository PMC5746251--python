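# Methods

## The observer model

The task is yes/no visual search: a display of `N = 25` oriented line
elements either contains one target among `N - 1` distractors (probability
0.5) or contains distractors only. The near-cardinal orientation is 80° and
the oblique orientation 50° (counterclockwise from vertical), a 30°
separation; one group of observers trains with the near-cardinal target
among oblique distractors, the other with the roles reversed.

The observer receives one noisy orientation measurement per location,

    x_i ~ Normal(s_i, sigma_i^2),

where `s_i` and `sigma_i` are the orientation and the encoding uncertainty
of the element at location *i*. Uncertainty depends on the element's
identity: `sigma_T` for targets, `sigma_D` for distractors. The optimal
decision rule evaluates the local log-likelihood ratio at each location,

    d_i = 1/2 log(sigma_D^2 / sigma_T^2)
          - 1/2 [ (x_i - s_T)^2 / sigma_T^2 - (x_i - s_D)^2 / sigma_D^2 ],

pools over the uniform prior on target position,

    d = log( (1/N) * sum_i exp(d_i) ),

and reports "present" when `d` exceeds 0, the optimal criterion at equal
prevalence. Ties (`d` exactly at threshold) respond "absent"; the event has
measure zero and the convention only fixes determinism. Orientations are
treated on a linear degree scale: the measurement model is a linear
Gaussian and a 30° separation is far from circular wrap-around.

Model d′ has no closed form. It is measured by simulating an experiment —
4,000 trials at 50% prevalence by default — and applying the standard
signal-detection formulae, `d' = z(H) - z(F)` and `c = -(z(H) + z(F))/2`,
to the simulated counts. Extreme rates are handled by the log-linear rule
(add 0.5 to each response cell and 1 to each trial count) so that a
simulated hit rate of exactly 0 or 1 stays finite; the raw-rate variant is
selectable.

## Learning and the four variants

Perceptual learning is modelled as an exponential decay of uncertainty over
training sessions:

    sigma(t) = sigma_0 * (1 + exp(-tau * t)),

with `sigma_0` the asymptote and `tau` the per-session rate. We take
`t = session_index - 1`, so day 1 evaluates to `2 * sigma_0` and training
drives uncertainty toward `sigma_0`. (The functional form fixes
`sigma(0) = 2 sigma_0`; describing `sigma_0` as a "pre-training"
uncertainty would contradict that, so we consistently treat it as the
asymptote.)

Each orientation (near-cardinal, oblique) carries its own curve. Rates
attach to the *role* an orientation holds during training: in the
near-cardinal group the cardinal orientation learns at the target rate and
the oblique orientation at the distractor rate, and conversely in the
oblique group. The four variants differ in what is free:

| variant | initial uncertainties | learning rates | k |
|---------|----------------------|----------------|---|
| R       | sigma_cardinal, sigma_oblique | one shared tau | 3 |
| L       | one shared sigma     | tau_target, tau_distractor | 3 |
| RL      | sigma_cardinal, sigma_oblique | tau_target, tau_distractor | 4 |
| RLG     | sigma_cardinal, sigma_oblique | tau_target, tau_distractor per group | 6 |

In the orientation-transfer test the two orientations swap task roles while
each keeps the uncertainty it acquired during training, frozen at the
end-of-training state (`t = 5`); the test is treated as a read-out, not a
seventh training step. This matches using the model both for joint
seven-session fits and for predicting the test from training-only fits: if
the test itself trained the swapped roles, the "prediction" would not be a
pure extrapolation.

## Fitting

Each variant is fit to the group-mean d′ trajectories — two groups × the
selected sessions (14 points for the joint fit, 12 for training-only) — by
least squares. Because model d′ is itself a simulation, the objective is
stabilised with common random numbers: one base seed freezes the
standard-normal measurement draws, present/absent assignment and target
placements for every (group, session) condition, making the objective a
deterministic function of the parameter vector. Candidates differ only in
how the frozen draws are scaled and shifted.

Optimisation is Nelder–Mead on log-transformed parameters (enforcing
positivity), tolerance 1e-4 on parameters and objective, run twice per
start: the second pass re-inflates the simplex at the first pass's
solution. The restart matters — on this step-noisy objective a single pass
regularly stalls with SSE two to three times the attainable floor. Starts
are sampled uniformly, `sigma` on [1, 20] and `tau` on [0, 2] (20 by
default), and a soft quadratic penalty confines the search to the same
box: above `sigma = 20` the first-session hit rate is zero and the
objective flat, and a rate above 2 per session (more than 86% of the decay
inside one session) is empirically indistinguishable from instantaneous
learning, so solutions out there are degenerate ridges. Ties between starts
break toward the earliest index; every start and its final SSE is recorded
in the result, together with the base seed, so fits are reproducible
bit-for-bit.

For analyses that hinge on *which* parameter carries the learning — in
particular attributing improvement to the target versus the distractor rate
from training days alone — a second, coarse-to-fine stage is used
(`refine_fit`): the top final vectors of the broad multi-start are
re-polished under a fresh 20,000-trial frozen experiment. The two
attributions can differ by less SSE than the simulation noise of a
4,000-trial evaluation, so basin search (many cheap starts) and basin
resolution (few precise polishes) are deliberately separated. On every
cohort we examined, the correct attribution had the lower SSE once
evaluated at high fidelity.

## Model comparison and evaluation

AICc uses the Gaussian-error identification for least squares,

    AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n-k-1),

with `k` counting only the variant's named parameters (3/3/4/6). The error
variance is a shared constant across variants fit to the same data and is
omitted; only AICc differences are meaningful, and they are invariant to
that constant. `n = 14` keeps `n > k + 1` for all variants.

Generalisation is measured by leave-one-observer-out cross-validation: each
round drops one observer, refits to the remaining observers' group means,
and takes the fitted model's per-session d′ for the held-out observer's
group as the prediction; `r^2` is the squared Pearson correlation between
predicted and observed trajectories, summarised by its mean (and SD) over
observers. The attainable ceiling is estimated from the data alone: the
upper bound is the mean `r^2` between each observer's trajectory and their
own group's mean; the lower bound excludes the observer from that mean.
Observers with constant trajectories have undefined correlations and are
excluded with a warning.

## The synthetic cohort

No observer-level behavioral data are distributed with the study this
package emulates, so the pipeline runs on synthetic cohorts with the
study's design: two groups of 5 observers, six training sessions plus the
orientation test, 540 trials per session at 50% prevalence.

The generating truth is the RL variant with `tau_target = 0.24`,
`tau_distractor = 0.65` (the reported best-fitting learning rates) and
asymptotes `sigma_cardinal = 6`, `sigma_oblique = 7.5` degrees. The ~1.25
sigma ratio is not arbitrary: full transfer in the near-cardinal group
requires the two orientations' end-of-training uncertainties to nearly
equalise, which with the above rates pins
`sigma_oblique / sigma_cardinal ≈ (1 + e^-1.2) / (1 + e^-3.25) ≈ 1.25`;
the absolute level puts SOA-averaged d′ in the ~0.8–3 range typical of
this task. Under this truth the cohort shows the three signatures the
model explains: higher day-1 sensitivity for the oblique-target group
(search asymmetry), monotone learning in both groups, and — at test —
near-day-6 performance for the near-cardinal group against a clear drop
for the oblique group.

Observers differ by independent multiplicative lognormal jitter on each
parameter (unit median), the simplest positive-support heterogeneity
model. The jitter coefficient of variation is a design knob with no
empirical anchor, and it was calibrated against two requirements that pull
in opposite directions: generated cohorts must reliably express the
generating model's qualitative signatures (the day-1 asymmetry and the
transfer/specificity pattern are ~0.3–0.5 d′ group effects, easily
swamped by parameter scatter in 5-observer means), and the noise ceiling
must stay non-trivially below 1. Sweeping the CV over 0.05–0.15 across 40
cohorts per value showed the signature-expression rate falling from ~100%
to 75% while the mean ceiling dropped from ~0.96 to ~0.93; the default
0.08 keeps signatures near-certain (day-1 asymmetry 100%, transfer pattern
97% of cohorts) with a ceiling around [0.93, 0.96]. Sessions are
homogeneous blocks: no SOA dimension, no reaction times, no within-session
learning, no sequential effects, and no color-test session. Passing tests
therefore certify the pipeline's behavior under the model's own
assumptions plus simple parameter heterogeneity — not robustness to the
structured variability (SOA effects, criterion drift, learning-curve shape
violations) that real observers add.

## Known limitations

- Attributing learning to target versus distractor from training days alone
  is fragile at this design's noise level: with 5 observers × 540 trials,
  the SSE separation between the correct and the role-swapped attribution
  is small, and individual cohorts can genuinely favour a different sigma
  gap than the generating truth. The coarse-to-fine fit removes the
  *numerical* part of this fragility; the sampling part is irreducible at
  the study's size.
- The noise model (lognormal parameter jitter) ignores trial-to-trial
  criterion drift and any observer-specific decision suboptimality.
- AICc differences depend on the k-convention; values are comparable within
  this package, not across conventions that count the noise variance.

## Problem sizes used in tests and scripts

Model d′ uses 4,000 simulated trials per evaluation in fits (the standard
setting), 20,000 in refinement stages and 40,000 for reported transfer
predictions. The model-recovery study uses 20 cohorts with 1,000-trial
evaluations and 2 starts per fit; cross-validation defaults to 2–5 starts
per refit. These sizes were chosen so each analysis resolves the quantity
it reports well inside the decision margins it is used for.
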