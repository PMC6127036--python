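# Methods

## The model

An observer discriminates the direction (left/right) of random-dot motion
in blocks of 15–42 trials.  Each block has a concealed base rate
`B ∈ {0, 0.2, 0.4, 0.6, 0.8, 1}` — the probability that motion is
rightward — drawn uniformly per block.  Per trial, motion strength `|c|`
is drawn from {0, 3.2, 6.4, 12.8, 25.6, 51.2}% (approximately balanced
within a block, independent of `B`), and viewing duration `T` from a
truncated exponential (τ = 0.6 s) on [0.1, 0.9] s.

**Decision stage.**  Momentary evidence is accumulated as a drift-diffusion
process: drift `κc` per second, unit diffusion variance per second (not a
free parameter — any other value is absorbed by rescaling `κ` and the
bound `A`), absorbing bounds at `±A`.  A trial ends with terminal state
`(e, te)` either at a bound hit (`|e| = A`, `te ≤ T`) or at stimulus
offset (`te = T`).

**Counterfactual posterior.**  From the Fokker–Planck solution
`p(e, te | c, d)` and a uniform distribution over the coherences
compatible with each direction, the observer can evaluate
`pu(R | e, te) = p(e,te|R) / (p(e,te|R) + p(e,te|L))` — the posterior
probability of rightward motion under a fictitious neutral prior
(`B = 0.5`).  It is proportional to the likelihood ratio and is the
correct evidence for learning the base rate, because it is not
contaminated by the observer's current bias.

**Choice and confidence.**  The biased posterior combines the
counterfactual posterior with the prior expectation
`E[B] = Σ B·p(B)`:

    p(R | e, te, E) = E[B]·pu / (E[B]·pu + (1−E[B])·(1−pu))

The observer chooses rightward when this exceeds 1/2 (fair coin at an
exact tie) and reports the posterior for the chosen side as confidence;
a criterion `ϕ` classifies reports as high/low.

**Belief updating.**  After every trial p(B) is multiplied pointwise by
`B·νr + (1−B)·(1−νr)` and renormalized; the posterior becomes the next
trial's prior, and p(B) resets to the two-parameter initial prior
(weights `(ω2, ω1, 1, 1, ω1, ω2)`) at each block start.  The update
weight `νr` distinguishes the rival rules:

| rule | νr |
|---|---|
| bayesian | `pu(R | e, te)` (counterfactual posterior) |
| choice_only | 1 for right choices, 0 for left |
| choice_confidence | reported posterior for rightward |
| mixture | `β·pu + (1−β)·`reported posterior |
| empirical | logistic in (confidence, prior expectation for the chosen side) |

The empirical rule uses the five-term basis
{1, conf, p, conf·p, conf²} inside the logit; the fifth (curvature) term
was chosen here because the flexible map only needs enough curvature to
interpolate between the three theoretical rules.

The reported **belief** that the block favors rightward is
`Σ_{B>0.5} p(B)`.  Two lag variants are provided: a first-order filter on
the *report* only (`f_i = f_{i−1} + (b_i − f_{i−1})(1−α)`, seeded at 0.5
per block; internal p(B) untouched) and a non-Bayesian variant in which
the p(B) update itself is the same convex combination (affecting choice
and confidence too).

## Fitting

Each trial contributes the probability of the observed (choice, high/low
confidence) pair.  At fixed `E[B]` the biased posterior is monotone in
`pu`, so the four outcomes correspond to three cutoffs on `pu`; the
integral of `p(e, te | c, T)` over each region is computed by sorting the
joint-density atoms by their `pu` value once per (coherence, duration)
condition and reading three points off the cumulative mass.  Mass exactly
at the choice cutoff is split evenly (the tie is a fair coin); the high
band is closed (`conf ≥ ϕ`).  Zero-mass observed outcomes are floored at
1e−10 with a diagnostic counter.

Between trials p(B) is propagated from the *subject's* observed choice
and confidence.  For the bayesian and mixture rules the counterfactual
weight is recovered by the exact inverse of the biased-posterior mapping,
`odds(pu) = odds(conf_R)·(1−E[B])/E[B]`, with confidences clipped to
[1e−4, 1−1e−4] so the odds stay finite.

Raw confidence ratings need not be calibrated probabilities, so they are
rank-matched onto the probability-correct values of a model simulation on
the identical stimulus sequence (ties receive their band mean, keeping
the map weakly monotone and the high/low labels unchanged).  All
optimizer restarts are scored under a common initial transform (the raw
reports, which already live on the probability scale); the transform is
then refreshed and re-optimized at the incumbent optimum until the
log-likelihood changes by less than 0.01 (at most 3 rounds).

Optimization is bounded derivative-free Powell search from Latin-
hypercube restarts (default 30; the recovery analyses here use 5), with
box bounds κ ∈ [1, 60], A ∈ [0.3, 5], ϕ ∈ (0.5, 0.999], ω ∈ [0, 20],
β ∈ [0, 1], empirical betas ∈ [−20, 20], update-lag α ∈ [0, 0.95].
Nelder–Mead was tried and stalls on this likelihood; Powell reaches the
generating parameters from dispersed starts within a few hundred
evaluations.

Confidence binarization for data lacking an explicit category uses the
per-subject 30th percentile of the raw reports, ties going to "low"; the
synthetic observer instead emits its category directly from the ϕ
criterion, which is what makes ϕ a recoverable parameter on synthetic
data (a purely continuous synthetic report would leave ϕ without any
behavioral trace).

The report-lag constant α is fit separately by minimizing the MSE between
lag-filtered predicted beliefs and reported beliefs (coarse grid plus
bounded scalar refinement); the update-lag variant is fit by maximum
likelihood alongside the other parameters.

## Numerics

**Propagation.**  The evidence density is evolved on a cell-centered grid
whose ghost (absorbing) cells sit exactly at `±A`, using Crank–Nicolson
over a Scharfetter–Gummel (exponential-fitting) discretization.  The SG
hop-rate ratio equals `exp(−2μh)` exactly, so the discrete chain
reproduces the continuous first-passage splitting probabilities to
machine precision (verified against the gambler's-ruin closed form to
1e−13), and it remains positive and accurate at the high cell-Péclet
corner of the parameter box where upwinding is overly diffusive and
central differencing oscillates.  The first two steps are implicit-Euler
half-steps (Rannacher smoothing) so the point-mass initial condition
cannot excite Crank–Nicolson oscillations.  Mass is conserved to solver
round-off at every step: boundary losses are computed from the same
time-averaged boundary states the solver uses, and the absorbed stream at
each bound carries its own time-resolved counterfactual value.

Bound crossings are assigned to the end of the step in which they occur;
curtailed trials end at exactly `T` (a dt-order bias, identical in
simulation and propagation).  Default grids: dt = 1 ms with 513 evidence
cells for stand-alone maps; fitting uses dt = 7.5 ms with 181 cells
(doubling either resolution changes choice probabilities by <1e−3).
Simulation uses Euler–Maruyama at 0.5–1 ms with a Brownian-bridge
correction for intra-step crossings, which removes the O(√dt)
first-passage bias (simulated joints agree with the propagated density by
coarse-bin chi-square).

Grid nodes that no coherence can reach carry the tail-limit posterior
(1 above the origin, 0 below) and are flagged; lookups for simulated
trials use bilinear interpolation in (t, e), and absorbed trials use the
bound columns.  0% coherence counts as compatible with both directions in
the marginal `p(e,te|d)` (a configuration switch, `include_zero_both`,
exposes the alternative reading).

## Synthetic-data generator

The stimulus generator follows the task rules exactly: block lengths
geometric(1/15) truncated to [15, 42]; base rates uniform over the six
values with the rightward-trial count equal to round(B·ntr) (round half
away from zero — never exercised in-domain); coherence lists built by
repeating the six magnitudes to the first multiple of six strictly larger
than ntr, shuffling, and taking the first ntr (so per-magnitude counts
follow the hypergeometric bounds of that pool); durations truncated-
exponential.  0% trials keep a nominal direction so the base-rate count
is well defined.  All randomness flows from one seed through per-block
substreams.

The reference observer used throughout the tests is κ = 14, A = 1.2,
ϕ = 0.75, ω1 = 1.0, ω2 = 0.6: a sensitivity/bound pair in the typical
range for coherence-as-fraction motion discrimination (overall accuracy
≈ 0.83 across the coherence mix, at ceiling for 51.2%), a criterion near
the 30th percentile of the resulting confidence distribution (mirroring
the binarization convention), and a mild under-weighting of the extreme
base rates.  Recovery and model-recovery analyses use 150 blocks per
synthetic subject and three subjects — the deposited study's scale —
with 5 optimizer restarts; belief-dynamics summaries use up to 2,000
blocks from a single simulation.

What the generator does **not** emulate: motor/pointing noise on the
confidence arc and belief slider, sequential non-stationarities
(fatigue, session breaks), idiosyncratic confidence scale use (the
synthetic reports are exactly calibrated posteriors, so the rank-matching
transform is near-identity on synthetic data), and any reward- or
value-induced biases.  Passing recovery tests therefore show the
estimator is consistent and the model comparison discriminating under the
model's own assumptions — not that human data are free of the
mis-specifications above.

## Known limitations

* The likelihood treats duration on the propagation time grid (durations
  are snapped to the nearest step), a quantization well below behavioral
  resolution but visible at extreme grid coarsening.
* The empirical rule's fifth basis term is a design choice; any basis
  rich enough to bend the (confidence × expectation) map would do.
* Reaction times are out of scope (durations are experimenter-
  controlled), as are collapsing bounds and across-trial drift
  variability.
* Fits are per subject; no hierarchical pooling across subjects and no
  bootstrap uncertainty on the fitted parameters.
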