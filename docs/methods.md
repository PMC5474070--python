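# Methods

## The model

`ewalearn` implements a multilevel experience-weighted attraction (EWA)
model of behavioural choice for bout-level time series: a group of
individuals repeatedly chooses among K techniques; each choice is driven by
a mixture of accumulated personal experience and recently witnessed social
information.

**Individual learning.** Each individual j keeps an attraction score
A_ij for every technique i. After a bout with realized pay-off π,

    A_ij ← (1 − φ_j) A_ij + φ_j π          (performed technique only)

φ_j ∈ (0,1) is the updating (recency) weight; small φ means past
experience dominates. Unperformed techniques neither update nor decay (the
update is defined per observation of the performed behaviour; a global
decay variant was considered and rejected because it changes the meaning of
φ from a recency weight to a forgetting rate). The individual choice rule
is soft-max, P_ind(i) ∝ exp(λ A_ij), with a single group-level sensitivity
λ ≥ 0 (no individual variation in λ — per-individual soft-max scales are
not separately identifiable from the scale of the attractions at this data
size).

**Pay-off.** A successful bout opening the fruit in T seconds pays
π = 1/log T; failures pay 0. Pay-off declines with opening time, steepest
early. Durations are clamped below at 2 s so the log stays positive; field
opening times are tens to hundreds of seconds, so the clamp only guards
synthetic edge cases.

**Social learning.** Each decision, individual j has a window summary of
the bouts it witnessed (it was in the audience) in the previous
`window_days` days (default 14; same-day earlier bouts included, own bouts
excluded — self-observation is personal experience, already in A). From the
window: counts N_i per technique and mean cue values κ_ik for five cues —

  * pay: 1/log T of the witnessed outcome (0 on failure),
  * rank: demonstrator is the alpha (0/1),
  * kin: shared matriline (0/1),
  * coho: inverse absolute age difference, 1/(1 + |Δage|),
  * age: demonstrator's standardized age.

The social choice probability is log-linear with frequency-dependence
exponent f:

    S(i) ∝ N_i^f · exp(Σ_k β_k κ_ik)        over techniques with N_i > 0.

f = 1 is unbiased (frequency-proportional) copying, f > 1 conformity,
f < 1 anti-conformity. Cue values are **averaged** per technique rather
than summed: frequency information enters exactly once through N_i^f, and a
sum would re-introduce it into the cue term; the mean also keeps β on the
per-observation cue scale, which is the scale on which the preference
curves (`preference_curve`) are defined. Realized choice is

    P(i) = (1 − γ_j) P_ind(i) + γ_j S(i),

with γ_j ∈ (0,1) the social-information weight. An empty window means no
social term exists and the decision falls back to P_ind alone (rather than
a uniform S, which would penalize naive decisions for information they do
not have).

**Multilevel structure.** φ_j and γ_j are logistic transforms of a
population intercept + standardized-age slope + individual deviation
(non-centered, independent across parameters); f is log-linked, β
identity-linked. Standardizing ages makes the slope priors scale-free; the
age-bias cue uses the same standardized ages.

## Priors

Weakly informative throughout: N(0,1) on cue weights, link-scale intercepts
and slopes; half-normal(1) on between-individual SDs; N(1,1) on log λ.
Under these priors the implied φ and γ place >98% of their mass inside
(0.01, 0.99) — sceptical of boundary values and of large effects.

## Posterior computation

Fitting is posterior sampling behind a single `fit_model` interface. The
backend is the affine-invariant ensemble sampler (emcee), with walkers
playing the role of chains: walkers start in a tight ball around a MAP
estimate (L-BFGS on the log posterior) and move by differential-evolution
proposals (80% DE, 20% DE-snooker), which keeps burn-in short for the
hierarchical specs. Convergence is monitored by split R-hat and bulk ESS
computed across walkers (arviz); a fit with max R-hat ≥ 1.2 or min ESS ≤ 50
is flagged `converged=False` and logged, never silently returned.

The likelihood replays the bout table once in (day, seq) order. Window
tallies depend only on the data, so they are precomputed into a design
(counts and mean cues per bout); the per-bout replay as a function of
parameters is a compiled (numba) loop, ~0.3 ms per evaluation at 2000 bouts,
which is what makes ensemble sampling practical. Disordered input is an
error rather than silently re-sorted, because re-sorting would corrupt the
attraction dynamics. The compiled path is verified against a naive
pure-Python per-bout replay to < 1e-10 on every fixture.

## Model set and comparison

Nine canonical learning strategies: individual-only; unbiased frequency
copying (f = 1, no cues); frequency-dependent copying (f free); five
single-cue strategies (pay-off, rank, kin, age-similarity, age-bias); and a
global model with all cues, free f, and age effects on φ and γ. Default
varying effects are φ (plus γ where social learning is on); the global
model adds f and the pay-off weight. Any other combination can be built
directly with `ModelSpec`.

Comparison uses WAIC with the single bout-choice event as the pointwise
unit: lppd = Σ_i log mean_s exp(ll_si), p_waic = Σ_i var_s(ll_si) (sample
variance, ddof = 1), WAIC = −2(lppd − p_waic), SE = sqrt(n · var of the
pointwise contributions). Model weights are Akaike-style,
w_m ∝ exp(−ΔWAIC_m/2). Window width is treated by fixed-width sensitivity
analysis over {7, 14, 21, 28} days (`window_sensitivity`); estimating the
width as a parameter is out of scope.

## The synthetic-data generator

`simulate_group` runs the generative process forward: per day a Poisson
number of bouts; per bout a uniformly drawn actor, its window tallied over
what it witnessed, technique sampled from the individual/social mixture,
outcome drawn from the technique's profile (Bernoulli success; lognormal
opening time with the profile's median and log-SD; failure durations drawn
from the same lognormal × 1.5, since no failure-duration data exist), an
audience of 0–3 uniformly sampled observers, and the actor's attraction
updated. Defaults emulate the field study: ~25 individuals, 7 techniques
with success probabilities 0.38–0.89 and duration medians ~29–211 s
(log-SDs backed out of the mean/median ratio), 75 experimental days with
~19 bouts/day (~1400 bouts total), a 14-day window. Knowledgeable
immigrant adults are represented by nonzero initial attractions for their
natal technique (~0.25–0.3, the long-run attraction scale of a reliable
technique).

Named fixtures (`make_fixture`): `tiny` (4 agents, 2 techniques, <200
bouts), `table1-like` (full field scale), `payoff-biased` (12 agents, 4
techniques, ~2000 bouts; β_pay = 1.02, f = 1, φ/γ means 0.15/0.14 with
age slopes −0.11/−0.10 and individual SDs 0.6/0.7 — the field-scale
posterior medians), `individual-only` (γ = 0), and `conformist` (two
equal-pay-off techniques, f = 3, γ mean 0.85). The payoff-biased technique
set spans the field pay-off contrast — quick-and-reliable through
never-successful — because that contrast (mean pay-off cues from ~0.24 down
to 0) is what identifies pay-off bias separately from frequency dependence.

The conformist fixture's γ = 0.85 deserves a note: with equal pay-offs the
attractions equalize, P_ind → 1/K, and every agent keeps a minority-choice
floor of about (1−γ)/K + γ S_min. At γ ≤ 0.8 the majority share is capped
near 0.8–0.85 for *any* f, so a regime intended to exhibit
conformity-driven fixation must make the social channel dominant.

What the generator does **not** emulate: endogenous attention (who chooses
to watch whom — audiences are exogenous), spatial structure of platforms,
demography, within-day non-stationarity, and observation error in the
recorded audiences. Passing recovery tests therefore show that the
inference machinery is correct *for the assumed generative process*, not
that the model is correct for any particular field system.

## Problem sizes used by the tests and the acceptance script

Recovery runs use the payoff-biased fixture at its native scale (~2000
bouts, 12 agents) with 10 (tests) or 5 (acceptance script) replicates and
ensemble runs of ~900 iterations after MAP initialization; WAIC
identifiability runs use 35-day (~500-bout) replicates of each regime,
three per regime, fitted with the four canonical specs; diffusion runs use
20 replicates. These sizes give stable pass/fail behaviour for the
properties tested while keeping a full run of the suite in the tens of
minutes on one core.

## Known limitations

* **Pay-off bias is weakly identified at realistic cue scales.** The
  pay-off cue spans only ~0.3 units, and it enters choice with weight
  γ ≈ 0.14, so ~2000 bouts support a β_pay posterior SD of roughly 0.8 even
  under the correctly specified single-cue model — the same order as the
  field-scale posterior SD. Sign recovery is reliable; interval separation
  from zero at truth β_pay ≈ 1 is not. Relatedly, pay-off bias and
  frequency dependence are partly equifinal (high-pay-off techniques are
  also common), so WAIC can rank `frequency-dependent` above `cue-pay` on
  pay-off-biased data.
* **WAIC rarely prefers the minimal true model over the global model.**
  Because the global spec nests every generating regime, its penalized score
  typically trails the matching minimal spec by only 1–3 WAIC points —
  within the WAIC standard error — and finite-chain underestimation of
  posterior spread further deflates its effective-parameter penalty, so the
  global model often ranks first on data generated by its sub-models. The
  wrong *non-nesting* strategies are separated decisively (tens of WAIC
  points). Treat WAIC weights here as evidence about which social-learning
  ingredients are needed, not as a minimal-model oracle.
* The ensemble sampler mixes more slowly than gradient-based HMC on the
  full hierarchical model; R-hat across walkers is a heuristic (walkers are
  not independent chains), and fits of the global spec at default lengths
  can carry R-hat ≈ 1.2–1.4. Diagnostics are attached to every fit.
* The parameter count of the global model depends on which varying effects
  are enabled; the module reports its own inventory (`ParamLayout.names`).
* No LOO-CV/PSIS, no Bayes factors, no estimation of the window width.
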