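# ewalearn

Multilevel experience-weighted attraction (EWA) models of social and
individual learning in animal groups.

## What this is for

When a new behaviour (say, a technique for opening a protected fruit)
appears in a wild social group, which learning strategies spread it?
Individuals could rely on their own reinforcement history, copy the
majority (conformity), copy whatever pays best (pay-off bias), or copy
particular demonstrators (rank, kin, similar-aged or older individuals).
`ewalearn` is for behavioural ecologists and cultural-evolution researchers
who have (or want to simulate) bout-level records of who did what, when,
with what outcome, and who was watching — and who want to estimate, per
individual, how those strategies combine.

## The model

Accumulated experience is an attraction score per individual j and
technique i, updated after each bout with realized pay-off π:

    A_ij,t+1 = (1 − φ_j) A_ij,t + φ_j π_t

Pay-off for a successful bout of duration T is π = 1/log T; failures pay 0.
Individual choice is soft-max, P_ind(i) ∝ exp(λ A_ij). Social information
is tallied over a moving window (default 14 days) of bouts the individual
witnessed, giving technique frequencies N_i and mean cue values κ
(pay-off, alpha rank, matrilineal kinship, age similarity, age bias), and

    S(i) ∝ N_i^f · exp(Σ_k β_k κ_ik)

with f the conformity exponent (f > 1 conformist, f < 1 anti-conformist)
and β the cue weights. Realized choice mixes the two channels:

    P(i) = (1 − γ_j) P_ind(i) + γ_j S(i)

φ_j and γ_j vary by individual through logistic links with standardized-age
slopes. Models are fitted by posterior sampling under weakly informative
priors and compared with WAIC; a forward simulator of the same generative
process provides synthetic data with known parameters for recovery tests.
See `docs/methods.md` for the full account.

## Worked example

Simulate a pay-off-biased group (12 individuals, 4 techniques of unequal
pay-off, 35 days), fit an individual-only and a pay-off-bias model, and
compare them:

```python
from dataclasses import replace
import ewalearn as ew
from ewalearn.inference import MCMCConfig, ModelSpec
from ewalearn.simulate import simulate_group

cfg, _ = ew.make_fixture("payoff-biased")
cfg = replace(cfg, n_days=35, bouts_per_day=14.0)
bouts = simulate_group(cfg, seed=1)

mcmc = MCMCConfig(iterations=900, warmup=400, seed=1)
fits = [ew.fit_model(bouts, cfg.roster, cfg.technique_set, spec, mcmc=mcmc)
        for spec in (ModelSpec.individual_only(), ModelSpec.single_cue("pay"))]
print(fits[1].summary().round(3))
print(ew.compare_models(fits).table[["label", "waic", "d_waic", "weight"]].round(2))
```

prints

```
          median   lo89%   hi89%
lam       20.507  18.098  23.472
phi_mean   0.209   0.153   0.276
gam_mean   0.119   0.061   0.191
b_pay      0.387  -1.635   1.410
             label    waic  d_waic  weight
0          cue-pay  712.20    0.00     1.0
1  individual-only  722.92   10.72     0.0
```

Read this as: the group's soft-max sensitivity λ ≈ 20.5, individuals update
attractions slowly (φ ≈ 0.21 — past experience dominates), and about 12% of
each choice (γ ≈ 0.12) is driven by social cues. The pay-off-bias weight
`b_pay` is positive at the median but weakly identified at this data size
(500 bouts); the model comparison is nevertheless decisive that social
learning with a pay-off cue predicts choices better than individual
learning alone (ΔWAIC ≈ 11, all weight on `cue-pay`).

There is also a command-line pipeline (`ewalearn simulate|fit|compare|
recover|sensitivity --config cfg.json`) that writes bout/posterior/model
tables as CSV + JSON into a run directory.

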