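# snagfall

Hierarchical Bayesian analysis of standing-dead-tree (snag) persistence and
its carbon-cycle consequences.

## The problem

When a tree dies it usually remains standing for years as a *snag* before it
falls and becomes a log. Where a dead tree sits in that sequence matters: a
snag is wildlife habitat and slowly decaying aboveground carbon, while a
fallen log decays an order of magnitude faster through ground contact. Forest
inventories resurvey plots on a multi-year cycle, so what they record about
each snag is interval-censored: standing again after *t* years, or gone.

`snagfall` is for ecologists and biometricians who want to estimate what
drives snag fall from such resurvey data — regional climate, stem size,
stand density, species' wood durability — and to propagate the fitted
effects into forecasts of deadwood carbon under warming.

## The model

Each observed snag *i* in physiographic class *j*, grid cell *k*, of species
*l* is a single Bernoulli trial

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>ijkl</sub> ~ Bernoulli(p<sub>ijkl</sub><sup>t</sup>),

where *p* is the **annualized** probability of remaining standing and *t*
the census interval in years. The annual probability follows a logistic
regression with three crossed random-effect layers:

&nbsp;&nbsp;&nbsp;&nbsp;logit(p<sub>ijkl</sub>) = β₀ + **t**<sub>ijkl</sub>·**ρ** + u<sub>j</sub> + v<sub>k</sub> + w<sub>l</sub>

* u<sub>j</sub> ~ Normal(0, σ²_P): exchangeable physiographic-class effects;
* v<sub>k</sub>: an intrinsic Gaussian conditional autoregressive (CAR)
  field on the survey grid — each cell is normal around its neighbors' mean
  with variance σ²_G / (number of neighbors);
* w<sub>l</sub> ~ Normal(μ<sub>l</sub>, σ²_S) with
  μ<sub>l</sub> = β_DUR · (DUR<sub>l</sub> − D̄UR): species effects centered
  on ordinal wood durability (0 = least durable, 4 = most durable).

Durability itself is modeled on the logit(DUR/4) scale with species nested
in family nested in division (angiosperm/gymnosperm), so species with no
published durability estimate get theirs imputed from relatives, jointly
with everything else during MCMC. All effect blocks are constrained to sum
to zero; β₀ is therefore the annualized baseline log-odds of standing at
average covariate conditions. Half-life is T<sub>½</sub> = log 0.5 / log p,
and average predictive comparisons translate a perturbation ξ of one driver
(e.g. +2.4 °C) into the posterior change in annual persistence or half-life
averaged over all observed snags.

A linear discrete-time carbon model (live, litter, snag, log pools; snags
fall at rate 1 − p) turns fitted persistence changes into changes in
steady-state snag carbon and net ecosystem production (NEP).

## Worked example

Everything runs without external data: the `snagfall.simulate` module
generates surveys with the exact statistical structure the model assumes,
with known truths. The numbered scripts under `analysis/` walk through the
pipeline; `python analysis/01_simulate.py` then `02_fit.py` print:

```
mimic survey: n=12000, mean interval 5.00 yr, 49.5% fallen before resurvey
recovery survey: n=5000, 40 species, 8 with masked durability

kept 3 x 1800 draws
  rho[AT]    mean -0.328 [-0.375, -0.280]  truth -0.30
  rho[DIA]   mean +0.210 [+0.162, +0.256]  truth +0.20
  rho[TPH]   mean +0.126 [+0.080, +0.171]  truth +0.10
  beta_dur   mean +0.176 [-0.027, +0.373]  truth +0.30
  beta0      mean +1.993 [+1.946, +2.041]  truth +2.00
```

i.e. the sampler recovers a strong negative temperature effect (warmer →
faster fall), positive diameter and density effects, and the durability
slope, each within two posterior standard deviations of the generating
value. `03_diagnose.py` checks Brooks–Gelman–Rubin upper limits,
`04_adequacy.py` reports the observed-vs-predicted proportion correct and
exact odds ratio, `05_effects.py` computes the average predictive
comparisons, and `06_carbon.py` pushes the warming response through the
carbon model (the fitted one-sd warming response removes roughly a fifth of
steady-state snag carbon under the packaged northern-hardwood-like budget:
-20.4% [-23.0%, -18.0%]).

The same pipeline is exposed as a CLI:
`snagfall simulate|fit|diagnose|adequacy|effects|carbon` (see `--help`).

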