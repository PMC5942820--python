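# Methods

## The persistence model

A snag observed standing at one inventory visit is recorded at the next
visit, *t* years later, as still standing (S = 1) or fallen (S = 0). The
model treats each record as one Bernoulli trial with success probability
p^t, where p is the annualized probability of remaining standing, so that
intervals of different lengths are directly comparable and survival over
consecutive intervals multiplies: p^(t1+t2) = p^t1 · p^t2. On the logit
scale p is a linear function of centered continuous covariates (mean annual
temperature AT in °C, stem diameter DIA in cm, stand density TPH in
trees/ha by default; WND, SL, QMD, DEN are accepted but off by default)
plus three random-effect layers:

* **Physiographic classes** u_j ~ Normal(0, σ_P²), exchangeable.
* **Grid cells** v_k: an intrinsic (improper) conditional autoregressive
  field. Conditionally, v_k given its neighbors is normal around their mean
  with variance σ_G²/a_k+, where a_k+ counts the neighbors. The joint prior
  is implemented in pairwise-difference form,
  (rank/2)·log τ − (τ/2)·Σ_edges (v_k − v_h)² with τ = σ_G⁻², rank = number
  of non-isolated cells minus connected components. Adjacency is rook
  (shared edge, ≤ 4 neighbors); an isolated cell falls back to an
  independent Normal(0, σ_G²) and a warning.
* **Species** w_l ~ Normal(μ_l, σ_S²) with μ_l = β_DUR·(DUR_l − D̄UR). D̄UR
  is the mean durability over species with an observed estimate, computed
  once from the input table and held fixed.

Wood durability is an ordinal 0–4 score. Its taxonomic measurement model
operates on z_l = logit(DUR_l/4) (values clamped to [0.05, 3.95] before the
transform so the end categories map to finite logits while preserving
order): z_l ~ Normal(μ_f(l), σ_f²), μ_f ~ Normal(μ_d(f), σ_d²) with
divisions angiosperm/gymnosperm. Species without an observed durability
carry z_l as a latent variable. By default the normal measurement model
applies to observed durabilities as well (configurable
`dur_prior_on_observed=False` restricts it to the latent ones); the latent
coordinate is z, so no Jacobian appears in the stated density.

Priors: Normal(0, 1000) (variance) on each covariate effect, β_DUR and the
division means; a flat prior on the intercept β₀; Uniform(0, 100) on σ_P,
σ_S, σ_f, σ_d; Gamma(0.5, rate 2) on the CAR precision τ (expressed over
σ_G with the 2σ⁻³ Jacobian). Out-of-support states return −∞ as a sentinel
rather than raising, so samplers can reject them.

### Sum-to-zero identification

β₀ plus the means of u, v, w is the only identified combination of those
levels, so all three blocks are reported centered. In the sampler this is
done two ways, deliberately: the CAR block is recentred in-chain after
every sweep (the intrinsic prior is shift-invariant and the flat-prior
intercept absorbs the mean, so the move is measure-preserving and pins the
improper null direction), while the exchangeable blocks u and w are left
free in-chain — their proper normal priors are not shift-invariant, so
in-chain recentring would break detailed balance — and the centering
reparameterization is applied when a draw is recorded. Every recorded
state satisfies |Σu|, |Σv|, |Σw| < 1e-10 exactly as downstream consumers
assume.

## Sampling

Adaptive random-walk Metropolis-within-Gibbs. Scalar parameters (β₀, each
ρ, β_DUR, and the five σ's on the log scale with the appropriate Jacobian)
update one at a time against the full likelihood or their prior terms.
The random-effect blocks update simultaneously: elements of u and w are
conditionally independent given everything else, so a vector of proposals
is accepted element-wise in one vectorized pass, with each element's
likelihood change aggregated by `bincount` over its records; the CAR block
does the same within graph-coloring classes (two colors on a rook lattice),
because cells of one color are never adjacent. Latent durabilities and the
taxonomy means update the same way and never touch the likelihood.
Per-parameter proposal scales adapt toward 44% acceptance during burn-in
only, so the post-burn-in kernel is fixed and every run is exactly
reproducible from its per-chain seeds. Initialization: β₀ at the empirical
logit of the annualized standing fraction, effects at zero, σ's at 1,
latent durabilities at family means, all jittered per chain.

Desk-scale defaults are 3 chains × 20,000 iterations, burn-in 2,000,
thinned by 10; the field-scale protocol (5 × 110,000, burn-in 10,000, thin
40) is a configuration choice. Convergence is judged by the
Brooks–Gelman–Rubin corrected scale-reduction factor with its 97.5%
F-quantile upper limit per parameter (flag: all upper limits < 1.05 by
default).

## What the generator emulates — and what it does not

`simulate_survey` draws covariates as independent (optionally truncated)
normals, census intervals as Normal(5, 0.5²) clipped below at 0.5 yr,
group memberships uniformly, durabilities from the taxonomy hierarchy, the
spatial field from the exact sum-to-zero intrinsic CAR (eigenbasis of the
graph Laplacian), and outcomes as Bernoulli(p^t) — i.e. data that satisfy
the model's assumptions exactly. The `default_study_mimic` configuration
echoes an eastern-US inventory: ~5.01-yr mean intervals, baseline annual
persistence 0.881 (so roughly 48% fallen over an average interval), 16
physiographic classes, a 10×10 grid, 60 species with 20% missing
durability, and a 12.7 cm floor on DIA matching the snag definition.

Passing recovery tests on these data show the estimation machinery is
correct; they do not show the model is adequate for real inventories,
where covariates are correlated and spatially structured, species
abundances are highly uneven, intervals cluster by survey panel, and
fall/decay processes can violate the annualized-Bernoulli form.

The `parameter_recovery_config` experiment fixes the validation conditions:
n = 5,000 snags, 6×6 grid, 40 species in 8 families, 20% durability
masked, covariates standardized (unit sd), true effects AT −0.3, DIA +0.2,
TPH +0.1, β_DUR +0.3, σ_f = 0.3. The replicated coverage check runs 20
datasets at n = 2,000 with a shortened 2-chain × 6,000-iteration protocol —
enough for interval coverage of a strongly identified fixed effect — and
asks for ≥ 80% empirical coverage of the nominal 95% interval.

### A small-grid caveat on the CAR check

Under the sum-to-zero intrinsic CAR the per-cell regression slope of v_k on
its neighbor mean is exactly (S a_k)_k / (a_kᵀ S a_k) with S the
pseudoinverse Laplacian. On a 4×4 lattice the projection makes these
0.816–0.888, not 1; the unconstrained-conditional value of 1 emerges only
as the grid grows (6×6: 0.94–0.98; 10×10: ≈ 1.00). The sampler's tests
therefore compare Monte-Carlo slopes to these exact values at 4×4 and to
the [0.9, 1.1] band at 10×10.

## Interpretation layer

* **Standardized effects** follow the literal reported rule — posterior
  mean and 95% CI limits *divided* by the covariate sd; the conventional
  multiply-by-sd variant sits behind `convention="multiply"`, clearly
  labeled, because dividing yields units of logit per sd⁻¹ and the intent
  of the rule is ambiguous. For durability the sd of the 0–4 scores depends
  on the imputed values, so it is recomputed per posterior draw and the
  summary averaged over draws.
* **Average predictive comparisons** Δ(ξ) average, over all records and per
  posterior draw, the change in the response when the focal predictor moves
  by ξ with everything else held at observed values. The response is the
  annualized probability (not p^t), or the half-life log 0.5 / log p
  computed on the earliest-decay-class subset only; a `linear` response
  exists as a test hook (Δ = ρξ exactly). Default mid-century scenarios:
  AT +2.4 °C, DIA +3.5 cm, TPH −100 trees/ha, durability −1 class.
  Perturbing durability adds β_DUR·ξ to the linear predictor with D̄UR held
  fixed. The plug-in variant evaluates each record at the posterior-mean
  imputed durability; `average_with_imputation` substitutes each draw's own
  imputed values (shifting the fitted linear predictor by
  β_DUR·(DUR_draw − DUR_plug) before perturbing), which reduces exactly to
  the plug-in version when nothing is missing and can only widen the
  interval. Draws are subsampled to 5,000 with replacement by default.
* **Adequacy**: predictions are p^t at posterior-mean parameters rounded at
  0.5 (ties predict standing). The 2×2 observed × predicted table is
  summarized by the proportion correct and the conditional-MLE odds ratio
  with an exact central CI from Fisher's noncentral hypergeometric
  distribution and the standard two-sided exact p — the same construction
  as R's `fisher.test`. Odds are of standing among predicted-standing over
  predicted-fallen. A zero margin yields a degenerate conditional
  distribution; the estimate is reported as NaN with the uninformative
  (0, ∞) interval and p = 1.

## The carbon model

Linear, spatially implicit, one-year timestep, four pools (kg C ha⁻¹):
live biomass gains a constant NPP and loses mortality m (split
`snag_fraction` to snags, the rest directly to logs) and litter production;
snags fall at f = 1 − p_snag and decay at k_snag; logs decay at k_log,
litter at k_litter. All decay flows to heterotrophic respiration, so total
carbon obeys Δtotal = NPP − Σdecay exactly and the steady state solves in
closed form (live* = NPP/(m+lit), snag* = φ·m·live*/(f + k_snag), …). NEP
is NPP minus the decay flux, positive = uptake; it is NPP with empty
detritus (the "maximum NEP" bound) and identically zero at the steady state
of this closed model. Because steady-state NEP carries no sensitivity
information, `persistence_sensitivity` compares NEP on the accumulation
transient — live at steady state, detritus starting empty, evaluated at a
50-year horizon by default — where faster snag fall routes carbon through
the fast-decaying log pool and lowers NEP, while snag C is compared at
steady state. Only f changes between scenarios; decay rates are held
fixed.

The packaged `northern_hardwood.yaml` configuration (NPP 5,000 kg C
ha⁻¹ yr⁻¹, mortality 1.2%/yr with 70% snag-forming, litter 5%/yr, decay
0.4/0.04/0.12 for litter/snags/logs, baseline p = 0.881) is an
illustrative round-number budget for a mature north temperate hardwood
stand; every value is overridable and none is a fitted quantity, so the
sensitivity results are shape-level statements, not site predictions.

## Numerical choices and limitations

* Likelihood terms are computed in log space (log p = −log(1+e^(−η)),
  log(1 − p^t) = log(−expm1(t log p))); an outcome of probability zero
  yields −∞, the rejection sentinel.
* The sampler caches per-record likelihood terms and the linear predictor,
  refreshing both every 2,000 sweeps to cap float drift.
* Degenerate covariate columns (constant, or a single row) fall back to
  unit sd in `CovariateSpec.from_data`.
* `exact_odds_ratio` root-finds on log ψ in [−50, 50]; estimates beyond
  e⁵⁰ report as 0/∞.
* The durability clamp (0.05) is configurable only at the module constant;
  analyses with many category-0/4 species should check sensitivity to it.
* Fitting assumes every grid cell index in the data exists in the grid and
  every species has a durability-table row; validation enforces this at
  I/O time.
* No climate-driven decay response, fire/beetle dynamics, or within-interval
  timing: a snag that falls in year 1 or year 4 of a 5-year interval is the
  same observation.
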