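# Methods

## Fitness scores and variance propagation

The assay estimates a focal population's one-generation competitive fitness
against a GFP-marked reference as `W = ln(p1/p0)`. Proportions are measured
by classifying worms on ~10 microscope images per slide sample; each sample
therefore carries sampling error. The propagation model treats each
sample's proportion estimate as having variance `v` (default: the assumed
constant `v = 5·10⁻⁴`, roughly the binomial variance of ~400 classified
worms at p = 0.75; optionally each sample's observed binomial variance
p(1−p)/n). The four replicate competition plates of one assay share
micro-environment, so their offspring proportions are correlated with
ρ = 0.8 by default; the variance of their mean is

    Var(p̄1) = (1/m²)[Σᵢ vᵢ + ρ Σ_{i≠j} √(vᵢvⱼ)]  =  v(1+(m−1)ρ)/m  for equal v,

i.e. 0.85·v at m = 4, ρ = 0.8 — correlation removes most of the benefit of
averaging. The parental proportion comes from a single mixing-tube sample
shared by all four plates, so its variance enters once. The log-ratio
variance is the first-order delta method,
`Var(W) ≈ Var(p̄1)/p1² + Var(p̂0)/p0²`, with parental and offspring
estimates treated as independent. At the operating point p0 = p1 = 0.75
this gives Var(W) ≈ 1.64·10⁻³ (SD ≈ 0.041).

Boundary counts (a class with zero worms) get an Agresti-style continuity
correction (+0.5 to both classes), flagged on the sample and surfaced as a
warning in the score; W is undefined at proportions 0 and 1.

## Effect sizes

Divergence of an evolved population from its ancestor within one block is

    d = (W_ee − W_anc) / s_pooled · J,    s_pooled = √((v_ee + v_anc)/2),

with Hedges' small-sample correction `J = 1 − 3/(4·df − 1)` at
df = n_ee + n_anc − 2 = 6 by default (four replicate plates per side). Two
attributed-variance conventions are implemented:

* `standard` (default): `Var(d) = J²(v_ee+v_anc)/s_pooled² + d²/(2·df)`,
  which reduces to `2J² + d²/12` under the pooled-SD definition — the
  conventional standardized-mean-difference variance;
* `constant`: `Var(d) = 2J²` exactly.

The `d²/(2·df)` term exists to account for the noise of an *empirically
estimated* pooled SD. Here s_pooled is computed from propagated sampling
variances and is nearly deterministic, so the term misattributes variance;
worse, it makes meta-regression weights depend on the estimated effect
itself, which measurably shrinks large coefficients (~10 % in simulation).
The `standard` mode is kept as the default for data analysis because it is
the field convention; all simulation-based validation studies run in
`constant` mode, and any analysis conclusions sensitive to this switch
should be treated with caution.

**Shared-ancestor covariance.** Within a block, every evolved population of
a given reproductive type is standardized against the *same* ancestral
score, so their effect-size errors are correlated:
`Cov(d_i, d_j) = J_i J_j · var_anc/(s_i s_j)` (≈ J² ≈ 0.76, i.e. correlation
≈ ½, when both sides are measured with equal precision). The package can
build this full sampling covariance matrix (`effect_sizes.
sampling_covariance`) and fit the meta-regression against it
(`FitOptions(use_sampling_covariance=True)`). The diagonal-only model is
the default (matching common practice), but per-coefficient confidence
intervals are only calibrated under the full covariance — simulation puts
diagonal-model coverage anywhere between 0.84 and 1.00 per coefficient,
versus 0.94–0.98 with the covariance.

## The meta-regression

Effect sizes are modelled as `d ~ N(Xβ, V)`,

    V = V_sampling + σ²_pop·Z_p Z_pᵀ + σ²_block·Z_b Z_bᵀ + σ²_obs·I,

where `V_sampling` is the known diagonal (or full) sampling covariance and
the three components are crossed random intercepts for population (35
levels; populations recur across 2–4 blocks), block (8 levels; assay
sessions), and observation (80 levels; residual heterogeneity). X is
treatment-coded against the reference cell isoline 6 / wt / 20 °C: main
effects of isoline 8/9, temperature 24, fog, a raw generation-number
covariate (centering available), all two-way interactions of the three
factors and both three-way interactions — 13 columns.

Estimation is REML with β profiled out by GLS. Variance components are
optimized on the log scale (non-negativity by parameterization; the lower
bound 10⁻¹² is an effective zero and is reported as exactly 0) by L-BFGS-B
from three dispersed starts, objective tolerance 10⁻¹⁰; near-zero
components sit cleanly on the boundary, as the population component does on
real-shaped data. Inference is Wald: Z = estimate/SE against the standard
normal, 95 % CIs; predicted means for the 12 design cells are x'β at a
configurable generation value (default: mean observed) with delta-method
CIs. The fit refuses rank-deficient X unless asked to drop aliased columns
(reported), and non-convergence is recorded in the result, never silent.

The companion generation-trend test regresses d on generation number
through the same known-covariance GLS machinery (intercept + slope only).
A naive inverse-variance WLS version is available but its nominal test is
strongly anticonservative here (type-I error ≈ 0.15 at α = 0.05 in null
simulations) because effect sizes are correlated within population, block
and shared ancestor.

## The synthetic-assay generator

The generator mirrors the assay workflow per population × block: a realized
seeding proportion near 0.75 (jitter SD 0.02, the droplet-counting
imprecision of seeding; it cancels from W by construction), one parental
slide sample, and four offspring plates. Measured proportions carry three
error layers, calibrated so that attributed and actual sampling variances
agree:

* shared plate-environment deviation per assay, variance ρ·v (ρ = 0.8,
  v = 5·10⁻⁴) — produces the within-block replicate correlation;
* slide-sampling noise, variance (1−ρ)·v minus the binomial part (a 5 µl
  drop is not perfectly representative);
* binomial counting error over the worms classified per image, with
  per-image totals negative-binomial (mean 200, shape 10; ~2000 classified
  worms per sample, binomial variance ≈ 9.4·10⁻⁵ at p = 0.75). The worms-
  per-image mean is chosen so the binomial part fits inside the (1−ρ)·v
  slice; at proportions far from 0.75 the slide-noise slice clamps at zero
  and realized correlation drifts slightly below ρ.

True divergences are imposed on the d scale, `d = x'β + u_pop + u_block +
e_obs` with variance components defaulting to realistic magnitudes
(σ²_pop = 0, σ²_block = 0.0066, σ²_obs = 0.0208), and mapped to the W scale
by `ΔW = d·s_ref/J` with s_ref the propagation-based pooled SD at the
operating point (0.0406); dividing by J makes downstream d estimates centre
on the truth. Ancestral baselines are 0 (log-ratio units) per isoline plus
a block-level environmental shift (SD 0.05 W; it cancels exactly from
divergences but shapes raw scores the way strong block effects do). With
p0 = 0.75 the offspring proportion has only ln(0.999/0.75) ≈ 0.29 of upward
log-headroom, so the generator clips proportions to (0.001, 0.999) and
warns when more than 5 % of samples hit the bounds (truth scale too extreme
for the counting model).

What the generator does **not** emulate: mating dynamics of the mixed
fog/GFP groups (only net offspring proportions are drawn), image synthesis
or classification errors beyond counting noise, freeze/thaw survival,
cross-contamination, or any mechanistic basis of block effects. Passing
tests therefore validate the statistical pipeline under its own
distributional assumptions, not the biology of a real assay.

## Validation studies and problem sizes

* Parameter recovery: 500 simulated experiments shaped like the packaged
  design, truth vector with realistic magnitudes for every term (isoline 9
  main effect 2.0, one three-way interaction 2.5, generation slope 0.008).
  All 13 REML estimates are unbiased within Monte-Carlo error and Wald CI
  coverage is near-nominal (0.94–0.98) in the covariance-aware
  configuration.
* Null calibration: 1000 simulated experiments with β = 0 and variance
  components at the realistic defaults. Wald rejection rates at α = 0.05
  fall around 0.03–0.05 per coefficient; block-sensitive coefficients
  (notably the intercept) are mildly *conservative* (≈ 0.031), an inherent
  property of plugging boundary-truncated REML estimates of σ²_block (only
  8 blocks, ≈ ½ shared-ancestor correlation) into Wald SEs. The
  generation-slope test is calibrated (≈ 0.035–0.042).
* The REML/GLS core is cross-checked against R `metafor`'s `rma.mv` on the
  same data (estimates and SEs agree to ~10⁻³) and against dense brute-force
  linear algebra on small instances (10⁻⁸).

## Known limitations

* The exact variance-propagation conventions of the original analysis
  (degrees of freedom for J, the Var(d) formula) are not fully published;
  the defaults here are the standard conventions and are config-exposed.
  Coefficient-level agreement with the published table therefore depends on
  those choices.
* Wald-z inference is the reporting convention; with 8 blocks it is
  slightly conservative for block-level contrasts (see above). No
  likelihood-ratio, permutation or small-sample-adjusted tests are
  provided.
* The observation-level component σ²_obs is only weakly identified against
  a constant shift of the attributed sampling variances; its absolute value
  should not be over-interpreted.
* Generation effects are modelled as linear on the d scale; ancestral
  records store generation 0 and never enter effect-size rows.
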