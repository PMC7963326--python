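# Methods

This note documents the models behind `cryptmosaic`, the defaults and why
they were chosen, and what the synthetic data can and cannot say about real
imaging data.

## 1. Synthetic intensity cohorts

Each crypt draws a deficiency category from its genotype's mixture; the
defaults encode the mosaic prevalences the package emulates — heterozygotes
(52.82, 31.88, 4.24, 11.06)% over (NORMAL, CI_DEF, CIV_DEF, CI_CIV_DEF),
homozygotes (0, 53.1, 0, 46.9)%, wild type all NORMAL.

Intensities are generated multiplicatively:

* TOMM20 and VDAC1 are lognormal around the control means *regardless of
  category* — OXPHOS loss does not change mitochondrial mass, and the
  generator enforces that by construction (tested as "mass-marker
  neutrality").
* NDUFB8 and MTCO1 are the crypt's own TOMM20 draw times a lognormal
  mass-normalized level; deficiency scales that level's mean by
  (1 − `deficiency_effect`).

Coupling the OXPHOS markers to the realized TOMM20 reflects the biology
(marker abundance scales with mitochondrial content) and has a statistical
consequence that matters: `control_cv` is exactly the coefficient of
variation of the *ratio* the classifier scores. Had the markers been given
independent noise, the ratio's CV would be √2 larger and a 60% reduction
would sit near z ≈ −4.2 — on the calling line rather than clearly below it.
With the chosen parameterization a deficient crypt scores
z ≈ −0.6/0.1 = −6 with SD 0.4, so the z < −4.5 rule misclassifies at the
~10⁻⁴ level, matching the near-perfect recovery the tests assert.

Defaults: 4 mice per genotype × 200 crypts; control means 1200/1500/1800/1600
AU for NDUFB8/MTCO1/TOMM20/VDAC1 (arbitrary fluorescence units — only ratios
matter); CV 0.10; effect 0.6; no mouse-level intensity effect (an optional
lognormal mouse multiplier exists but defaults off, since crypts are pooled
per genotype for classification).

## 2. Deficiency classification

* Normalization is the plain linear ratio marker/mass; a log-ratio option
  exists but is off by default.
* The reference pools **all** wild-type crypts across wild-type mice; mean
  and sample SD use the n−1 denominator (control cohorts are small).
* The threshold is −4.5 with a **strict** inequality; a crypt exactly on the
  line is NORMAL. The unusually conservative threshold (vs the conventional
  −3) is adopted as given; at these effect sizes the choice is uncritical
  because the deficient cloud is ~6 SDs below the reference.
* Mass-marker QC z-scores the raw TOMM20 and VDAC1 against their control
  distributions with the same threshold; any flag would indicate a
  mitochondrial-mass artifact rather than an OXPHOS call.
* Per-genotype summaries average per-mouse category percentages and report
  SEM = SD/√n_mice; with a single mouse the SEM is reported as 0 with a
  warning rather than NaN so downstream tables stay numeric.

## 3. Labelling protocol and cell model

The default injection schedule places CldU at hours 0, 8, 24, 32, 48, 56, 72
(10 am and 6 pm for three days, 10 am on day four), IdU at hour 80, and
sacrifice at hour 95 (15 h after IdU). Each injection's analogue is
incorporable for `availability_window` = 2 h — thymidine analogues clear
rapidly in vivo — and this is exposed in config because the interpretation
"divided ⇒ labelled" depends on it.

Each cell slot is an independent alternating-renewal process:

* cycle lengths lognormal, mean 24 h (the canonical colonic stem-cell cycle),
  CV 0.15;
* S phase occupies 8/24 of the cycle, placed after a G1 of 60% of the non-S
  time;
* after each mitosis the cell pauses with probability `quiescence_rate`,
  drawing an exponential quiescent gap; otherwise it re-enters immediately;
* a label is acquired when an S interval overlaps an availability window
  (strict overlap, so a zero-width window never labels); labels persist;
* Ki-67+ ⇔ inside an active cycle at sacrifice.

Initialization is exactly stationary without burn-in: because pausing is a
per-cycle Bernoulli event and gaps are exponential, a cell's future depends
only on whether it is currently cycling — with probability equal to the duty
fraction — at a uniform cycle phase, or quiescent with a memoryless
remaining gap.

**The division-rate multiplier.** The parameter of scientific interest
(`rate_multiplier`, 1 = OXPHOS-normal) scales the cell's *long-run division
rate*. It acts through the mean quiescent gap: for multiplier m the gap is
set to g(m) = ((C + q·g₀)/m − C)/q, where C is the mean cycle, q the pause
probability and g₀ the gap scale at m = 1, so that the stationary division
rate 1/(C + q·g(m)) is exactly m times baseline. This choice — rather than
scaling the gap *rate* by m — is deliberate: with a fixed active-cycle time
a pure gap-rate scaling dilutes the realized division-rate ratio
((C+q·g₀) vs (C+q·g₀/m)), whereas the inferential chain treats the
multiplier as a rate ratio on a log link. With the exact construction,
expected label counts scale multiplicatively in m up to per-cell saturation
(probabilities are 1 − exp(−mΛ) per labelling channel), and a lognormal
mouse frailty multiplying m is precisely the log-normal random intercept the
GLMM estimates — the model is correctly specified by design.

**Quiescence defaults.** `quiescence_rate` = 0.2 and
`quiescence_scale_hours` = 600 put cells in bursts of ~5 consecutive daily
cycles separated by long pauses. These values were calibrated once, at
design time, by large-scale simulation of the default protocol: they keep
per-cell label probabilities small enough (dual ≈ 0.057 at m = 1) that the
saturation nonlinearity and the within-cell two-activation channel (a cell
labelling CldU in one burst and IdU in a later one, which scales as m²)
jointly perturb the marginal dual-labelling rate ratio by well under 1% —
measured ratio 1.204 at m = 1.2 — while leaving enough dual events
(~800 per 20-mouse arm) for stable mixed-model fits. Consecutive-cycle
bursts also make dual labelling a genuine two-division event, as the
protocol intends.

**What the generator does not emulate.** Absolute labelling and Ki-67
fractions are understated relative to real crypt epithelium (the whole-crypt
duty fraction is ~17%, whereas most real transit-amplifying cells cycle
continuously); the rate-*contrast* structure, not the absolute proliferative
fraction, is what the package's inferences consume. There is no spatial
position along the crypt axis, no lineage tree, no label dilution over
divisions, and LGR5-high identity is held fixed over the four-day window.
Whole-crypt and LGR5-high slots share one parameter set per crypt.
Passing tests therefore validate the statistical chain — calling,
simulation, inference — not the kinetic realism of any one parameter.

## 4. Count GLMMs

Family log-densities: Poisson, and NB2 with variance μ + αμ². The marginal
likelihood integrates the per-mouse intercept with adaptive Gauss–Hermite
quadrature, Q = 20 nodes by default (accuracy matters at 4 mice/group):

* the conditional mode per group is found by Newton iteration with
  backtracking line search — the objective is strictly concave, but where
  the likelihood is quasi-linear (NB far from the mode) undamped Newton
  oscillates, so each step must not decrease the objective;
* nodes are centred at the mode and scaled by the inverse root curvature;
  the integral uses the standard e^{z²}-weighted transform with
  log-sum-exp stabilization.

A dense trapezoid grid (±10σ, 4001 points) is kept as an independent oracle;
AGQ and grid agree to <10⁻⁶ on random toy datasets in the tests, and the fit
is cross-checked against lme4's `glmer` (nAGQ = 25) in one test. Note that
lme4 reports the nAGQ>1 log-likelihood on a scale missing constant terms;
its Laplace log-likelihood is the comparable quantity.

Fitting maximizes the AGQ log-likelihood over (β, log σ_u[, log α]) with
L-BFGS-B from Poisson-GLM starting values (moment estimate for α). The log
scale enforces positivity; a σ_u estimate collapsing to the lower bound is
reported as σ_u = 0 with a boundary flag, and the reported log-likelihood is
then recomputed at exactly σ_u = 0 so it reduces to the ordinary GLM value.
Standard errors come from the central-difference Hessian of the negative
log-likelihood at the optimum (β block alone at a σ boundary). Inference is
Wald: rate ratio exp(β̂), 95% CI exp(β̂ ± 1.96·se), two-sided normal p,
no multiple-testing adjustment. A likelihood-ratio alternative can be
assembled from `marginal_loglik` directly.

Offsets: label-count models use log(total cells) as exposure, LGR5 models
log(LGR5-high cells), and the cells-per-crypt NB model no offset. Counts are
"per crypt" with varying crypt sizes, so modelling them as rates per cell is
the defensible default; the offset column is recorded in every results
table.

At 40 mice the 95% Wald intervals cover a true rate ratio at ≈ 94% in the
package's own replicate studies — the small deficit is the usual cost of
plugging in σ̂_u without a degrees-of-freedom correction.

## 5. Study sizes, seeds, numerics

The self-validation studies use 10,000 crypts for prevalence recovery
(binomial SEs ~0.2–0.5 percentage points) and 200 replicate cohorts of
40 mice × 50 crypts for effect recovery (Monte-Carlo SE ≈ 0.7 percentage
points on the recovered 20% increase) — sizes at which the checks are
decisive while a full run stays around half a minute. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
configs and seeds give byte-identical CSV outputs. Numerical tolerances:
mode-finding 10⁻¹⁰, AGQ-vs-grid acceptance 10⁻⁶, σ_u boundary floor 10⁻³,
self-standardization identity 10⁻⁹.

## 6. Pipeline conventions

The intra-mouse analysis joins called categories onto counts by exact
(mouse, crypt) key — the serial-section registration of a real experiment is
treated as a solved problem. OXPHOS-normal crypts are the reference level
for category contrasts; wild type is the reference genotype. The default
category multipliers (1.0, 1.2, 0.8, 1.2) emulate the qualitative pattern
the package reproduces: CI-driven ~20% increases in cycle re-entry, slowed
re-entry under isolated CIV deficiency, unchanged crypt cellularity. Every
run writes a manifest (config hash, seed, library versions, record counts)
and contains no timestamps, so reruns are byte-identical.
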