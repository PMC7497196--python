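# Methods

## The measurement problem and the model

Maternal masses in this design come from photogrammetry: a morphometric
measurement extracted from photographs is mapped to mass through a linear
calibration against platform-weighed animals, so each maternal mass is a
point estimate with a prediction SE (typically ~15 kg on a ~450 kg
animal). Using such estimates directly as covariates attenuates the mass
coefficient toward zero, and using them inside ratio responses
contaminates the response too. The package therefore treats true masses
as latent.

Each observation carries latents `(M1_i, z_i)`: the true parturition mass
and the logit-scale latent response. The other occasion's true mass is
*derived* — `M3 = M1·(1−p)` for the proportion suite with
`p = logit⁻¹(z)`, and `M2 = M1 − pup_gain/e` for the efficiency suite with
`e = logit⁻¹(z)` — so the latent proportion/efficiency is in (0, 1) by
construction and the logit is never evaluated out of range. Raw
error-contaminated values may fall far outside (0, 1) (raw efficiencies
above 2 occur); the model attributes them to measurement error rather
than truncating them. A derived mid-lactation mass that would be
non-positive has zero density.

### The latent-mass population layer

`M1_i ~ Normal(μ_M, σ_M²)`, truncated to [100, 800] kg, with a flat
hyperprior on μ_M and U(0, 200) kg on σ_M. A *flat* latent prior was
considered and rejected: in the weaning suite the latent mass is then
informed only by its own estimate, the error-aware fit collapses onto the
naive fit, and attenuation is not corrected — the functional-model
pathology. The structural layer is also what the analysis design
describes: covariates are related to *true* maternal mass. σ_M is well
identified because the per-estimate SEs are known.

Observations whose SE is zero (platform-weighed) have their latent pinned
to the observed value; if every relevant SE is zero the latent response
is pinned too and the model degenerates to exact arithmetic on observed
values — this is the "naive" fit used in the attenuation contrast.

### Priors and bounds

Slope coefficients get U(−10, 10) on the logit suites and U(−30, 30) on
the weaning (kg) suite; random-effect and residual SDs get U(0, 50). The
*intercept* carries the response's mean level — ~99 kg for weaning — which
no ±30 bound can contain, so the intercept gets its own wide bound
(±1000). Residual σ uses the same U(0, 50) bound as the random-effect
SDs.

## Sampler

An adaptive Metropolis-within-Gibbs kernel targets the joint density
(`matalloc.model.log_joint`, kept as an explicit function and tested
against hand-summed fixtures):

- **β**: conditionally multivariate normal given the latents (the latent
  response is linear in β once `M1` fixes the mass column), drawn jointly
  by Cholesky; redrawn in the rare event a draw leaves its bounds.
- **u_year, u_ind**: conjugate normal, vectorized over levels.
- **σ_e, σ_year, σ_ind, σ_M and μ_M**: with uniform priors on SDs the
  variance conditionals are inverse-gamma (drawn exactly, redrawn while
  out of bounds); μ_M is conjugate normal.
- **latents (M1_i, z_i)**: per-observation random-walk Metropolis,
  vectorized across observations (conditionally independent), with
  per-coordinate proposal scales adapted toward 0.44 acceptance during
  burn-in only.

Chains are seeded via `numpy` `SeedSequence` spawning, so identical
settings reproduce draws bit-for-bit. Default chain lengths per suite
follow the production protocol (weaning 40k after 20k burn-in; proportion
70k after 30k; efficiency 250k after a 300k burn-in — the efficiency
burn-in really does exceed its retained length); an `McmcSettings.scale`
factor divides the lengths for desk-scale runs, and every test and the
acceptance script state their scaled sizes explicitly. Convergence is
gated on PSRF < 1.1 for all monitored parameters; Geweke z-scores are
always reported but only gate runs with ≥ 2000 retained draws, because
the spectral variance estimate (Bartlett window, 10% of segment) is
unreliable on shorter segments. Variance-component chains (especially
σ_ind, identified by few repeat mothers) mix slowest; they dominate
desk-scale Geweke scores.

## Leave-one-out selection

A candidate's score is the sum of log conditional predictive ordinates:
per observation, a single warm-started chain refits the model with that
observation's likelihood contribution omitted, and the held-out
predictive density is averaged over refit draws by log-mean-exp. Omission
units: the proportion suite omits the observation's parturition and
late-lactation maternal mass estimates *simultaneously* (its latent logit
response then integrates to one, so the pair omission is implemented as
dropping the row's every likelihood term — an exact equivalence, not an
approximation); the efficiency suite analogously omits the parturition
and mid-lactation pair; the weaning suite omits only the weaning-mass
response, so the parturition estimate still informs the latent covariate.
Held-out densities integrate the latent mass analytically-in-form: the
structural layer times the (omitted or retained) estimate density is
normal, so inner Monte-Carlo draws of `M1*` (and `z*` for the logit
suites) average the omitted densities exactly.

Per-unit refits share nothing, are seeded by (seed, unit index), and
merge by index, so results are independent of execution order. The pair
comparison is a z-test on per-observation log-CPO differences,
`z = mean(d)·√n / sd(d)` (identical vectors return z = 0, p = 1 by
convention); the per-observation paired variance is one of several
defensible estimates for a ΔBPIC test and is this package's choice.
A harmonic-mean importance-sampling approximation from full-fit draws is
available for speed but is never the reference path.

The machinery is written against a minimal protocol (`n_units`,
`refit_without`, `heldout_logdensity`) so the parameter-free
fixed-density oracle (BPIC equals the exact summed log density to
machine precision) and the conjugate normal-mean oracle (closed-form LOO
predictive) exercise the same code path as the allocation models.

## Diagnostics

- **PSRF**: classic between/within variance ratio; constant chains are
  flagged NaN, not raised; values slightly below 1 are reported as-is.
- **Geweke**: first 10% vs last 50% segment means over spectral SEs.
- **HDI**: shortest contiguous window of the sorted draws containing
  ⌈mass·n⌉ draws; ties break to the lowest starting index. Tested against
  an exhaustive window scan on every fixture up to 200 draws.
- **Ordered-z discrepancy**: per posterior draw, sorted standardized
  residuals of the observed responses (the latent logit responses for the
  logit suites) and of a replicated dataset are each compared with Blom
  expected normal order statistics; `T = Σ(z_(i) − m_i)²` and the
  Bayesian p is `Pr(T_rep ≥ T_obs)`. Using Blom expected order
  statistics as the reference points is this package's design choice.
  σ_e = 0 replicates are flagged degenerate.

## Synthetic colony generator

The generator is the study conditions, not a dial. Demography: 362
mothers over 15 seasons; a mother's observed seasons follow a geometric
continuation (repeat probability 0.36, consecutive-year probability 0.8),
back-solved once from the repeated-measures profile (249/74/26/13 mothers
with 1/2/3/4+ seasons) and the ~531-observation total; 40% of mothers are
first observed at their first reproduction (age = AFR, prebreeder-last-
year status), the rest enter with a negative-binomial experience gap.
AFR is drawn on ages 4–14 with mean ≈ 8.4; resulting observed ages
average ≈ 14 and reach the low 30s.

Truth: parturition mass ~ Normal(450, 55) kg; pup birth mass ~
Normal(29, 5) kg; birthdate an integer day-of-season ~ Normal(27, 7) (day
27 ≈ 27 October); day offsets uniform in the 1–4 / 15–25 / 30–40 windows.
True coefficient defaults are the study-scale posterior means for each
suite (quadratic age for proportion and efficiency, logarithmic for
weaning); random-effect SDs are set near the reported estimates, and
residual SDs (0.15 / 0.35 logit, 12 kg) were chosen once to reproduce the
raw response spreads. The day-20 true mass interpolates linearly in
measurement days between the parturition and late-lactation truth. A
weaning draw below the mid-lactation pup mass (biologically impossible)
triggers a bounded joint redraw of the efficiency and weaning residuals;
this truncation is negligible at the defaults but means extreme
efficiency configurations are mildly right-truncated. Measurement error
adds Normal(0, 15 kg) to maternal masses (the SE the pipeline reads);
pup platform masses are error-free by default.

What the generator does *not* emulate: environmental covariates beyond
the year effect, within-season mass-loss nonlinearity, state-dependent
sampling effort, heteroscedastic photogrammetric SEs (every estimate
shares one SE), and any demographic feedback. Passing tests therefore
validate the estimation machinery under the assumed error model, not the
biology of any particular colony.

## Known numerical behaviour and limitations

- For the *proportion* response, parturition-mass error enters both the
  covariate and the response ((m1−m3)/m1), producing a shared-error
  *upward* bias in a naive fit rather than classical attenuation; the
  attenuation demonstration therefore uses the weaning suite, where the
  error is purely covariate-side.
- The efficiency suite's intercept shows a small upward bias (~+0.1 on
  the logit scale at desk scale) relative to generative truth: with
  ~15-kg errors on an early-lactation loss of ~80 kg, the nonlinear map
  from latent efficiency to the observed mid-lactation mass makes the
  latent posterior right-skewed. This mirrors the suite's slow production
  chain lengths and is documented rather than corrected.
- Raw transfer-efficiency summaries are ratio statistics and inherit a
  positive bias from noise in the denominator; colony summary checks use
  the generator's true efficiencies.
- Coverage experiments pass the generator's own standardization into the
  fit so "true coefficient" is defined on the exact scale being
  estimated; with the default raw-estimate standardization the mass
  coefficient's scale differs by the ratio of raw to true mass SDs
  (~3–4%).
- Desk-scale suite runs can flag candidates non-converged; `run_suite`
  excludes them from selection with a warning rather than failing, and
  refuses only when no candidate converges.
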