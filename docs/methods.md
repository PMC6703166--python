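# Methods

This note documents the model as implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Model and likelihood

Patient-year outcomes are Gaussian within clinic-year with a clinic-specific
variance shared by the two years; the clinic-level baseline mean and mean
change follow two linear models on the same design, each with a system-level
random effect (see README for the display).  The joint density factorises into

1. patient-outcome factors — entered through per-clinic-year sufficient
   statistics (n, Σy, Σy²), never raw rows;
2. the two clinic-level regressions, N(mu^diff | XΘ + ψ_s, τ²) and
   N(mu(2009) | XΘ~ + υ_s, λ²);
3. system-effect priors ψ_s ~ N(0, ζ²), υ_s ~ N(0, ω²);
4. optional covariate-measurement factors: Bin(x.comm | n, θ),
   Bin(x.fem | n, γ), Bin(x.ivd | n, κ), N(age-bar | η, σ²_age / n), one
   (θ, γ, κ, η) per clinic-year and one σ²_age per clinic.

Clinic scores and the neighborhood (ACS) covariates are treated as fixed; they
are not patient-level measurements.

## Priors

* σ²_sj and σ²_sj,age: a single inverse-gamma prior per outcome, empirically
  Bayes: shape/scale moment-matched to the mean and (n−1)-denominator variance
  of the per-clinic sample variances (a = E²/V + 2 guarantees a > 2, so the
  prior variance is finite and the match is exact in closed form).  The
  package pools each clinic's two years (df n09 + n12 − 2) to form the input
  sample variances.  Sensitivity variant: multiply V by a constant
  (`ig_variance_multiplier`, e.g. 4) before matching.
* Proportions θ, γ, κ: uniform Beta(1,1); Jeffreys Beta(½,½) variant.
* η and the coefficient vectors: flat.  A Gaussian ridge on Θ/Θ~
  (`coef_prior_precision`) exists because the coefficient update is derived in
  general prior form; the default 0 is the non-informative setting.  The
  proper option is what makes the Geweke joint-consistency test possible.
* τ², λ², ζ², ω²: log-uniform π(v) ∝ 1/v (improper), full conditional
  IG(k/2, SS/2).  A proper IG(a₀, b₀) alternative (`variance_prior =
  "inverse_gamma"`) is available; log-uniform is its a₀ = b₀ = 0 limit.
  Posterior propriety under the improper defaults is the user's
  responsibility; the sampler guards the known failure modes (below).

## Gibbs sampler

Update order per sweep: covariate latents (and latent design columns) →
(mu2009, mu^diff) jointly per clinic (closed-form bivariate normal) → σ² →
Θ marginally over ψ → ψ → Θ~ marginally over υ → υ → (τ², λ², ζ², ω²).

* The marginal coefficient draw uses the Woodbury identity on
  Σ = τ²I + ζ²ZZᵀ, so no dense covariance is ever formed; drawing (Θ, ψ) as
  p(Θ | mu^diff) p(ψ | Θ, mu^diff) is an exact joint conditional draw, so the
  partially collapsed ordering is a valid Gibbs scheme.  `collapsed=False`
  conditions on ψ instead (required under the flat system-effect prior, where
  the marginalisation does not exist).
* Measurement feedback.  Default is **cut feedback**: latents are drawn from
  their own conjugate measurement posteriors each sweep and the latent design
  columns rebuilt — pure Gibbs, and the regression never feeds back into the
  measurement model.  The **full-feedback** variant adds the regression
  factors to the latents' targets via random-walk Metropolis (logit scale for
  proportions, with the change-of-variables Jacobian; natural scale for η;
  both years proposed jointly per clinic).  Its kernel is validated against a
  single-clinic grid posterior.  Caveat: with few clinics the joint posterior
  of (latent diffs, their coefficient) is ridge-shaped and the variant mixes
  poorly — posterior summaries can differ wildly across seeds at J ≈ 16.  Cut
  feedback is the default for this reason as well as for interpretability.
* All draws come from one seeded `numpy` Generator in a fixed order; runs are
  bit-reproducible from (config, seed).
* Simulation-study fits can pin σ², τ², λ² at known design values
  (`fix_sigma2` etc.); the replicate studies use this because their generating
  variances are part of the study design (see below).

Degenerate-input guards: variance full-conditional scales below 1e−12 are
floored (warned); a variance draw with zero residual count under an improper
prior holds its value (warned); any hierarchical variance exceeding 1e12
aborts the run (divergence guard).  With a single system and log-uniform ζ²
the funnel can drive ζ² to the floor repeatedly — expected improper-prior
behaviour, logged not hidden.

## Credible intervals and DIC

Equal-tail intervals use linear-interpolation (type-7) empirical quantiles of
the retained chain.

DIC = D̄ + p_D with p_D = D̄ − D(posterior-mean parameters).  The deviance
treats the latent clinic means *and the system effects* as parameters: it sums
the patient-outcome factors, the two clinic-level regression factors and (when
active) the measurement factors, and **excludes** the N(ψ|0, ζ²) N(υ|0, ω²)
prior densities.  Including them makes DIC useless for column selection under
the log-uniform ζ²/ω² priors: the funnel's log ζ² excursions dominate the
deviance and the comparison, to the point that a candidate column with a true
coefficient of 2.5 was not favored.  With the focus used here the same
comparison is stable to ±2 across chain seeds and cleanly separates signal
from pure-noise columns.  D(·) at the posterior mean rebuilds latent design
columns at the latent posterior means.

Forward selection starts from the mandatory [1, c^diff]; candidates are
screened by single-addition DIC reduction, added cumulatively in sorted order
(ties broken by input order), and the first non-strict reduction stops the
procedure.  Selection chains default to 20,000 draws (2,000 burn-in) with a
fixed per-step seed schedule.  Baseline and change models always share the
selected set.

## Exclusion filters and summaries

Patient-year rows are excluded, in a fixed precedence giving a one-reason-per
-record additive log: invalid measurement date; A1c outside [3, 25] %; LDL
outside [0, 1000] mg/dL; SBP < 50 mmHg or below DBP; Type 1 diabetes.  Range
endpoints are kept ("outside the range" reads as strict violation); missing
values pass range rules vacuously (missingness is carried by the date-validity
flags); a record violating several rules counts once under the first.
Clinics need both years with at least `min_n` (default 30) patient-years each;
otherwise the whole clinic is dropped and logged.  Sample variances use n − 1.

## Synthetic generators — what they emulate

* `generate_bias_study_data`: J = 100 clinics × I = 10 patients per year, four
  iid N(0,1) clinic covariates, Θ = [0, 0, 0.5, 1, 0] and Θ~ = [0, 1, 0.5, 0,
  0] on [1, X1..X4], unit noise everywhere, no system effects.  Fits pin
  σ² = τ² = λ² = 1 — the generating values are part of the study design, and
  estimating λ² instead would let an inflated baseline variance absorb the
  omitted-predictor signal and roughly halve the MS1 bias being measured.
* `generate_coverage_study_data`: the hierarchical cascade with
  υ_s, ψ_s ~ N(0,1), Θ = [0, 1, 0.5] on [c^diff, X1, X2],
  Θ~ = [0, 0, 0.5], X1 = 0.1·c^diff + N(0,1) (the dynamic confounder), true
  alpha = 0, and per-clinic patient draws both years.  The original experiment
  reused real clinic sizes and scores, which are not available; the stand-in
  design uses 100 clinics in 10 equal systems, per-year sizes
  round(lognormal(log 60, 0.5)) ≥ 2 and c^diff ~ N(0, 7²).  The c^diff scale
  was fixed a priori so the confounded marginal correlation between clinic
  mean change and c^diff is ≈ 0.35 — the magnitude of the spurious signal the
  study exhibits; the ad-hoc rejection rate is therefore reproduced
  qualitatively (high), not as a printed number.  Coverage fits estimate all
  variances (they exercise the full proposed model).
* `generate_full_hierarchy`: a registry-shaped patients.csv/scores.csv pair —
  binomial insurance/sex/IVD flags and Gaussian ages from clinic-year latents,
  A1c-scale outcomes from the hierarchical cascade, clinic-level neighborhood
  scores with patient jitter, independent year samples (patients unmatched by
  construction), and an optional fraction of filter-violating rows.  Clean
  rows are clipped inside the registry-valid ranges so that
  `violation_fraction=0` means the filters remove nothing.

None of the generators emulate: survey item-level structure behind the clinic
scores, real ACS geography, informative clinic dropout, non-Gaussian outcome
tails, or patient-level correlation across years (the model never uses it).
Passing tests on these generators therefore demonstrate correctness of the
inferential machinery under the model's own assumptions, not robustness to
real-registry misspecification.

## Study defaults

Desk-scale replicate-study settings: bias study 500–600 replicates × 2,000-draw
chains (200 burn-in); coverage study 200–1,000 replicates at the same chain
length (the top of each range is what `scripts/acceptance.py` runs; a 1,500-
replicate calibration run measured the CI non-coverage rate at 5.3% ± 0.6).  The full-scale analogues (10,000 replicates / 10,000 draws; 1,000
replicates; T = 100,000 with 10,000 burn-in for a single data analysis) are
plain arguments.  Chain-length sensitivity was checked on the coverage study:
at 2,000 draws the CI-endpoint Monte-Carlo error adds ≈ 1 point of apparent
non-coverage versus 4,000-draw chains, well inside the binomial error at these
replicate counts.

## Known limitations

* Improper-prior posteriors are not certified proper; the guards above make
  failures loud rather than impossible.
* Single-chain diagnostics only (by design); no R̂ across chains.
* The DIC focus excludes the system-effect prior factors (rationale above);
  users wanting the textbook full-joint deviance can evaluate
  `log_joint_likelihood` with `hierarchical_system_prior=True` themselves.
* Full-feedback measurement updates are provided but weakly identified at
  small J (see above).
* The three outcomes are fitted independently; no cross-outcome correlation.
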