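# Methods

## Model

`aortaforecast` implements a multivariate linear mixed model for serial CMR
measurements of the thoracic aorta in adult women with Turner syndrome.
For subject *i*, visit *t* (equally spaced, ~2.4 years apart) and
measurement position *j* (nine anatomical landmarks from the aortic sinus
to the distal descending aorta),

    log d_itj = x_it' beta_j + e_itj ,

where `d` is the diameter in mm and `x_it` holds the risk factors: aortic
coarctation, age, bicuspid aortic valve (BAV), antihypertensive treatment,
24-h diastolic ambulatory blood pressure, body surface area (BSA), duration
of oestrogen replacement therapy (ERT), 45,X karyotype, and elongated
transverse arch.  Each covariate enters with position-specific coefficients
(a 9-vector) unless constrained to a shared slope.

The residual field is Kronecker-separable plus measurement noise:

    Cov(e_itj, e_isk) = rho^|t-s| * Sigma_jk + 1{t=s, j=k} * sigma2_j ,

i.e. an unstructured 9x9 spatial covariance `Sigma` between positions, a
first-order autoregression with coefficient `rho` over visits, and
independent position-specific measurement-error variances `sigma2_j`.
Stacked visit-major, the marginal covariance of a subject's full vector is
`R(rho) ⊗ Sigma + I_T ⊗ diag(sigma2)`.

Key assumptions: a constant inter-visit interval (`rho` is *per visit
interval*, not per year — forecasts therefore step on the fitted visit
grid, and unequally spaced requests are rejected); a single `rho` common to
all positions; log-normal diameters; dropout that is missing at random and
monotone.

Identifiability: `Sigma_jj` and `sigma2_j` are separated only through the
temporal correlation, so fitting requires at least two visits (enforced
with an explicit error) and degenerates to a likelihood ridge as
`rho -> 0`; see "Optimization" below.

## Estimation

The fixed effects are profiled out by generalized least squares, leaving
the covariance parameters (45 Cholesky entries of `Sigma`, `z = atanh(rho)`,
9 log error variances) to numerical optimization of the REML criterion
(ML available; likelihood-ratio comparisons of fixed-effect structures
always refit under ML).  Subjects are grouped by missingness pattern so
each distinct observed covariance sub-matrix is factorized once per
evaluation; gradients are exact, computed by trace contractions of the
per-pattern inverse/residual/projection matrices against the derivative
directions `dGamma/dtheta_k`.

**Parameterization.** The public round-trip transform is log-Cholesky for
`Sigma`, Fisher-z for `rho`, and log for `sigma2` (floored at 1e-10 so an
exactly-zero error variance is representable).  Internally the optimizer
uses a *raw* Cholesky diagonal box-bounded at zero instead of the log: when
the temporal signal is weak, REML legitimately places the optimum at or
near a singular `Sigma` (the spatial-variance/measurement-error split is
then unidentified), and a log diagonal puts that boundary at minus
infinity, which manifests as an interminable curved-valley crawl.  With the
raw diagonal the boundary is an ordinary box face (the same device lme4
uses).

**Optimizer.** Levenberg–Marquardt-damped Fisher scoring (expected
information, Marquardt diagonal scaling, monotone by construction)
alternating with bounded L-BFGS-B polishing, multi-started from a
method-of-moments initialization: `Sigma` off-diagonals from the pooled
same-visit cross-position residual covariance, `rho` from lag-2/lag-1 (or
lag-1/lag-0) autocovariance trace ratios, diagonals from the lag-1
autocovariance, error variances from the remainder.

**Convergence.** Primary criterion: the information-scaled Newton decrement
`g' I^{-1} g / (1 + |loglik|)` restricted to the identifiable subspace
(eigenvalues above 1e-8 of the largest; KKT-projected at active bounds)
below `tol` (default 1e-8).  An absolute gradient-norm criterion is not
attainable here: with |REML| of order 5e3 the objective is only resolvable
to ~1e-12 relative, so line searches cannot certify descent below that.  On
ridge cases the decrement criterion itself is unattainable and the fit is
declared converged by relative-function stagnation (a full scoring+polish
round gains < 1e-7 relative while the decrement indicates a remaining gain
below ~2 log-likelihood units) — the analogue of lme4's boundary fits and
SAS's FCONV/GCONV fallbacks.  `diagnostics["converged_by"]` records which
criterion fired; the accepted log-likelihood path is monotone and recorded.

Typical behavior: calibrated-truth data (rho = 0.9, 150 subjects, 3 visits)
converge by decrement in ~7 scoring iterations (~0.3 s); rho = 0 ridge data
take ~10-20 s and finish by stagnation with `Sigma` at or near the singular
boundary.

**Uncertainty.** Wald intervals and joint chi-square tests use the GLS
coefficient covariance `(sum_i Z_i' Gamma_i^{-1} Z_i)^{-1}` at the
covariance-parameter estimates; no Kenward–Roger-style small-sample
correction is applied, and the position-uniformity test is an ML LRT
referred to chi-square with 8 df.  These are asymptotic conventions and
differ from the F tests with estimated denominator df that proprietary
mixed-model software reports; they agree asymptotically.

## Forecasting

The model is rewritten exactly as a linear-Gaussian state-space system
(state = the 9-vector of error-free log diameters; AR(1) transition with
innovation covariance `(1-rho^2) Sigma`; observation adds `diag(sigma2)`),
filtered over any prior measurements (missing positions handled by row
selection) and propagated to each requested horizon.  This equals exact
conditioning of the joint Gaussian on the observed entries; a dense
Schur-complement oracle is kept in the package and the equivalence is
asserted to 1e-8 over randomized instances in the test suite.

Prediction limits target the future *measurement* (they include
`sigma2_j`), because that is what a new CMR reading is compared against;
latent-scale limits are available via `target="latent"`.  Limits are
`exp(log-mean ± 1.96 log-SD)`, hence asymmetric in mm.  A measurement is
flagged only when *strictly* outside its limits.  Projected covariates
default to last-value-carried-forward with age and (when on ERT) ERT
duration advanced by the visit spacing.  When a subject has prior visits,
the filter conditions on all of them — the information-optimal choice under
the model.

## Synthetic cohort generator

The generator is the model run forward, emulating the study design: 102
subjects, 3 visits at 2.4-year spacing, and monotone MAR dropout at 10% per
post-baseline visit (the observed retention was 102 -> 80 -> 78).  Covariate
distributions are calibrated to the cohort's baseline table: age ~
N(38, 11) truncated at 18, BSA ~ N(1.5, 0.2) truncated above 1.0 with a
0.03 m² per-visit random walk, diastolic ABP ~ N(77, 11) with a 5 mmHg
random walk, BAV 25%, coarctation 12%, 45,X 58%, elongated arch 47%, ERT
86% (baseline duration Uniform(0, age-18), advancing with time), and
antihypertensive treatment 29% at baseline with a 20%/visit switch-on
probability (treatment only ever switches on; the cohort went 29% -> 55%).
Covariates are drawn independently of one another, since their joint
dependence is not reported.

The default "truth" uses the published position-specific coefficients.
The covariance components are not published and were calibrated once from
reported summaries:

* total marginal log-variance per position = `log(1 + CV^2)` from the
  baseline mean/SD table, minus the variance explained by the covariates
  under the distributions above (floored at 0.006);
* measurement-error SD 0.67 mm (from intra-observer Bland–Altman limits of
  about ±1.85 mm on a difference of two readings, /sqrt(2)/1.96), mapped to
  the log scale as `(0.67/mean_j)^2`;
* between-position correlation `0.85^|j-k|` (anatomically adjacent
  positions strongly correlated, decaying along the aorta);
* `rho = 0.9` per 2.4-year interval: aortic calibre is a highly persistent
  individual trait, but not perfectly so over years.

Intercepts are solved so that the model's baseline *arithmetic* mean
diameter at the covariate means (including the lognormal `v/2` correction)
reproduces the cohort's baseline means; with these defaults the simulated
baseline means and SDs match the reported table to ~0.1 mm.

What the generator does **not** emulate: informative dropout (the study
itself treats loss to follow-up as MAR), covariate co-occurrence (e.g.
BAV–coarctation association), visit-time jitter, non-lognormal tails, and
scanner drift.  Passing tests therefore validate the estimator and
forecaster *under the model's own assumptions*, not robustness to their
violation.

## Simulation study sizes

The packaged statistical checks use: 50 randomized small instances for the
likelihood and forecast oracles (tolerance 1e-8); 200 replicates of 150
subjects x 3 complete visits for interval coverage (band 90–98%) and rho
bias (< 0.03); 2000 subject-forecasts for 95%-limit calibration (band
93–97%, per-position flag rate 3–7%); and 500 replicates of 200 subjects
with a null covariate for Wald type-I error (band 3–8% at alpha = 0.05) —
the null simulation uses a reduced model (intercept, age, and the null
indicator) and a cohort size where the asymptotic Wald reference is
adequate.

## Numerical conventions

* Stacked vectors are visit-major (visit 1 positions 1–9, then visit 2 …).
* Visit indices are 1-based, matching baseline / follow-up / end-of-study
  naming; `years_from_baseline = (visit-1) * spacing`.
* Ties at a prediction limit are not flagged (strict inequality).
* Reporting units for percent changes: diastolic ABP per 10 mmHg, BSA per
  0.1 m², all other covariates per natural unit; percent changes are
  computed from unrounded coefficients.
* CSV artifacts carry a schema tag comment and round-trip floats bit-
  exactly (`%.17g` out, `float_precision="round_trip"` in).
* Paired t-tests in the descriptives use complete cases (subjects observed
  at both visits).

## Known limitations

* No continuous-time autoregression: unequally spaced visits are rejected
  rather than approximated.
* A single temporal correlation parameter is shared by all nine positions.
* Wald/LRT inference is asymptotic; at small cohort sizes the joint tests
  run slightly liberal.
* The fitted measurement-error variances are weakly identified when the
  temporal correlation is near zero (ridge); estimates of `rho` and the
  fixed effects remain well behaved there, but the `Sigma`/`sigma2` split
  should not be interpreted.
* No dissection-risk model: the package predicts diameters, not events.
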