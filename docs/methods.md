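# Methods

This note documents the models and procedures implemented in `renalpanel`,
the default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter.

## Renal phenotypes

eGFR is computed from serum creatinine with the CKD-EPI 2009 equation,

eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female],

with κ = 0.7/0.9 and α = −0.329/−0.411 for females/males. No race
coefficient is applied (the cohorts this pipeline targets are analysed
without one); creatinine is accepted in µmol/l (divided by 88.4) or mg/dl.
Readings flagged as concurrent with a hospital admission are excluded before
any derivation, since acute illness transiently inflates creatinine.

*Weighted historical eGFR* summarises the retrospective record with weights
decreasing in the time Δt (years) before the biosample date. The functional
form is a design choice (only "inversely related" is implied by the
phenotype definition); the default is w = 1/(1 + Δt), with an exponential
alternative w = exp(−Δt/2) available via `weight="exponential"`. A
participant with no retrospective data has the historical eGFR imputed to
the study-day value.

*Final eGFR* is the median over the closed window of the last 182 days
("6 months") of follow-up. Initiation of renal replacement therapy is coded
as an achieved eGFR of 10: later readings are censored and a reading of 10
enters the window at the RRT date. The *prospective slope* is the ordinary
least-squares slope of eGFR on time; it is undefined (flagged) with fewer
than two distinct dates. *Progression* to below 30 or 45 is defined only for
participants at or above the threshold at study day.

*Albuminuric status* uses ACR bands [0, 3.39), [3.39, 33.9], (33.9, ∞)
mg/mmol (normo/micro/macro; boundary values resolve to the band of higher
concern at 3.39 and to micro at 33.9). A stage transition is discarded as
transient when a measurement of the prior stage occurs within 90 days before
or after it. Baseline status applies a two-out-of-three rule to the last
three pre-baseline measurements, falling back to the most recent durable
stage when no two of the three agree (the exact scope of the rule is
underdetermined; this resolution is idempotent on durable series and is
property-tested). Incident albuminuria is a durable micro/macro episode
beginning after the study day in a participant normoalbuminuric at baseline.

## Biomarker QC

Reproducibility is quantified by the one-way random-effects intraclass
correlation ICC(1,1) = (MSB − MSW)/(MSB + MSW) over blinded duplicate
aliquots (the estimator is a design choice; no specific estimator is implied
by the exclusion rule). Because assay readings are right-skewed, the ICC is
computed on log readings. Markers are excluded when ICC < 0.4 or when more
than 99% of readings are identical — the latter rule is evaluated *after*
imputation of below-detection-limit readings to LOD/2, which is what makes
an almost-entirely-censored marker constant. The processing order is fixed
and tested: LOD imputation → urinary-creatinine normalisation (urine markers
only) → Gaussianisation. Gaussianisation is the rank-based inverse-normal
transform with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)), ties averaged,
then exact centring and scaling; it is monotone in the input and makes
per-SD regression coefficients comparable across skewed analytes.

## Hierarchical-shrinkage panel model

Clinical covariates b receive N(0, 2²) priors on standardized inputs (weakly
informative, ridge-like; binary covariates are standardized like continuous
ones so the prior scale is comparable). Biomarker coefficients receive the
regularised horseshoe: β_j = z_j τ λ̃_j with λ̃_j² = c²λ_j²/(c² + τ²λ_j²),
z_j ~ N(0,1), λ_j ~ half-Cauchy(0,1), τ ~ half-Cauchy(0, τ₀), and slab
c² ~ Inv-Gamma(ν/2, νs²/2) with s = 2, ν = 4. The global scale default is
τ₀ = p₀/(p − p₀)·σ̂/√n with a prior guess of p₀ = 2 relevant biomarkers
(σ̂ = sd(y) for the linear family, 2 for logistic). These hyperparameters
follow the standard regularised-horseshoe construction and are all exposed
in `ShrinkagePrior`. The linear family adds σ ~ half-Cauchy(0, 5); the
intercept prior is N(0, 10²).

Sampling is by a No-U-Turn sampler implemented in `renalpanel.sampler`
(tree-doubling with slice sampling, dual-averaging step-size adaptation to a
0.95 target acceptance, and a diagonal mass matrix estimated during warmup).
Local and global scales are sampled on the log scale with the non-centred
parameterisation of β, which removes most of the funnel geometry; gradients
are analytic and verified against finite differences in the test suite.
Defaults are 4 chains × 500 warmup + 250 draws (≥ 1000 post-warmup draws
total for reported fits). Fits are flagged when split-R̂ > 1.05 on any
reported parameter or when more than 1% of post-warmup transitions diverge
(energy error > 1000 in the unconstrained space). On heavy-tailed horseshoe
posteriors a divergence rate slightly above zero is common and the flag is
deliberately conservative.

With zero biomarker columns the model degenerates to Gaussian-prior (ridge)
regression on the covariates, which the tests compare against the conjugate
closed form; with τ₀ and c large the posterior mean approaches the
unpenalised maximum-likelihood fit.

## Cross-validated evaluation

Models are compared on withdrawn data by tenfold cross-validation (folds
stratified by event status for binary outcomes — at the rare-event rates
this pipeline targets, unstratified folds can contain no events). Pointwise
test log-likelihoods are log posterior-predictive densities,
log mean_s p(y_i | θ_s); ΔLoglik is their sum minus that of the
covariate-only reference on the same folds. r² is the squared Pearson
correlation between observed and predicted outcome over all test folds. AUC
is the normalized Mann–Whitney U (ties count ½), cross-checked against an
independent implementation. The expected information for discrimination Λ
uses the plug-in estimator of the mean weight of evidence,

W_i = log₂[p_i/(1 − p_i)] − log₂[π/(1 − π)],  Λ = ½[mean(W|cases) + mean(−W|controls)],

with π defaulting to the observed event fraction and probabilities clipped
to [10⁻⁶, 1 − 10⁻⁶] (a density-smoothed variant exists in the literature;
the plug-in mean is used here and the choice is visible in the API). The
biomarker gain is the difference of Λ between the biomarker and
covariate-only models on the same folds. 95% uncertainty intervals for
r²/AUC are percentile intervals of the metric across (thinned)
posterior-draw predictions.

## Projection predictive selection

Per posterior draw, the full model's linear predictor f is projected onto
the submodel design D = [1, covariates, selected biomarkers]: linear family
by least squares with projected variance σ_s² = σ² + mean squared
discrepancy and Gaussian KL averaged over observations; logistic family by
iteratively reweighted least squares on the full model's fitted
probabilities (tolerance 10⁻⁸, max 100 iterations) with mean Bernoulli KL.
The reported KL is the mean over a thinned set of draws (default 400; the
thinning seed is an argument). Forward selection greedily adds the biomarker
minimising KL, ties broken by column order. Relative explanatory power of a
panel of size k is 1 − KL_k/KL_0 with KL_0 the covariate-only projection, so
the empty panel scores 0 and the full panel scores 1 exactly (the identity
projection has KL 0 to solver tolerance). Normalising against the
covariate-only rather than the null model is a design choice: it measures
the biomarkers' contribution on top of the clinical information, which is
the question the selection answers. Greedy selection is not guaranteed
optimal in general; on small instances (p ≤ 8) the tests compare the first
greedy pick against exhaustive singleton search.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real cohort's values:

- **Markers**: jointly log-normal in four correlation clusters
  (within-cluster r = 0.5, cross-cluster 0.05 by default) with one
  TNF-family pair at r = 0.80; per-marker log-means U(0, 3) and log-SDs
  U(0.4, 0.8).
- **Outcome construction**: latent final eGFR = baseline + s·(Σ e_j z_j + ε)
  with s = 12 (the outcome scale in ml/min/1.73 m²), ε ~ N(0, 0.5), and
  default effects e = −0.4 SD on two markers. A global downward drift is
  calibrated by bisection so the expected prevalence of progression to < 30
  among those at risk equals `progression_base_rate` (default 2.5%, the
  rare-event regime of the target design).
- **Creatinine series**: the CKD-EPI equation is inverted along the linear
  latent eGFR trajectory at Poisson-spaced visits (2.5/year over ~5.4
  retrospective and ~5.1 prospective years), with 5% multiplicative visit
  noise; ~2% of visits are flagged in-hospital and given an AKI-like
  creatinine spike so the exclusion rule is exercised. Trajectories reaching
  kidney failure trigger an RRT date at the eGFR-15 crossing.
- **ACR series**: log-normal around a person-level mean coupled to the
  standardized latent decline (coupling 0.8 on the log scale — the strength
  of this dependence is a free parameter, as nothing pins it down — plus
  person-level heterogeneity SD 1.2 and visit noise SD 0.35), yielding
  mostly normoalbuminuric cohorts with small micro/macro strata.
- **Assay artefacts**: per-marker detection limits at the 2% quantile with
  below-limit readings missing-coded; measurement error shared between
  primary and duplicate aliquots calibrated on the log scale to a target
  ICC of 0.9 on 48 duplicate participants.
- **Enrichment sampling**: independent Bernoulli inclusion with probability
  0.5 below eGFR 75 and 0.25 above, reproducing the eGFR-enriched two-strata
  design.

What it does **not** emulate: real covariate distributions beyond orders of
magnitude, assay-platform specifics, informative visit schedules (sicker
patients measured more often), non-linear eGFR trajectories, and
between-marker effects on ACR other than through the shared latent decline.
Passing tests therefore demonstrate the statistical machinery — phenotype
derivation, QC rules, shrinkage, selection, and metric estimation — under
the assumed structure, not clinical validity on real data.

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use n = 800 participants with 20 markers and two
true effects of 0.4 SD magnitude; the expected regression-scale
coefficients account for assay measurement error analytically
(β_limit = [icc·R + (1−icc)I]⁻¹ √icc·R·e, scaled to the standardized
outcome). Cross-validated comparisons use n = 400 (linear) and n = 500 with
a 12% event rate (binary — the default 2.5% rate would leave ~1 event per
fold at this n) with 4+4 markers and 2 chains × 150 draws per refit. These
sizes were chosen once as the smallest at which the expected behaviour is
comfortably outside Monte-Carlo noise.

## Known limitations

- The NUTS implementation is single-threaded and runs chains sequentially;
  very large panels (hundreds of biomarkers) would need longer warmup and
  possibly higher target acceptance.
- Logistic-family projection uses fractional-response IRLS per draw, which
  is exact for the KL objective but slower than the linear closed form.
- Complete-case analysis throughout; no multiple imputation.
- The Λ estimator is the plug-in mean; with very small event counts it is
  noisy, and no smoothing is applied.
- `albuminuria_status` requires at least one pre-baseline ACR measurement;
  cohorts without retrospective ACR need the baseline stage supplied
  externally.
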