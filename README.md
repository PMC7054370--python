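# renalpanel

Biomarker-panel modelling of renal function decline in type 1 diabetes.

`renalpanel` is a reusable, tested implementation of an analysis pipeline for
studies that ask whether a panel of serum or urinary biomarkers improves the
prediction of future kidney function — the achieved (final) eGFR and
clinically significant progression to eGFR < 30 or < 45 ml/min/1.73 m² —
beyond routine clinical data and the urinary albumin/creatinine ratio (ACR).
It is aimed at biostatisticians and epidemiologists working with longitudinal
clinical-record cohorts, and ships a seeded synthetic-cohort generator so the
entire pipeline is exercisable and testable without access to individual-level
patient data.

## What it computes

**Renal phenotypes.** eGFR from serum creatinine via the CKD-EPI 2009
equation; a weighted average of historical (retrospective) eGFR with weights
decreasing in the time to the biosample date; final eGFR as the median of the
last 6 months of follow-up, with initiation of renal replacement therapy
coded as an achieved eGFR of 10 and later readings censored; the prospective
eGFR slope by per-person least squares; progression indicators to < 30 and
< 45; and albuminuric status from ACR bands 0–3.39 / 3.39–33.9 / > 33.9
mg/mmol with a 90-day transience rule and a two-out-of-three baseline rule.

**Biomarker QC.** One-way random-effects intraclass correlation, ICC(1,1), on
blinded duplicate aliquots; markers excluded when ICC < 0.4 or when > 99% of
readings are identical; below-detection-limit readings imputed to half the
detection limit; urine markers normalised to urinary creatinine; rank-based
inverse-normal (Blom) Gaussianisation; and the correlation matrix ordered by
average-linkage hierarchical clustering.

**Association and panel models.** Per-biomarker linear (final eGFR) and
logistic (progression) regressions under three covariate sets with
Bonferroni control (0.05/22 for the default panel), and a Bayesian
hierarchical-shrinkage panel model: clinical covariates *b* get a weakly
informative Gaussian prior, biomarker coefficients β get the regularised
horseshoe

    β_j = z_j τ λ̃_j,   λ̃_j² = c² λ_j² / (c² + τ² λ_j²),
    z_j ~ N(0,1),  λ_j ~ C⁺(0,1),  τ ~ C⁺(0, τ₀),  c² ~ Inv-Gamma(ν/2, νs²/2),

sampled with a built-in No-U-Turn sampler (analytic gradients, non-centred
parameterisation, diagonal mass adaptation, split-R̂/ESS diagnostics via
arviz).

**Evaluation and selection.** Tenfold (event-stratified) cross-validation
reporting ΔLoglik (summed out-of-fold log-likelihood difference against the
covariate-only model, nats), r² (squared Pearson correlation of observed and
predicted outcome), AUC (Mann–Whitney rank identity), and the expected
information for discrimination Λ in bits — the average of the mean weight of
evidence in cases and against controls. Parsimonious panels are found by
projection-predictive forward selection: posterior draws of the full model
are projected onto sparse submodels, ranked by Kullback–Leibler divergence,
and summarised as relative explanatory power 1 − KL_k/KL_0.

## Worked example

```python
import numpy as np
from renalpanel import (SimulationConfig, generate_cohort, derive_phenotypes,
                        run_qc, fit_shrinkage, ShrinkagePrior)
from renalpanel.pipeline import assemble_analysis_frame, design_matrices

cfg = SimulationConfig(n_participants=800, seed=20, n_serum_markers=9,
                       n_urine_markers=11,
                       true_effect_markers=((3, -0.4), (12, -0.4)))
participants, panel, truth = generate_cohort(cfg)
phenotypes = derive_phenotypes(participants)
report, markers = run_qc(panel)
frame = assemble_analysis_frame(participants, phenotypes, markers)
d, X_cov, X_bio = design_matrices(frame.dropna(subset=["final_egfr_std"]),
                                  "basic", report.included_names)
fit = fit_shrinkage(X_cov, X_bio, d["final_egfr_std"].to_numpy(), "linear",
                    ShrinkagePrior(), seed=21)
pm = fit.beta.mean(axis=0)
print("top markers:", np.argsort(-np.abs(pm))[:3], np.round(np.sort(-np.abs(pm))[:3], 3))
print("diagnostics:", {k: round(v, 4) for k, v in fit.diagnostics.items()})
```

prints (markers 3 and 12 carry the simulated effects; marker 9 is noise):

```
top markers: [12  3  9] [-0.217 -0.21  -0.078]
diagnostics: {'max_rhat': 1.0158, 'min_ess': 318.3073, 'divergence_rate': 0.014, 'tau0': 0.0039}
```

The two truly informative biomarkers have the largest posterior-mean
coefficients (−0.217 and −0.210 per SD of Gaussianised marker on the
standardized final-eGFR scale, matching the analytic errors-in-variables
limit of −0.217), while the 18 noise markers are shrunk towards zero by the
horseshoe.

The same analysis is available from the shell:

```bash
renalpanel run-all --seed 1 --outdir out --outcome final_egfr --covariates basic
```

which writes the cohort tables, `phenotypes.tsv`, `qc_report.json`, the
Table-2-shaped `univariate_associations.tsv`, `cv_performance.tsv`,
`selection_path.tsv` and a `manifest.json` with all seeds and output hashes.

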