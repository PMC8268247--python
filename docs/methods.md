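# Methods

This note documents the statistical model behind `metabodisc`, the choices
made where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Problem setting

A nested case–control metabolomics study measures a few hundred identified
plasma metabolites in participants sampled from a prospective cohort: cases
who later developed disease, and matched controls. Pooled-QC samples —
aliquots of a mixture of study plasma, injected repeatedly through the
analytical batch — carry purely experimental variation (instrument drift,
handling), since their biological content is constant. The analysis asks
(i) whether the multivariate metabolite profile discriminates future cases
from controls out of sample, and (ii) which metabolites carry the signal and
in which direction.

## Preprocessing chain

Order is fixed: impute → PQN → glog → autoscale → QC-correct. PQN needs
positive raw intensities, and autoscaling destroys the positivity glog relies
on, so glog must precede scaling; the QC correction operates in the scaled
space where PCA quality assessment is usually performed. The pipeline records
every learned parameter (rank, dilutions, λ, centers/scales, QC loadings) in
the result bundle.

**Imputation.** Missing entries are completed by iterative truncated SVD:
initialize at column means, alternate rank-k reconstruction with replacement
of the missing cells until the largest relative change is below `tol`
(default 1e-6, 200 iterations max). The rank k is picked by masking an extra
5% of *observed* cells (seeded), imputing at each k = 1..max_rank, and
minimizing held-out RMSE. Observed cells are never modified. This is the
SVD-iteration form of the "eigenvector" family of imputation methods; NIPALS
variants exist and equivalence with them is not claimed.

**PQN.** Dilution of sample i is the median over metabolites of
x_ij / ref_j. The reference spectrum is the per-metabolite median of the
pooled-QC rows when at least 5 QC samples exist (the least biased reference,
since QC intensity differences are purely experimental), else the study-sample
median. A key accuracy limit, visible in the generator's calibration below:
the log-scale standard error of the median quotient is roughly
σ_eff · √(1+(b−1)ρ) · 1.2533 / √m for m metabolites with per-metabolite
log-variation σ_eff in correlated blocks of size b, so dilution recovery
degrades with noisy or strongly co-regulated features.

**glog.** x ↦ log2((x + √(x²+λ))/2); strictly increasing for λ > 0, equal to
log2(x) at λ = 0. `auto` sets λ = (m/10)² with m the smallest positive entry,
a gentle regularization near the detection limit that leaves the bulk of the
dynamic range on an ordinary log2 scale. λ is recorded in provenance.

**Autoscaling.** Per-metabolite mean 0 / sample SD 1 (ddof 1). Centers and
scales are retained and re-applied to held-out samples; inside the MCCV loop
they are refit on each discovery split.

**Normality screen.** Shapiro–Wilk per metabolite, advisory only (reported,
never used to filter), since no downstream step requires marginal normality.

## QC-subspace correction

A PCA model with n_components = 2 (configurable) is fitted on the QC rows:
mean profile x̄_QC plus the leading right singular vectors P of the centered QC
matrix (sign fixed: largest-magnitude element positive). Every sample is then
projected orthogonally: x ↦ x − ((x − x̄_QC)·P)Pᵀ, for study and QC rows
alike. The projector is idempotent and removes exactly the variance of the
projected component (Pythagoras). Centering uses the QC mean, not the study
mean, because the subspace is estimated from — and anchored at — the QC model.

The correction is valid precisely when the experimental variability acts
identically on QC and study samples; the generator plants it that way. Its
accuracy is limited by high-dimensional PCA geometry: with ~46 QC samples in
214 dimensions, the angle between the fitted and true drift subspace has a
floor governed by the drift-to-noise eigenvalue ratio, so weak drift
(comparable to injection noise) cannot be sharply estimated no matter the
method.

## OPLS-DA

Binary y ∈ {0,1} is centered; per orthogonal component the current X yields
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, the orthogonal weight
w_o ∝ p − (wᵀp)w, scores t_o = Xw_o, loading p_o, and deflation
X ← X − t_o p_oᵀ; a single predictive component (w, t, p, c = yᵀt/tᵀt) is
fitted on the filtered X. R2Y = 1 − ‖y − tc‖²/‖y‖². By construction every
orthogonal score is uncorrelated with y. With n_orth = 0 the model is exactly
single-component PLS1 (checked against an independent NIPALS oracle).

Prediction removes the orthogonal components sequentially from the new sample,
then scores ŷ = t·c + ȳ; 0.5 thresholds the class for error-rate style
outputs (ROC outputs never threshold). y is coded {0,1} rather than ±1 so ŷ
reads as a probability-like quantity against 0.5.

**Q2.** 7-fold stratified CV (folds seeded; the fold count collapses to
leave-one-out when folds ≥ n); scaling is refit on each training fold so no
statistic leaks across the boundary. Q2 = 1 − PRESS/SS.

**Permutation check.** Q2 recomputed under random relabelings;
p = (1 + #{Q2_perm ≥ Q2_obs})/(1 + n_perm).

**Choosing n_orth.** Scan 0..max_orth (default 6), stop early when Q2 drops
by > 0.01, then take the most parsimonious count within 0.01 of the best Q2 —
a gain below CV noise does not justify an extra component. The study this
pipeline emulates settled on 4 orthogonal components for its own data; the
choice is data-driven and not portable, hence `auto` is the default.

## Monte-Carlo cross-validation

Per iteration (seed spawned from the master seed): stratified 70/30 split with
per-class floor rounding (146/272 → exactly 102/190 + 44/82), scaling and
OPLS-DA refit on discovery only, validation samples scored, AUROC recorded.
The default refits scaling per split (`preprocessing="discovery"`); a
`"global"` mode mimics analyses run on one pre-normalized matrix. The QC model
is not refit per split: the QC rows are outside the study split, so their
model is split-invariant. The full preprocessing chain (imputation, PQN) is
likewise fitted once on the whole table; only the supervised and
scale-sensitive steps are leakage-controlled. AUC uses the Mann–Whitney form
(ties ½); the DeLong 95% CI uses the variance of the placement values; Youden
J scans midpoints between adjacent distinct scores, ties broken toward higher
sensitivity.

## sPLS-DA

Y is a single centered dummy column. Each component's X-weight is
soft-thresholded at the (keep+1)-th largest |entry|, so exactly `keep`
variables are retained (the keepX convention — an order-statistic λ rather
than a continuous penalty path), then normalized; scores deflate both X and Y
by regression, making component scores mutually orthogonal. Defaults: 5
components × 15 variables, as fixed in the emulated analysis. Importance of a
variable is max over components of |weight| × the component's share of total
score variance; ties break toward earlier components, then lexicographic id.
The CV error rate uses repeated (5-fold × 10) stratified CV with a
nearest-class-centroid rule in score space — one of the cited method's
standard prediction rules; the emulated analysis does not name its rule.

## Association statistics

Welch (unequal-variance) t per metabolite — the safer default where the
original tool's pooling behavior is unknown — with Bonferroni adjustment
p_adj = min(1, m·p). Logistic regression is a single-predictor binomial GLM
fitted by IRLS (statsmodels; tol 1e-8, 50 iterations); OR = exp(β₁) with 95%
Wald CI. **Units:** the ORs are per 1 SD of the glog-transformed,
autoscaled metabolite level, since the pipeline feeds the fully processed
matrix to the models; this matters when comparing magnitudes across studies.
Complete or quasi-complete separation is detected (statsmodels'
perfect-separation signals plus a |β₁| divergence guard) and flagged rather
than reported as a huge OR. Models are unadjusted; matched-set conditional
logistic regression on the matching covariates is out of scope.

## Synthetic-data generator

Log-intensities are built additively: per-metabolite baseline location
(uniform on ln 8–13, i.e. a realistic dynamic range) + block-correlated
biological variation (blocks of 10 metabolites, correlation ρ) + case-only
group effects on the discriminant subset + rank-r nuisance (scores × unit-norm
loadings, applied to study *and* QC rows) + iid technical noise; raw intensity
is exp(log) × a log-normal per-sample dilution factor. QC rows are the pooled
mean profile (case/control mixture in cohort proportion) + nuisance + noise.
Missingness mixes completely-at-random and low-intensity-preferential
components (the latter standardized within metabolite, emulating
detection-limit censoring).

Defaults and rationale (all log-scale SDs):

| parameter | default | rationale |
|---|---|---|
| n_cases / n_controls | 146 / 272 | study dimensions |
| n_qc | 46 | one pooled-QC injection per ~10 study injections |
| n_metabolites | 214 | identified-metabolite panel size |
| effects | ±1.2 SD, 5 up / 5 down | single-marker AUC ≈ 0.80: moderate markers, strong panel |
| baseline_sd | 0.28 | inter-individual CV ≈ 29% |
| noise_sd | 0.05 | technical CV ≈ 5% (QC-grade LC-MS) |
| dilution_sd | 0.3 | typical plasma dilution spread |
| nuisance | rank 2, SD 1.0 | e-fold instrument drift across the batch |
| block_correlation | 0.1 | mild pathway co-regulation |
| missing_rate / mnar_weight | 0.05 / 0.5 | typical identified-panel missingness |

The variance parameters were calibrated jointly against the recovery
properties the suite asserts: PQN dilution recovery r ≥ 0.99 at m = 214 bounds
σ_eff·√(1+(b−1)ρ) ≤ ~0.5 (the PQN median-SE formula above), and a residual
drift correlation ≤ 0.05 after 2-PC QC correction requires drift well above
technical noise (the PCA spike-ratio floor). The defaults satisfy both bounds
while staying inside plausible plasma-LC-MS ranges.

`planted_auc` gives the normal-theory AUC of the best single marker,
Φ(|e| / √2 / √(1 + noise_sd²/baseline_sd²)), assuming dilution and drift have
been removed — it calibrates post-correction recovery tests.

**What the synthetic tests do not show.** The generator is log-additive and
homoscedastic within metabolite; real LC-MS data carry intensity-dependent
noise, retention-time-localized drift, batch steps, correlated missingness
between co-eluting features, and matched-design structure (matching covariates
are deliberately not simulated — the matched design enters only through the
labels). Passing recovery tests therefore demonstrates correctness of the
algorithms under their stated assumptions, not performance claims about any
real cohort; in particular the real study's headline AUROC is not a
reproduction target here.

## Numerical choices

- All randomness flows from one master seed through stage-name-keyed SHA-256
  derivation (`derive_seed`), so every stage is independently reproducible and
  reruns are bit-identical.
- MCCV iteration seeds come from `SeedSequence.spawn`, keeping the 1000
  iterations independent and individually replayable.
- Degenerate cases are errors, not silent results: one-class labels,
  zero-variance columns, non-positive PQN references, all-missing columns,
  perfect separation, too few QC samples.
- Stratified folds are redrawn (up to 100 times, seeded) if a training fold
  loses a class; doubly-constant t-tests fall back to an exact-equality rule.
- Problem sizes in the test and acceptance suites: recovery medians over 20
  cohorts of 418 × 214; null calibration with 50 permuted-label Q2 replicates
  and 100 null FWER replicates; MCCV summarized at 100 iterations (the
  package default remains 1000).

## Known limitations

- No run-order (LOESS/spline) drift correction; the QC correction is a global
  subspace model, blind to smooth time trends orthogonal to its components
  only in expectation.
- No multi-class OPLS-DA, no O2PLS, no CV tuning of the sPLS-DA geometry
  (components/keep are fixed by design).
- Internal-standard-based normalization is not modelled.
- The pipeline starts at the quantified feature table; raw spectra, peak
  integration and identification are upstream concerns.
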