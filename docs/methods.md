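# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `longewas`.

## Study design being modelled

A prospective pregnancy cohort in which maternal glycemia is measured once,
mid-pregnancy, by a 75 g OGTT, and offspring blood DNA methylation is
measured on an EPIC-style array at up to two occasions: umbilical cord blood
at delivery and peripheral blood at roughly five years. Children overlap
only partially between occasions, so the per-CpG analysis must combine an
unbalanced mix of subjects with one or two samples. The default synthetic
cohort has 539 dyads — 440 with a cord sample, 293 with an age-5 sample,
194 with both — satisfying the identity
`n_birth + n_age5 − n_both = n_dyads`, which is asserted for every
generated study.

## Exposures

`auc_trapezoid` integrates the 0/1/2 h glucose triplet with the trapezoidal
rule (mmol/L·h). The trapezoid is linear in the glucose values and invariant
to inserting collinear points; both are property-tested. Fasting, 1 h and
2 h glucose are carried as secondary exposures. GDM classification
(`classify_gdm`) flags a profile when any value meets or exceeds its cutoff;
the default cutoffs (5.1, 10.0, 8.5 mmol/L) are an IADPSG-style convention
chosen by this package — the emulated cohort's diagnostic rule is not
published — and are configurable.

Report tables round half-to-even at one decimal after a pre-quantisation at
seven decimals that strips binary-float noise (so a trapezoid of 12.05 that
is stored as 12.050000000000001 still prints 12.0). Medians and IQRs use
linear interpolation between order statistics (type-7), the numpy default.

## Preprocessing

*Transforms.* M = log₂(β/(1−β)); β at exactly 0 or 1 is clipped to
[1e−6, 1−1e−6] (logged) so M stays finite. The round trip is exact to
1e−12 inside the clip range.

*Probe filtering* applies, in a fixed order that only affects report
attribution, never the retained set: non-CpG ids (flag or `rs`/`ch`
prefix), sex-chromosome, SNP-associated (MAF ≥ 0.05), cross-reactive,
zero-variance, and probes with detection p > 0.05 in ≥ 5% of samples (rule
skipped and logged when no detection matrix exists). Filtering is
idempotent.

*Batch adjustment* re-implements the parametric empirical-Bayes
location/scale model: per-probe OLS under [batch indicators | protected
covariates], standardization, per-batch location (γ) and scale (δ²)
estimates shrunk with method-of-moments priors — normal across probes for
locations, inverse-gamma for scales — solved by the standard fixed-point
iteration, then back-transformation with the protected fitted effects
restored unchanged. Protected covariates are the three OGTT glucose values,
maternal age, first-trimester BMI, gravidity, smoking and child sex. The
adjustment runs on the M-value scale, before residualization; with a single
batch the model is degenerate and the input is returned unchanged. Planted
batch shifts (SD 0.5) are removed to better than 99% while a protected
exposure slope moves by ~1e−3 M-units in the bundled fixtures.

*Cell composition* is estimated per sample by constrained projection: with
panel F (cell type × mean β at the panel's discriminating CpGs) and sample
vector y, solve min‖y − Fᵀp‖² subject to p ≥ 0, Σp = 1. The simplex
constraint is imposed through a heavily weighted sum row inside a
non-negative least-squares solve, followed by exact renormalization;
noiseless mixtures are recovered to machine precision and the mean per-type
error at β-noise SD 0.02 is below 0.01. A panel with linearly dependent
cell-type profiles raises a non-identifiability error. Composition is
estimated from the unadjusted β (reference panels describe raw
proportions), before probe filtering, so filtering cannot remove
discriminating probes from under the deconvolution.

*Residualization* regresses M on [intercept, cell proportions, age] per
time point by QR projection, with the panel's most abundant cell type
dropped to break the simplex sum-to-one collinearity (how the original
analysis handled this constraint is not published; dropping the dominant
type is the package's choice). Age is gestational weeks at birth and years
at age 5. Residuals are exactly orthogonal to every design column
(~1e−13 relative in practice).

## The random-intercept REML engine

For each CpG the stacked residuals follow
y_ij = x_ij'θ + b_i + e_ij with b_i ~ N(0, σ_b²), e_ij ~ N(0, σ_e²). With
γ = σ_b²/σ_e², each subject's covariance is V_i = I + γJ whose inverse is
I − γ/(1+n_i γ) J for block sizes n_i ∈ {1, 2}. The restricted
log-likelihood is profiled to γ:

    l_R(γ) = −½ [ (N−p) log σ̂²(γ) + Σ_i log(1+n_i γ) + log|X'V⁻¹X| ]

with σ̂²(γ) the GLS residual mean square on N−p degrees of freedom. The
engine precomputes per-design sufficient statistics (X'X; singleton and
pair-sum Gram matrices) so each γ evaluation costs O(p³) regardless of N,
which is what makes a 10,000-CpG EWAS run in well under a minute.

Numerical choices:

- γ is maximized on the log scale over [1e−8, 100] by bounded Brent search
  (xatol 1e−13); the γ = 0 boundary is always evaluated explicitly and kept
  when superior. With no repeated subjects the boundary fit is returned
  directly and equals OLS exactly.
- Single likelihood evaluations carry O(1e−13) floating-point noise, which
  caps any bracketing optimizer near √(noise/curvature); the single-CpG
  fitter therefore polishes γ̂ with a local least-squares parabola whose
  vertex averages that noise out (~two orders of magnitude sharper). The
  genome-wide loop skips the polish — a sub-1e−6 refinement of γ is
  irrelevant to Wald p-values — for speed.
- Inference is Wald with a normal reference rather than the
  t-with-denominator-degrees-of-freedom convention of common mixed-model
  software; at the design's N ≈ 600–750 the difference is negligible, and
  the simpler contract is used consistently by the mixed and linear models.
- Rows with missing exposure or covariates are dropped per model
  (complete-case); non-convergent CpGs are flagged in a status column,
  excluded from λ and DMR input, and retained in the output table.

A deliberately naive reference (`reml_loglik_full`,
`fit_random_intercept_full`) builds the dense N×N covariance and maximizes
it with a generic scalar optimizer; it shares no code with the profiled
path and anchors the equivalence tests (agreement to better than 1e−6
relative in all parameters over random mixed designs).

Single-time-point analyses (`ewas_linear`) are vectorized per-CpG OLS with
the same covariates minus the time-point indicator; with one observation
per subject they coincide with the mixed model exactly.

## Genome-wide inference

- **Thresholds.** Genome-wide significance is strict `p < α/n_tests`; the
  suggestive tier is inclusive `p ≤ 1e−5`. Report text prints the
  Bonferroni threshold with its mantissa truncated to two significant
  figures (0.05/719,360 = 6.95e−8 prints as 6.9e−08).
- **λ.** Median of the χ²₁ quantiles of observed p divided by 0.4549364
  (the χ²₁ median), over converged tests only; QQ quantile pairs are
  exported alongside.
- **DMRs.** Candidates are maximal runs of consecutive same-chromosome
  CpGs, every one at p < 0.05, same effect sign, successive positions
  ≤ 500 bp apart (an intervening non-candidate CpG breaks the run). Each
  candidate is combined by GLS: S = D·R·D with D = diag(SE) and R the
  correlation of the member CpGs' stacked residuals;
  B = (1'S⁻¹β̂)/(1'S⁻¹1), Var(B) = 1/(1'S⁻¹1). A singular S is
  ridge-regularized (R + 1e−6 I) and flagged. Region p-values are
  Bonferroni-adjusted over the number of candidates. The method named for
  this step in the emulated analysis publishes no parameter settings, so
  maxgap and the candidate threshold are config-exposed with these
  conventional defaults. A size-1 candidate reproduces its CpG's Wald test
  bit-for-bit.
- **Annotation.** Nearest-gene assignment against a 1-based inclusive
  interval table (a converter from 0-based half-open BED is provided);
  containment wins, distance ties break to the smaller start, CpGs on
  chromosomes absent from the table get an empty annotation.

## The synthetic cohort generator

The generator is first-class, tested code; it defines the conditions under
which the pipeline is validated.

Covariates follow the emulated cohort's marginals: maternal age
N(28.2, 4.2) years; first-trimester BMI log-normal with median 23.9 and
log-SD 0.19 (back-solved from the published IQR); smoking 9.1%, primigravid
33.4%, girls 46.8%; gestational age at delivery ~N(39.7, 1.11) weeks
clipped to [30, 43]; age at follow-up ~N(5.2, 0.22) years clipped to
[4.5, 6.5]. The OGTT triplet is log-normal with medians 4.2/7.1/5.7 mmol/L,
log-SDs 0.089/0.232/0.236 (from the published IQRs) and pairwise log-scale
correlation 0.5 — only marginals are published; the correlation value keeps
glucose positive and gives the AUC a realistic spread (SD ≈ 2.2 mmol/L·h,
matching the published IQR).

Methylation is generated on the M scale:

    M_gj = μ_g + cell_g(p_j) + s_g·(age_j − mean age) + batch shift
           + β_g·(AUC_i − mean AUC) + b_ig + ε_gj

with probe baselines μ_g from a bimodal mixture (mostly near-unmethylated
or near-methylated, as on real arrays), per-probe age slopes s_g ~
N(0, 0.02), per-probe×batch shifts ~ N(0, 0.1) over 4 batches, subject
intercepts b_ig ~ N(0, 0.12) shared across a child's two samples, and
residual noise ε ~ N(0, 0.22). The subject/residual SDs were chosen so the
total M-value SD (≈0.25) reproduces the sampling uncertainty implied by the
published effect/p-value pairs at this design size; planted effects default
to |β| ∈ [0.02, 0.04] M-units per mmol/L·h with random sign, the magnitude
range of the published top hits. Cell proportions are Dirichlet with
concentration 20 × the panel mean composition (7-type cord panel including
nRBC, 6-type peripheral panel; composition distributions are not published,
these centres are typical reference-based estimates). For background probes
the composition term is the cell-composition-weighted mixture of panel
logits, centred at the mean composition and scaled by `cell_effect_sd`; for
the panels' discriminating probes the methylation *is* the uncentred
mixture of panel logits, so that reference-based deconvolution sees genuine
cell-type markers. β = logistic₂(M) is stored; causal probes are drawn from
flag-free probes outside the discriminating sets so exposure effects cannot
leak into composition estimation. Planted effects are constant across time
points by default; `birth-only` and `5y-only` profiles exercise the
per-time-point models. All randomness flows from one integer seed through
named generator streams; identical seeds give byte-identical studies.

A second generator (`simulate_region_study`) emits residual-scale outcomes
directly with one planted multi-CpG region of configurable cross-CpG
correlation, used to validate the DMR machinery with exact expected
boundaries.

What the generator does **not** emulate: probe-type (I/II) chemistry and
intensity-level artefacts, detection-p structure from control probes,
genomic autocorrelation of methylation outside planted regions, non-Gaussian
residuals, time-varying confounding, and exposure–cell-composition
correlation. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
failure mode of real arrays.

## Validation conditions and problem sizes

The bundled validation uses the default study (539 dyads, 2,000 CpGs, 50
causal) for parameter recovery; because per-study coverage of 50 planted
effects is a coarse binomial measurement, the recovery check pools four
replicate studies with distinct seeds (200 causal CpGs), matching the scale
at which the engine's coverage was designed to be assessed. Observed:
signed bias well under 1% of the planted magnitude, 95% Wald coverage
≈ 94%. Null calibration uses a 10,000-CpG global-null pipeline: rejection
rate at 0.05 within the binomial 99% interval and λ ≈ 1.00. The REML
equivalence suite uses 100 random designs of 20–60 subjects with mixed
1/2-observation patterns.

## Known limitations

- Wald/normal inference slightly undercovers relative to
  Kenward–Roger-style corrections at small subject counts; at this design
  size the deficit is ≈1 point of coverage.
- The empirical-Bayes batch model assumes enough probes to estimate its
  priors; with very few probes (or near-identical ones) it falls back to no
  shrinkage.
- Residualizing on *estimated* cell composition leaves a small share of
  composition variance in the outcome (attenuated, never sign-flipped, in
  simulations).
- DMR candidate formation uses the analysed CpG universe; sparse coverage
  of a genomic region fragments candidates rather than bridging them.
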