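# Methods

## Score and population model

The polygenic risk score is the raw weighted allele count
`PRS_j = Σ_i β_i x_ij` with `β_i = ln OR_i`.  All evaluation runs on raw
scores; nothing is standardised implicitly.  Two explicit, opt-in
transforms exist in `score.standardize_scores`:

* **μ-centring** — shift by `μ − E[raw]` with `E[raw] = Σ 2p_iβ_i` and
  `μ = −σ²/2`, so the population mean relative risk `E[e^PRS]` is one.
  A D'Agostino–Pearson omnibus normality test is reported alongside.
* **shift-log** — the monotone map `ln(score − min + 1)` for skewed score
  distributions.  It is never applied silently because it changes only
  scale-sensitive summaries (means, medians), not ranks, cutoff
  classifications, quartiles or AUC.

Population parameters assume Hardy–Weinberg equilibrium and linkage
equilibrium between loci: `σ² = Σ 2p_i(1−p_i)β_i²`, the variance of the
score in the general population.  Under the multiplicative model and the
rare-disease approximation, tilting the population law by `e^PRS` gives
the case distribution; for the normal approximation this is a mean shift
of σ² at equal variance, hence the closed-form check
`AUC = Φ(σ/√2)` implemented as `score.theoretical_auc`.

## Synthetic cohort generator

Controls draw each locus independently as Binomial(2, p_i).  Cases use
the exact per-locus tilted law, which is again binomial at
`p′ = p·OR/(1−p+p·OR)`; this is O(n·m), exactly consistent with the
multiplicative model, and analytically checkable (the expected
case–control mean score shift `Σ 2β_i(p′_i−p_i)` is a test oracle).
No linkage disequilibrium, population structure or age-dependent incidence
is modelled; passing tests therefore demonstrate internal consistency of
the method under its own assumptions, not robustness to the LD,
winner's-curse and stratification effects present in real genotype data.

Clinical phenotypes are drawn independently of genotype given case
status, from categorical marginals whose defaults reproduce the baseline
characteristics of a Finnish non-familial prostate-cancer case series
(clinically detected and screen-detected columns: age at diagnosis,
diagnostic PSA ≤/> 20 ng/mL, Gleason group, T/N/M stage, cause of death,
each with its missing-data category).  Printed percentage columns summing
to 100.1 from rounding are renormalised exactly.  One optional dependence
is provided: a log-odds tilt of M1 stage per case-PRS standard deviation
(`m1_prs_log_or`, default 0), divided by `e^{b²/2}` so the configured
marginal M1 rate is approximately preserved.

Baseline PSA for screening-arm subjects is log-normal: controls
`ln PSA ~ N(ln 1.1, 0.7²)` (≈2% above 4 ng/mL), cases
`ln PSA ~ N(ln 4 + z₀.₉·0.9, 0.9²)` so the conventional 4 ng/mL threshold
detects ≈90% of screen-detected cases.  These parameters are package
defaults (`PsaModel`), chosen to make PSA the dominant predictor in the
screening models (simple-model AUC ≈0.98) while the PRS contributes
residual information — the qualitative structure the screening analysis
expects.  No published PSA distribution was available to calibrate
against; the marginal positivity (~16%) is in the range seen in
PSA-screening trials.  The generator labels case `source` (clinical vs
screening trial) but does not model the screening process itself.

Randomness: one master seed; each component (controls, cases,
missingness, phenotypes) uses `SeedSequence([seed, stream_id])` with
documented stream ids, so stages are independently reproducible.

## Demonstration panel

`data/synthetic_panel55.tsv` is a synthetic stand-in for a
population-specific 55-locus panel: 47 risk loci (OR 1.105–1.18) and
8 protective loci (OR 0.85–0.895), every record passing the selection
funnel (p < 5·10⁻⁸, OR > 1.1 or < 0.9).  Effect-allele frequencies
(0.047–0.144) were solved once so that σ² = 0.180, the value at which the
model's theoretical AUC equals 0.618 and the theoretical top-vs-bottom
quartile odds ratio is ≈3.0 — the discrimination regime this kind of
55-SNP panel achieves in practice.  The file is frozen; it is data, not a
tuning knob.

## Evaluation conventions

* **Above median** means strictly greater than the control median; ties at
  the cutoff count negative.  With an even number of tie-free continuous
  control scores, control specificity is exactly 0.5.
* **Quartiles** use linear-interpolation empirical quantiles (the common
  "type 7" rule) of the pooled study population by default; a
  control-only basis is available (`basis="controls"`), as is a
  screening-cohort-internal basis in `psa_quartile_table`.
  Scores equal to a boundary fall into the lower quartile, consistent
  with the strictly-greater rule.
* **Odds ratios** from 2×2 tables are cross-products with Woolf CIs; a
  zero cell triggers the Haldane–Anscombe +0.5 correction with a warning.
  `logistic_fit` on a binary covariate reproduces the cross-product
  exactly (tested), so the two routes are interchangeable.
* **ROC/AUC** uses the Mann–Whitney identity (ties count ½), equal to the
  trapezoidal area under the empirical sweep; CIs are Hanley–McNeil by
  default with DeLong available by flag; the p-value against AUC = 0.5 is
  the tie-corrected normal approximation of U.
* **Chi-square** tests of independence are Pearson, no continuity
  correction; a Cochran–Armitage trend test is available for ordered
  2×k tables (quartile-by-outcome), since an ordered exposure often calls
  for a trend alternative.
* **HWE** is the 1-df asymptotic chi-square against expectations at the
  sample allele frequency.  Monomorphic loci pass with statistic 0 and a
  warning: they contribute a constant to every score, so the test is
  vacuous and a hard failure would only force callers to special-case
  them.
* **Per-SNP allelic ORs** are maximum-likelihood logistic fits of status
  on dosage, computed on the collapsed 2×3 table with frequency weights
  (identical likelihood to the per-subject fit).  |log OR| > 15 or a
  non-finite standard error is reported as a flagged, unbounded-CI result.
* **Missing dosages** are mean-imputed with the HWE expectation `2p_i` by
  default, keeping scores comparable across subjects with different
  missingness; an omit-locus mode exists for sensitivity analyses.
* **Effect-allele orientation** is defined by the panel.  A VCF record
  whose {REF, ALT} differs from the panel's allele pair is an error, never
  a silent flip; when the effect allele is REF, reference alleles are
  counted.

## Numerical choices

Logistic fits use Newton's method (statsmodels), tolerance 1e-10, 100
iterations; non-convergence or quasi-separation yields a flagged result.
The cumulative-AUC sequence of the nested screening models (PSA → +age →
+PRS) is monotone in likelihood but not exactly in AUC, which is a rank
statistic: adding a weak covariate to a near-separating model can lower
the in-sample AUC by ~1e-4–1e-3.  The report logs any decrease beyond
1e-6 and the tests allow 1e-3 of rank noise.

## Problem sizes

Simulation-backed tests use the sizes at which their tolerances are
meaningful: 50,000 subjects for moment-convergence checks (4 standard
errors), 20,000 per arm for AUC-vs-theory (±0.01) and per-SNP OR
CI-coverage (50 replicates, ≥90% coverage of the nominal 95%), and the
study-sized 2,738 cases / 2,400 controls for the quartile-OR envelope
(50 replicates, median within [2.2, 3.6]).

## Known limitations

* Independence of loci is assumed everywhere; with LD the σ² formula and
  the tilted sampler both overstate per-locus information.
* The rare-disease tilt ignores disease prevalence; for common outcomes
  the case genotype law is flatter than the tilt implies.
* Clinical covariates are conditionally independent of the score given
  case status (except the optional M1 tilt), so subgroup analyses on
  synthetic data are calibration checks of the null, not power studies.
* Wald/Woolf intervals are first-order; no exact or profile-likelihood
  intervals are provided.
* No survival analysis, calibration testing or reclassification indices.
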