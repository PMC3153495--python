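# Methods

## Problem setting

Two rabbit monoclonal antibodies stain, respectively, EGFR carrying the
L858R point mutation and EGFR carrying the E746-A750 exon-19 deletion.
Sequencing of EGFR exons 18–21 provides ground truth.  Each stained section
is read as an ordinal intensity I ∈ {0, 1, 2, 3} and a percent of stained
tumor cells P ∈ [0, 100]; the quickscore Q = P·I ∈ [0, 300] combines both.
A pan-cytokeratin stain acts as a per-section quality gate: a section with
pan-CK intensity 0 is treated as non-reactive and excluded, and sections
with under 60% tumor cells are excluded before analysis (the threshold is a
loader parameter, `tumor_content_min`).

The package treats each reading as a single consensus record; adjudication
between observers happens upstream of the data model.

## Scoring schemes and the logistic combination

For each target mutation there are six scoring schemes: the
mutation-marker's intensity or quickscore, alone or combined with the
total-EGFR antibody's intensity or quickscore.  A combined scheme is fit as
a binary logistic regression

  p̂ = σ(β₀ + β₁·x_mut + β₂·x_total),

with labels from the sequencing genotype.  Label rules: the L858R target
counts any genotype containing L858R, including complex (multi-mutation)
genotypes; the E746-A750 target counts only exact E746-A750 deletions, so
other exon-19 deletions are negatives for that antibody's target even
though they are Del-19 mutations.

Fitting is IRLS (Newton scoring) on the unpenalized likelihood with
deviance-based convergence (tolerance 1e-8 on the deviance change, max 100
iterations) and step halving, which keeps the deviance monotone.  Features
enter unstandardized; predicted probabilities are invariant to affine
feature rescaling.  Complete separation — a single-feature threshold that
classifies perfectly, or a zero-deviance fit in higher dimension — raises
`SeparationError` rather than silently diverging; callers may retry with
`firth=True`, which maximizes the Jeffreys-penalized likelihood (score
correction `y − μ + h(½ − μ)` with hat diagonals h) and exists under
separation.  The pipeline driver uses that fallback automatically and
records it in the report row, because separation is routine at n ≈ 143 with
a nearly perfect antibody.  Wald standard errors come from the observed
information at the optimum.

## ROC, cutoff and paired AUC comparison

Classification at threshold t calls score ≥ t positive.  ROC vertices sit
at every unique score plus sentinels above the maximum and below the
minimum; tied scores share one vertex and no interpolation beyond the
trapezoid is used (intensity-only curves have at most six vertices).  The
AUC is the Mann–Whitney statistic (ties count ½), which equals the
trapezoid area under this construction.

The operating point is chosen closest to the top-left corner of ROC space:
argmin d² = (1−sens)² + (1−spec)².  Ties on d² (within 1e-12) resolve
toward higher specificity — the scheme exists to remove false positives —
and any residual tie toward the stricter threshold.

Correlated AUCs on the same patients are compared with DeLong's
structural-components variance estimate and a standard-normal z test;
single-AUC confidence intervals use the same components and are labeled
DeLong intervals.  Zero estimated variance returns p = 1 when the AUC
difference is zero and raises otherwise.

## Diagnostic metrics and categorical tests

From a 2×2 table against sequencing truth: sens = tp/(tp+fn),
spec = tn/(tn+fp), PPV, NPV, accuracy, LR+ = sens/(1−spec),
LR− = (1−sens)/spec, reported in percent.  Two conventions are exposed
because published diagnostic tables typically form likelihood ratios from
the *rounded* operating point: `printed` rounds sens/spec/PPV/NPV/accuracy
to one decimal percent first and then forms LR± to three decimals (38/23/5/77
gives LR+ 3.843), while `exact` uses full precision (3.842).  Zero
denominators yield NaN with an explicit flag; LR+ under perfect specificity
is flagged infinite.  Pearson's χ² is computed without continuity
correction; Fisher's exact test (two-sided hypergeometric sum) is the
recommended alternative whenever an expected cell count is below 5
(`expected_counts_below`), and the pipeline switches automatically.  Wilson
score intervals for proportions are provided as an extension beyond the
tabulated metrics.

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; the median is the smallest t with S(t) ≤ 0.5 and is flagged
undefined when the curve never reaches 0.5.  Median follow-up uses the
reverse-KM convention (event/censor roles swapped).  Cox regression is
delegated to statsmodels PHReg with Efron tie handling by default — ties
are the norm with month-resolution PFS — and Breslow behind the `ties`
flag.  Non-convergence and monotone partial likelihood (runaway
coefficients, |β| > 20) raise `CoxConvergenceError`.  Covariates must be
numeric; the pipeline encodes sex, smoking, ECOG performance status (0–1
vs 2–4), IHC status and treatment line (first vs later) as 0/1 indicators.
Note that exact sample-duplication invariance of the hazard ratio holds for
Breslow but only approximately for Efron, since duplication manufactures
ties that Efron's correction treats differently.

## Synthetic cohort generator

The generator is the test bed for every stage; its defaults are the study
conditions the pipeline assumes.

* **Genotypes** — five classes {E746-A750, other Del-19, L858R, other
  mutant, wild} drawn with probabilities proportional to 31:10:43:8:50
  (renormalized; the printed class counts sum to one less than the cohort
  size, and renormalization is the documented resolution).  Genotype
  strings use a controlled vocabulary; L858R carriers are complex
  (L858R+X) with probability 5/43, and other-class tumors draw from the
  printed rare forms.  The exon-18 deletion delE709-T710insD is classified
  as not-Del-19.
* **Demographics** — sex and smoking are drawn conditional on mutation
  status so that mutation prevalence reproduces 79.2% (female) vs 50.7%
  (male) and 77.7% (never-smoker) vs 40.8% (ever-smoker).
* **Staining** — total-EGFR intensity cuts a latent Gaussian (mean 1.8 for
  mutants, 1.0 for wild type, sd 1) at 0.5/1.5/2.5; percents are Beta draws
  scaled to [0, 100] (Beta(3, 1.5) for total EGFR, Beta(6, 2) for cognate
  staining, Beta(2, 3) for cross-reactive staining), rounded to one
  decimal.  Carriers stain their cognate antibody at intensity 2–3 except
  an IHC false-negative minority (rates 5/43 and 2/31).  Non-carriers
  receive cross-reactive staining by cutting κ·base·(Q_total/300)·Exp(1)
  at the same thresholds, so nonspecific positivity increases with
  total-EGFR level — exactly the structure the combined model exploits —
  and vanishes at κ = 0.  Base strengths (2.6 for the L858R antibody, 0.55
  for the deletion antibody) were set so the legacy 1+/>10% rule shows
  false-positive rates near 42% and 9.8% at the default mix.  One in ten
  other-Del-19 tumors cross-stains the deletion antibody (the L747-T751
  phenomenon).
* **Outcomes** — recurrence (rate 80/143) and TKI treatment (37/80 of
  recurrences) are Bernoulli; treatment lines follow 7:12:14:4.  Response
  is Bernoulli by IHC status (0.773 vs 0.333; responders split CR/PR
  1:9, non-responders SD/PD 4:11).  PFS is exponential with group medians
  12.0 / 4.7 months (rate = ln 2 / median); when the ECOG scenario flag is
  set, poor performance status (probability 9/37) multiplies the hazard by
  the configured ratio (5.52 in the tabulated scenario).  Censoring is an
  independent Uniform(0, τ) time with τ solved per hazard rate so the
  expected censored fraction equals `censor_rate` (default 0.2); this
  keeps the KM estimator consistent for the configured medians.
* Everything flows from one `numpy.random.Generator` seeded by
  `SimConfig.seed`; identical configs give byte-identical TSVs.

**What the generator does not emulate:** intratumoral staining
heterogeneity and observer disagreement (a single consensus read is
drawn), correlation between staining strength and outcome beyond the
binary IHC call, non-exponential PFS shapes, cohort-level time trends in
specimen age, and sequencing error (truth labels are exact).  Passing
tests therefore demonstrate correctness of the statistical machinery under
the assumed generative structure, not clinical performance on real slides.

## Problem sizes and numerical choices

Stochastic validation uses sizes chosen to make sampling error small
relative to the tolerance checked: parameter-recovery fits at n = 2000–5000,
law-of-large-numbers checks at n = 20000–100000, 100 seeded replicates for
the directional AUC property, 500 replicates for log-rank type-I-error
calibration, and a 20000-resample paired bootstrap as the oracle for the
DeLong test on a fixed n = 30 fixture.  Probability clipping in IRLS uses
1e-12; ROC tie comparison uses exact float equality of identically computed
quantities with a 1e-12 guard on d².

## Known limitations

* The optimal cutoff is selected and evaluated on the same cohort (as in
  the source analyses); no cross-validation or bootstrap optimism
  correction is applied.
* The Firth fallback reports Wald intervals from the penalized information,
  which are known to undercover for extreme separation; profile-likelihood
  intervals are not implemented.
* `paired_auc_test` assumes a paired design on identical patients; there is
  no unpaired variant.
* The H-score and other alternative IHC quantifications are out of scope;
  only intensity and quickscore readouts are modeled.
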