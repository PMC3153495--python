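# stainclass

Immunohistochemistry (IHC) with EGFR mutation-specific antibodies is a fast,
cheap screen for the two "classical" activating EGFR mutations in lung
adenocarcinoma — the L858R point mutation and the E746-A750 exon-19
deletion — whose carriers respond to EGFR tyrosine-kinase inhibitors (TKIs).
The catch is nonspecific staining: wild-type tumors with high *total* EGFR
expression can weakly stain the mutation-specific antibodies, so the usual
positivity rule (more than 10% of tumor cells at intensity 1+ or higher)
produces false positives.

`stainclass` is a library for building and evaluating IHC scoring rules
against DNA-sequencing ground truth, for biostatisticians and pathology
groups working with mutation-specific antibodies:

* **quickscore quantification** — Q = P × I, the product of percent positive
  cells (0–100) and ordinal intensity (0–3), range 0–300;
* **logistic score combination** — p̂ = σ(β₀ + β₁·Q_mut + β₂·Q_totalEGFR),
  fit by IRLS with explicit complete-separation detection and an optional
  Firth-penalized fallback; six scoring schemes per target (intensity or Q
  score, alone or paired with total-EGFR intensity/Q score);
* **ROC toolkit** — empirical ROC at the score ≥ t convention, Mann–Whitney
  AUC with tie handling, the closest-to-corner optimal cutoff
  (argmin (1−sens)² + (1−spec)², ties toward higher specificity), and
  DeLong's paired z-test for correlated AUCs;
* **diagnostic accuracy** — sensitivity/specificity/PPV/NPV/LR±/accuracy
  from 2×2 tables in both exact and "printed" (pre-rounded operating point)
  conventions, plus Pearson χ² and Fisher's exact test;
* **outcome analysis** — Kaplan–Meier PFS curves, two-group log-rank test,
  and multivariate Cox regression (Efron or Breslow ties);
* **synthetic cohorts** — a seeded generator reproducing the study structure
  the pipeline assumes: a 143-patient genotype mix, cross-reactive
  mutation-marker staining that scales with total-EGFR level in
  non-carriers, IHC false-negative minorities, and TKI outcomes (response
  probabilities 0.773 vs 0.333 and exponential PFS medians 12.0 vs 4.7
  months by IHC status).

## Worked example

```python
from stainclass import (SimConfig, SchemeSpec, simulate_cohort, build_features,
                        fit_logistic, predict_probability, roc_curve,
                        optimal_cutoff, paired_auc_test)

cohort = simulate_cohort(SimConfig(seed=7))           # 143 patients
X, y, names = build_features(cohort, SchemeSpec("L858R", "qscore", "qscore"))
coefs = fit_logistic(X, y)
p_hat = predict_probability(coefs, X)
curve = roc_curve(p_hat, y)
cut = optimal_cutoff(curve)
X_int, _, _ = build_features(cohort, SchemeSpec("L858R", "intensity"))
test = paired_auc_test(p_hat, X_int.ravel(), y)
print(f"AUC {curve.auc:.3f}, cutoff p>={cut.threshold:.3f} "
      f"(sens {cut.sensitivity:.1%}, spec {cut.specificity:.1%})")
print(f"vs intensity-only AUC {test.auc_b:.3f}, DeLong p = {test.p_value:.3f}")
```

prints

```
AUC 0.839, cutoff p>=0.287 (sens 83.3%, spec 88.4%)
vs intensity-only AUC 0.828, DeLong p = 0.563
```

The combined score out-ranks raw intensity (0.839 vs 0.828 here; across 100
seeded replicates it wins ≈99% of the time) because the model discounts
mutation-marker signal in tumors whose total-EGFR level predicts nonspecific
staining.  One cohort of 143 is usually too small for the paired difference
to reach significance, as the p-value shows.

The `examples/` directory holds one short script per capability
(quickscore, combined score + ROC, diagnostic metrics, survival, full
pipeline).  A thin CLI wraps the same functions:

```bash
stainclass simulate --seed 7 --out cohort.tsv
stainclass evaluate --target l858r --rule combined --cohort cohort.tsv
stainclass report --seed 7 --out report.json
```

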