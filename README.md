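# parenclitic

Per-patient **parenclitic network analysis** for clinical cohorts, with a
survival-modelling layer.  The motivating application is 12-month prognosis in
liver cirrhosis from seven routine clinical/laboratory variables (serum
albumin, total bilirubin, prothrombin time, serum creatinine, ammonia, serum
sodium and hepatic encephalopathy grade), but the machinery is generic: it
works for any cohort in which pairwise relationships that hold in a reference
class are disrupted in patients with poor outcomes.

## The method

Population-level correlation networks cannot be attached to a single patient.
The parenclitic ("deviation") approach maps a network *per subject*:

1. **Reference models.** On the reference class (patients who survived the
   follow-up horizon), every variable pair (x, y) is screened by Spearman
   correlation with pairwise deletion, at the Bonferroni-corrected level
   α/m.  With p = 7 variables, m = p(p−1)/2 = 21 and α = 0.05 the per-pair
   level is 0.05/21 ≈ 0.0024.  An OLS line y = a + bx is fitted for each
   significant pair; non-significant pairs are excluded from all further
   analysis.
2. **Parenclitic deviations.** For each patient and each reference pair, the
   deviation ∂ is the orthogonal residual of the patient's point from the
   reference line: with vertical leg v = |y₀ − (a + bx₀)| and horizontal leg
   h = v/|b|,

   ∂ = v·h / √(v² + h²) = v / √(1 + b²),

   i.e. the perpendicular distance to the line.  ∂ is an unsigned edge weight
   in the patient's network (nodes = variables, edges = reference pairs).
3. **Topology indices.** Each ∂-weighted network is summarized by weighted
   degree centrality (strength) and its SD across nodes, characteristic path
   length, diameter and global efficiency, with ∂ acting as a *distance*
   (more deviation = weaker physiological connectivity).
4. **Survival layer.** Deviations and topology indices are compared between
   survivors and non-survivors (Mann-Whitney U), entered into univariate and
   bivariate Cox proportional-hazards models (with MELD or Child-Pugh as the
   second covariate, Efron ties), and evaluated as prognostic scores via ROC
   AUC with Youden-J cutoffs and Kaplan-Meier / log-rank (Mantel-Cox) tests.
   The combined severity-deviation index is the bivariate Cox linear
   predictor, MELD-∂ = β₁·MELD + β₂·∂.

Because real patient-level data of this kind are rarely shareable, the
package ships a first-class synthetic-cohort generator
(`parenclitic.synthetic`) that reproduces the structure the analysis assumes:
linearly coupled variable pairs in a clean class, inflated residual noise on
disrupted axes in a second class, and exponential event times whose
log-hazard rises with the true deviations.

## Worked example

```python
from parenclitic import (AnalysisConfig, SyntheticConfig, apply_horizon,
                         generate_cohort, run_pipeline)

cohort = apply_horizon(generate_cohort(SyntheticConfig(seed=1)), 365)
res = run_pipeline(cohort, AnalysisConfig())
```

On the default 500-patient synthetic cohort at seed 1 this prints (see the
full snippet in `docs/methods.md` for the formatting code):

```
significant pairs: 10 of 21 (threshold p <= 0.0024)
Alb-Bil reference line: slope -3.08, intercept 164.5
delta Alb-Bil  survivors 3.05 (1.59-5.27)  non-survivors 8.89 (4.56-16.17)  p=1.60e-16
univariate Cox Alb-Bil: HR 1.185 (1.155-1.216), p=2.04e-38
AUC alb_bil: 0.801 (0.739-0.864), cutoff 7.38
log-rank (Alb-Bil cutoff): chi2 127.13, p=1.74e-29
```

Reading: the albumin-bilirubin coupling fitted on survivors has slope ≈ −3
µmol/L per g/L; non-survivors deviate from that line about three times as
far as survivors (median ∂ 8.9 vs 3.1); each unit of ∂ multiplies the
12-month hazard by ≈ 1.19; and dichotomizing at the Youden cutoff separates
the Kaplan-Meier curves decisively.  The six injected axes are always among
the significant pairs; the extra significant pairs are transitive
correlations that any joint distribution with couplings this strong must
carry.

A command-line interface wraps the same pipeline:

```bash
parenclitic simulate --seed 1 --out cohort.csv
parenclitic run --input cohort.csv --outdir results/
```

`run` writes one CSV per result table (screening report, per-patient deltas
and topology indices, group comparisons, Cox tables, AUC table, per-group
Kaplan-Meier step functions).

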