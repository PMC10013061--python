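# Methods

This note records the model, the numerical conventions, the synthetic data
generating process, and the design choices that were genuinely open.

## Reference models and screening

The reference class is the set of patients event-free at the follow-up
horizon (default 365 days; deaths and transplants within follow-up are
events, and events recorded after the horizon are administratively censored
at the horizon before any analysis).

Every unordered pair of the seven clinical variables is screened by Spearman
rank correlation with midrank ties, computed with pairwise deletion: each
pair uses exactly the rows where both members are observed.  The two-sided
p-value uses the large-sample t approximation, adequate at the default
minimum of 10 complete pairs.  Significance is judged at the
Bonferroni-corrected level α/m with m = 21 counting *all* pairs, including
pairs flagged as having insufficient data — the corrected level is a
property of the variable set, not of the missingness pattern.  Screening is
invariant to strictly monotone transforms of either variable (a Spearman
property, verified by test); the fitted lines are not.

Pair orientation is fixed by the variable order (albumin, bilirubin,
prothrombin time, creatinine, ammonia, sodium, HE): the earlier variable is
the predictor.  Orthogonal distance to an OLS line depends on which variable
is regressed, so a fixed convention is required for reproducibility.  For
each significant pair an ordinary least-squares line is fitted on the
reference class (pairwise deletion again); a constant predictor raises a
degenerate-fit error and drops the pair with a warning.

## Parenclitic deviation

∂ is computed via the closed form v/√(1+b²) (perpendicular distance), which
is algebraically identical to the residual-triangle altitude
v·h/√(v²+h²) for b ≠ 0 and extends it continuously with ∂ = v at b = 0 and
∂ = 0 at v = h = 0, avoiding the 0/0 and division-by-zero corners of the
triangle form.  The equivalence is enforced by test to 1e−9 over random
lines and points.

Deviations are unsigned and kept in raw units: values are comparable across
patients within an axis, not across axes.  No per-axis normalization is
applied before the topology stage; the network consumes ∂ as given.  A pair
with a missing member yields no ∂ and no edge for that patient; missing
values are never imputed anywhere in the pipeline.

## Network topology

Nodes are the variables covered by at least one reference pair (under the
default synthetic conditions: albumin, bilirubin, prothrombin time, ammonia,
HE; creatinine and sodium never pass screening and are excluded from the
networks entirely).  Edges carry ∂ as weight and as *distance*: larger
deviation = longer path = weaker connectivity.

Standard weighted-graph definitions are used: degree centrality is the
undirected weighted degree (strength; the regression-derived network has no
natural edge direction); its dispersion is the sample (n−1) SD over nodes;
characteristic path length is the mean Dijkstra shortest-path distance over
connected node pairs; diameter is the largest finite distance; global
efficiency is the mean of 1/d over all node pairs with unreachable pairs
contributing 0.  Edgeless graphs return 0 for every index.  A zero-weight
edge (a patient exactly on a reference line) would make 1/d infinite; such
pairs are excluded from the efficiency sum, which keeps the index finite and
has probability zero under continuous data.  All indices are verified
against a brute-force Floyd-Warshall oracle to 1e−12.

## Survival layer

* Mann-Whitney U: two-sided normal approximation with midrank tie correction
  and continuity correction; groups summarized as median (IQR).  Within 0.02
  of the exact permutation null at eight per group (tested); at very small
  sizes (≤ 5 per group) the approximation is cruder, as expected.
* Cox regression: lifelines partial likelihood with Efron tie handling,
  complete-case on the used columns.  Output per covariate: β, SE(β),
  HR = exp(β), Wald 95% CI exp(β ± 1.96·SE), Wald p.  β is verified against
  a grid-search maximizer of an independently coded Efron partial likelihood
  to 1e−4.
* ROC: AUC equals the normalized Mann-Whitney statistic (ties ½); CI by
  Hanley-McNeil.  The optimal cutoff maximizes Youden's J over observed
  scores with ties broken toward the lower cutoff (favouring sensitivity);
  "predicted non-survivor" means score ≥ cutoff.  All scores are oriented
  higher-is-worse; a score whose AUC falls below 0.5 is flagged as
  reverse-oriented rather than silently flipped.
* Kaplan-Meier / log-rank: product-limit estimates per predicted group and
  the Mantel-Cox chi-square (1 df), verified on a hand-tabulated risk-set
  example.
* The combined index is the bivariate Cox linear predictor
  β₁·MELD + β₂·∂.  The survival layer reports raw two-sided p-values at
  0.05 with no multiplicity correction beyond the network-screening
  Bonferroni — a deliberate choice to keep the layer's semantics those of a
  conventional prognostic-factor analysis.

## Synthetic cohort generator

The generator is the package's test bed; its defaults define the study
conditions under which the validation suite runs.

* **Classes.** 400 "clean" patients follow six injected linear axes; 100
  "disrupted" patients are identical except that the residual noise on four
  axes (Alb-Bil, Alb-PT, Alb-HE, NH4-HE) is inflated ×3.
* **Variable chain.** Albumin is uniform on [20, 45] g/L; bilirubin
  (slope −3 µmol/L per g/L, noise SD 14), prothrombin time (−0.45 s per g/L,
  SD 1.8) and a latent HE severity (−0.09 per g/L, SD 0.30) are direct
  responses of albumin; ammonia is generated by inverting the NH4→HE line so
  that the HE-on-NH4 residual SD is exactly the configured 0.30.  The
  Bil-PT and PT-HE axes are *induced* through the shared albumin parent: no
  sampling step, correlation ≈ the product of the parent correlations.  HE
  is discretized into grades 0/1/2 (cutpoints 0.25 and 0.85 on the latent
  scale) only at the end.  Creatinine and sodium are independent noise and
  serve as negative controls.  Physical floors (e.g. bilirubin ≥ 0.5) clip
  a percent-level tail.
* **Outcome.** Event times are exponential with rate
  6e−6/day · exp(Σ c_axis |∂_true|), censored at day 365, with per-axis
  coefficients {0.18, 0.6, 2.25, 2.25} scaled to each axis's deviation
  units.  These values were chosen so that the disrupted class has ≈ 70%
  12-month mortality and the clean class ≈ 4% (cohort event rate ≈ 18%),
  giving each disrupted axis a clearly super-chance prognostic AUC while
  keeping substantial class overlap.  Because the draw for the event time
  uses a common uniform variate, scaling the coefficients up can only move
  each patient's event earlier — a per-patient monotonicity that is tested
  exactly.
* **Severity scores.** MELD and Child-Pugh are rounded monotone noisy
  functions of bilirubin, PT and albumin (Child-Pugh also adds the HE
  grade), clipped to [6, 40] and [5, 15].
* **Missingness** is completely at random at 2% per clinical cell,
  consistent with the analysis side correcting by pairwise deletion only.

### What the generator does and does not emulate

It reproduces the *structure* the method assumes — linear survivor
couplings, inflated deviations in non-survivors, proportional-hazards
deviation→mortality link — so passing tests demonstrate that the pipeline
recovers a signal of this form.  It does not emulate real marginal
distributions beyond order-of-magnitude plausibility, informative
missingness, subgroup structure, or severity-driven mortality: the hazard
depends on the deviations only, so MELD is (by construction) only weakly
prognostic on synthetic cohorts and the "deviation predicts independently of
MELD" contrast is structurally easy there.  Results on synthetic data
therefore validate the software and the statistical machinery, not the
clinical effect sizes.

Two further structural facts are worth noting.  First, six pairwise
couplings this strong (|ρ| ≥ 0.6) among five variables force transitive
correlations (e.g. Bil-HE) well above the detection threshold at n ≈ 400, so
screening correctly reports more than the six injected pairs (typically ~10
of 21); the validation suite asserts that the injected axes are always
found and that the negative-control variables never are.  Second, the
survivor-residual-SD check applies to the directly generated continuous
axes; induced and discretized axes cannot satisfy it by construction.

## Validation studies and problem sizes

The Monte-Carlo studies used by the tests and by `scripts/acceptance.py`
run at: screening power, 100 cohorts of 500; family-wise error, 200
independent-noise cohorts of 50; end-to-end recovery, 100 cohorts of 500
(Mann-Whitney, univariate Cox, ROC AUC per disrupted axis, and the sd-of-
centrality contrast).  Observed under defaults: screening power 1.00,
family-wise error ≈ 0.03–0.05 (binomially consistent with α = 0.05),
per-axis detection rates ≥ 0.96, mean disrupted-axis AUC ≈ 0.73, sd-of-
centrality detection 1.00.

## Worked-example snippet

The README output was produced by:

```python
from parenclitic import (AnalysisConfig, SyntheticConfig, apply_horizon,
                         generate_cohort, run_pipeline)

cohort = apply_horizon(generate_cohort(SyntheticConfig(seed=1)), 365)
res = run_pipeline(cohort, AnalysisConfig())

print(f"significant pairs: {len(res.refset.pairs)} of {res.refset.m} "
      f"(threshold p <= {res.refset.threshold:.4f})")
line = res.refset.get("alb_bil").line
print(f"Alb-Bil reference line: slope {line.slope:.2f}, intercept {line.intercept:.1f}")
cmp = res.delta_comparisons.set_index("feature")
row = cmp.loc["alb_bil"]
print(f"delta Alb-Bil  survivors {row.median_survivor:.2f} "
      f"({row.iqr25_survivor:.2f}-{row.iqr75_survivor:.2f})  "
      f"non-survivors {row.median_non_survivor:.2f} "
      f"({row.iqr25_non_survivor:.2f}-{row.iqr75_non_survivor:.2f})  p={row.p_value:.2e}")
uni = res.cox_univariate.set_index("feature").loc["alb_bil"]
print(f"univariate Cox Alb-Bil: HR {uni.hazard_ratio:.3f} "
      f"({uni.ci_low:.3f}-{uni.ci_high:.3f}), p={uni.p_value:.2e}")
auc = res.auc_table.set_index("score")
for s in ("alb_bil", "meld", "meld_alb_bil"):
    r = auc.loc[s]
    print(f"AUC {s}: {r.auc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}), cutoff {r.cutoff:.2f}")
km = res.km_results["alb_bil"]
print(f"log-rank (Alb-Bil cutoff): chi2 {km.chi_square:.2f}, p={km.p_value:.2e}")
```

## Known limitations

* Linear pairwise reference models only; no kernel-density or multivariate
  reference models.
* No signed or per-axis-normalized deviations; topology mixes axes with
  different units.
* The HE grade (an ordinal 3-level variable) enters the regressions as if
  continuous — faithful to the method's published form, but a recognized
  approximation.
* No time-dependent covariates, landmarking, or AUC-difference testing; the
  AUC comparison between nested scores is reported descriptively only.
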