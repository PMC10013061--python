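"""Survival-statistics layer: group comparisons, Cox models, ROC, KM.

Conventions
-----------
* Mann-Whitney U uses the two-sided normal approximation with midrank tie
  correction and continuity correction; groups are summarized as
  median (IQR).
* Cox proportional-hazards models are fitted by partial likelihood with the
  Efron tie approximation (the default of mainstream survival software);
  per-covariate output is beta, its standard error, HR = exp(beta), Wald 95%
  CI exp(beta +- 1.96 se) and the Wald p-value.
* Scores are oriented "higher = worse" (predicts non-survival).  ROC AUC is
  the probability a non-survivor scores above a survivor (ties count 1/2);
  the CI is Hanley-McNeil.  The optimal cutoff maximizes Youden's
  J = sensitivity + specificity - 1, ties broken toward the lower cutoff;
  patients with score >= cutoff are "predicted non-survivors".  A score whose
  AUC falls below 0.5 is flagged as reverse-oriented.
* Kaplan-Meier curves are product-limit estimates per predicted group and the
  groups are compared with the log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import NoEventsError, ParencliticError


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int
    u_stat: float
    p_value: float


@dataclass(frozen=True)
class CoxCoefficient:
    covariate: str
    beta: float
    sem: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    coefficients: tuple[CoxCoefficient, ...]
    n: int
    n_events: int
    converged: bool = True

    def __getitem__(self, covariate: str) -> CoxCoefficient:
        for c in self.coefficients:
            if c.covariate == covariate:
                return c
        raise KeyError(covariate)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    flipped: bool  # True when the score is reverse-oriented (AUC < 0.5)


@dataclass(frozen=True)
class KmResult:
    survival: dict[str, pd.DataFrame] = field(repr=False)
    chi_square: float = 0.0
    p_value: float = 1.0


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def mann_whitney_compare(
    values_a: np.ndarray, values_b: np.ndarray, feature: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of a feature between two groups.

    Missing values are dropped per group.  Group A is conventionally the
    survivor/reference group, B the comparison group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ParencliticError(f"both groups must be non-empty for {feature!r}")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    return GroupComparison(
        feature=feature,
        median_a=med_a,
        iqr_a=iqr_a,
        median_b=med_b,
        iqr_b=iqr_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_stat=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def cox_fit(
    time: np.ndarray, event: np.ndarray, covariates: pd.DataFrame
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties), complete-case.

    ``covariates`` holds one or two columns; rows with any missing covariate
    are dropped before fitting.
    """
    df = covariates.reset_index(drop=True).astype(float).copy()
    df["__time"] = np.asarray(time, dtype=float)
    df["__event"] = np.asarray(event, dtype=int)
    df = df.dropna()
    if int(df["__event"].sum()) == 0:
        raise NoEventsError("cannot fit a Cox model with zero events")
    for col in covariates.columns:
        if df[col].nunique() <= 1:
            raise ParencliticError(f"covariate {col!r} is constant in complete cases")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="__time", event_col="__event")
        except Exception as exc:  # convergence failure -> flagged result
            raise ParencliticError(f"Cox fit failed: {exc}") from exc
    coefs = []
    for name in covariates.columns:
        beta = float(cph.params_[name])
        sem = float(cph.standard_errors_[name])
        coefs.append(
            CoxCoefficient(
                covariate=str(name),
                beta=beta,
                sem=sem,
                hazard_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.96 * sem)),
                ci_high=float(np.exp(beta + 1.96 * sem)),
                p_value=float(cph.summary.loc[name, "p"]),
            )
        )
    return CoxResult(
        coefficients=tuple(coefs),
        n=int(len(df)),
        n_events=int(df["__event"].sum()),
        converged=converged,
    )


def combined_index(
    beta1: float, meld: np.ndarray, beta2: float, delta: np.ndarray
) -> np.ndarray:
    """Combined MELD-deviation prognostic index beta1 * MELD + beta2 * delta.

    The coefficients are the MELD and deviation coefficients of a converged
    bivariate Cox model; the index is the model's linear predictor up to a
    constant.
    """
    return beta1 * np.asarray(meld, dtype=float) + beta2 * np.asarray(delta, dtype=float)


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    return max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)


def roc_with_cutoff(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC analysis of a higher-is-worse score against a binary outcome.

    AUC is the normalized Mann-Whitney statistic (ties 1/2, equivalent to the
    trapezoidal area under the empirical ROC).  The cutoff maximizes
    Youden's J over the observed score values, ties broken toward the lower
    cutoff so sensitivity is favoured.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParencliticError("both outcome classes must be present for ROC analysis")
    auc = float(roc_auc_score(y, s))
    ci_low, ci_high = _hanley_mcneil_ci(auc, n_pos, n_neg)

    pos = s[y == 1]
    neg = s[y == 0]
    best_cut, best_j, best_sens, best_spec = np.nan, -np.inf, np.nan, np.nan
    for cut in np.unique(s):  # ascending, so strict improvement keeps the lowest
        sens = float((pos >= cut).mean())
        spec = float((neg < cut).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_cut, best_j, best_sens, best_spec = float(cut), j, sens, spec
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=best_cut,
        sensitivity=best_sens,
        specificity=best_spec,
        flipped=auc < 0.5,
    )


def km_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> KmResult:
    """Kaplan-Meier curves per predicted group and the log-rank test.

    ``group`` is binary: 1 for "predicted non-survivor" (score >= cutoff),
    0 for "predicted survivor".
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group, dtype=int)
    if e.sum() == 0:
        raise NoEventsError("log-rank test requires at least one event")
    if (g == 1).sum() == 0 or (g == 0).sum() == 0:
        raise ParencliticError("both predicted groups must be non-empty")
    curves: dict[str, pd.DataFrame] = {}
    for value, name in ((0, "predicted_survivor"), (1, "predicted_non_survivor")):
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == value], e[g == value])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
    res = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
    return KmResult(
        survival=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
    )
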