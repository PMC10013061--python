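"""Reference model construction: pair screening and per-pair regressions.

The reference class is the set of patients who survived the follow-up
horizon.  Every unordered variable pair is screened by Spearman correlation
computed with pairwise deletion ("pair matching": each pair uses exactly the
rows where both members are observed), at a Bonferroni-corrected level
alpha / m where m counts *all* pairs -- with seven variables m = 21 and the
default level is 0.05 / 21 = 0.00238..., displayed as 0.0024.  Pairs that do
not meet the threshold are excluded from all further analysis; an ordinary
least-squares line is fitted (on the reference class, again with pairwise
deletion) for each pair that passes.

Pairs with fewer complete observations than ``min_pair_n`` are flagged as
having insufficient data and cannot pass screening, but they still count in
the Bonferroni denominator: the corrected level is a property of the variable
set, not of the missingness pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateFitError, NoReferenceClassError, ParencliticError
from .variables import CLINICAL_VARIABLES, ordered_pairs, pair_key, pair_label


@dataclass(frozen=True)
class PairCorrelation:
    """Spearman correlation of one variable pair on complete observations."""

    x_var: str
    y_var: str
    rho: float
    p_value: float
    n_complete: int


@dataclass(frozen=True)
class RegressionLine:
    """OLS line y = intercept + slope * x."""

    slope: float
    intercept: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class ReferencePair:
    corr: PairCorrelation
    line: RegressionLine

    @property
    def key(self) -> str:
        return pair_key(self.corr.x_var, self.corr.y_var)

    @property
    def label(self) -> str:
        return pair_label(self.corr.x_var, self.corr.y_var)


@dataclass
class ReferenceModelSet:
    """Screened, fitted reference models.

    ``pairs`` holds only the significant pairs; ``screening`` is the full
    report over all m pairs (rho, p, n_complete, significance flag, fitted
    line where applicable).
    """

    alpha: float
    m: int
    threshold: float
    pairs: list[ReferencePair]
    screening: pd.DataFrame

    @property
    def pair_keys(self) -> list[str]:
        return [p.key for p in self.pairs]

    @property
    def nodes(self) -> list[str]:
        """Variables appearing in at least one significant pair, in canonical order."""
        used = {v for p in self.pairs for v in (p.corr.x_var, p.corr.y_var)}
        return [v for v in CLINICAL_VARIABLES if v in used]

    def get(self, key: str) -> ReferencePair:
        for p in self.pairs:
            if p.key == key:
                return p
        raise KeyError(key)


def count_variable_pairs(p: int) -> int:
    """Number of unordered variable pairs, m = p(p-1)/2."""
    if p < 2:
        raise ParencliticError(f"need at least 2 variables, got {p}")
    return p * (p - 1) // 2


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-pair significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ParencliticError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ParencliticError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def spearman_pairwise(
    data: pd.DataFrame, x_var: str, y_var: str, min_pair_n: int = 10
) -> PairCorrelation | None:
    """Spearman correlation on the rows where both variables are observed.

    Ties are handled by midranks and the two-sided p-value uses the
    large-sample t approximation.  Returns ``None`` when fewer than
    ``min_pair_n`` complete pairs exist (the pair is flagged as insufficient
    data by the caller).
    """
    x = data[x_var].to_numpy(dtype=float)
    y = data[y_var].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n_complete = int(ok.sum())
    if n_complete < min_pair_n:
        return None
    res = stats.spearmanr(x[ok], y[ok])
    return PairCorrelation(
        x_var=x_var,
        y_var=y_var,
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n_complete=n_complete,
    )


def fit_pair_model(data: pd.DataFrame, x_var: str, y_var: str) -> RegressionLine:
    """Ordinary least squares of ``y_var`` on ``x_var`` with pairwise deletion."""
    x = data[x_var].to_numpy(dtype=float)
    y = data[y_var].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateFitError(
            f"need >= 3 complete pairs to fit {x_var}->{y_var}, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"constant predictor {x_var!r}: cannot fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionLine(slope=float(slope), intercept=float(intercept))


def build_reference_set(
    cohort: pd.DataFrame, config: AnalysisConfig | None = None
) -> ReferenceModelSet:
    """Screen all variable pairs on the survivor class and fit the models.

    ``cohort`` must already be horizon-censored; the reference class is the
    subset with ``event == 0``.
    """
    config = config or AnalysisConfig()
    survivors = cohort[cohort["event"] == 0]
    if len(survivors) == 0:
        raise NoReferenceClassError("no survivors: cannot build a reference model")

    all_pairs = ordered_pairs()
    m = count_variable_pairs(len(CLINICAL_VARIABLES))
    threshold = bonferroni_threshold(config.alpha, m)

    rows = []
    pairs: list[ReferencePair] = []
    for x_var, y_var in all_pairs:
        corr = spearman_pairwise(survivors, x_var, y_var, config.min_pair_n)
        row = {
            "pair": pair_key(x_var, y_var),
            "label": pair_label(x_var, y_var),
            "x_var": x_var,
            "y_var": y_var,
            "rho": np.nan,
            "p_value": np.nan,
            "n_complete": 0,
            "insufficient_data": corr is None,
            "significant": False,
            "slope": np.nan,
            "intercept": np.nan,
        }
        if corr is not None:
            row.update(rho=corr.rho, p_value=corr.p_value, n_complete=corr.n_complete)
            if corr.p_value <= threshold:
                try:
                    line = fit_pair_model(survivors, x_var, y_var)
                except DegenerateFitError as exc:
                    warnings.warn(f"dropping pair {row['pair']}: {exc}", stacklevel=2)
                else:
                    row.update(significant=True, slope=line.slope, intercept=line.intercept)
                    pairs.append(ReferencePair(corr=corr, line=line))
        rows.append(row)

    screening = pd.DataFrame(rows)
    if not pairs:
        warnings.warn(
            "no variable pair passed Bonferroni screening; the network layer is empty",
            stacklevel=2,
        )
    return ReferenceModelSet(
        alpha=config.alpha, m=m, threshold=threshold, pairs=pairs, screening=screening
    )
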