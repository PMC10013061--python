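"""End-to-end analysis pipeline and result tables.

``run_pipeline`` chains the full analysis on a validated cohort table:

1. administrative censoring at the follow-up horizon;
2. Bonferroni-screened Spearman pair correlations and per-pair OLS reference
   lines on the survivor class;
3. per-patient orthogonal deviations and deviation-weighted network topology
   indices;
4. survivor vs non-survivor Mann-Whitney comparisons of every deviation axis
   and topology index;
5. univariate Cox models per feature, bivariate Cox models adding MELD and
   (separately) Child-Pugh;
6. ROC analysis with Youden cutoffs for each deviation axis, MELD, and the
   combined MELD-deviation indices, followed by Kaplan-Meier / log-rank on
   the cutoff-dichotomized groups.

The pipeline is a pure function of (cohort, config): identical inputs yield
byte-identical output tables.  Degenerate inputs degrade gracefully (empty
tables and a recorded warning) except for the absence of any survivor, which
is unrecoverable because there is no reference class.
"""

from __future__ import annotations

import os
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .deviation import compute_cohort_profiles
from .errors import NoReferenceClassError, ParencliticError
from .io import apply_horizon
from .reference import ReferenceModelSet, build_reference_set
from .survival import (
    KmResult,
    cox_fit,
    combined_index,
    km_logrank,
    mann_whitney_compare,
    roc_with_cutoff,
)
from .topology import INDEX_COLUMNS, topology_table


@dataclass
class PipelineResult:
    refset: ReferenceModelSet
    deltas: pd.DataFrame
    topology: pd.DataFrame
    delta_comparisons: pd.DataFrame
    topology_comparisons: pd.DataFrame
    cox_univariate: pd.DataFrame
    cox_with_meld: pd.DataFrame
    cox_with_child_pugh: pd.DataFrame
    auc_table: pd.DataFrame
    km_results: dict[str, KmResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


_EMPTY_COMPARE = pd.DataFrame(
    columns=[
        "feature",
        "label",
        "median_survivor",
        "iqr25_survivor",
        "iqr75_survivor",
        "median_non_survivor",
        "iqr25_non_survivor",
        "iqr75_non_survivor",
        "u_stat",
        "p_value",
    ]
)
_EMPTY_COX = pd.DataFrame(
    columns=["feature", "covariate", "beta", "sem", "hazard_ratio", "ci_low", "ci_high", "p_value", "n", "n_events"]
)
_EMPTY_AUC = pd.DataFrame(
    columns=["score", "auc", "ci_low", "ci_high", "cutoff", "sensitivity", "specificity", "flipped"]
)


def _compare_table(
    features: pd.DataFrame, labels: dict[str, str], survivor_mask: np.ndarray
) -> pd.DataFrame:
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        cmp = mann_whitney_compare(vals[survivor_mask], vals[~survivor_mask], col)
        rows.append(
            {
                "feature": col,
                "label": labels.get(col, col),
                "median_survivor": cmp.median_a,
                "iqr25_survivor": cmp.iqr_a[0],
                "iqr75_survivor": cmp.iqr_a[1],
                "median_non_survivor": cmp.median_b,
                "iqr25_non_survivor": cmp.iqr_b[0],
                "iqr75_non_survivor": cmp.iqr_b[1],
                "u_stat": cmp.u_stat,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows) if rows else _EMPTY_COMPARE.copy()


def _cox_rows(feature, result, row_covariates):
    rows = []
    for cov in row_covariates:
        c = result[cov]
        rows.append(
            {
                "feature": feature,
                "covariate": cov,
                "beta": c.beta,
                "sem": c.sem,
                "hazard_ratio": c.hazard_ratio,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "n": result.n,
                "n_events": result.n_events,
            }
        )
    return rows


def run_pipeline(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> PipelineResult:
    """Run the full parenclitic analysis on a validated cohort table."""
    config = config or AnalysisConfig()
    warn_log: list[str] = []
    data = apply_horizon(cohort, config.horizon_days)
    survivor_mask = (data["event"] == 0).to_numpy()
    if survivor_mask.sum() == 0:
        raise NoReferenceClassError("no survivors: cannot build a reference model")
    if survivor_mask.sum() < 2:
        raise NoReferenceClassError("at least 2 survivors are required")

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        refset = build_reference_set(data, config)
    warn_log.extend(str(w.message) for w in caught)

    data = data.sort_values("patient_id").reset_index(drop=True)
    survivor_mask = (data["event"] == 0).to_numpy()
    if not refset.pairs:
        warn_log.append("empty network layer: no significant pairs")
        return PipelineResult(
            refset=refset,
            deltas=pd.DataFrame(index=pd.Index(data["patient_id"], name="patient_id")),
            topology=pd.DataFrame(index=pd.Index(data["patient_id"], name="patient_id")),
            delta_comparisons=_EMPTY_COMPARE.copy(),
            topology_comparisons=_EMPTY_COMPARE.copy(),
            cox_univariate=_EMPTY_COX.copy(),
            cox_with_meld=_EMPTY_COX.copy(),
            cox_with_child_pugh=_EMPTY_COX.copy(),
            auc_table=_EMPTY_AUC.copy(),
            warnings=warn_log,
        )

    deltas = compute_cohort_profiles(data, refset)
    topo = topology_table(deltas, refset)
    topo_indices = topo.loc[:, list(INDEX_COLUMNS)]
    pair_labels = {p.key: p.label for p in refset.pairs}

    has_events = int(data["event"].sum()) >= 1
    has_both_groups = has_events and (~survivor_mask).sum() >= 1
    if not has_both_groups:
        warn_log.append("no non-survivors at the horizon: survival contrasts skipped")
        return PipelineResult(
            refset=refset,
            deltas=deltas,
            topology=topo,
            delta_comparisons=_EMPTY_COMPARE.copy(),
            topology_comparisons=_EMPTY_COMPARE.copy(),
            cox_univariate=_EMPTY_COX.copy(),
            cox_with_meld=_EMPTY_COX.copy(),
            cox_with_child_pugh=_EMPTY_COX.copy(),
            auc_table=_EMPTY_AUC.copy(),
            warnings=warn_log,
        )

    delta_cmp = _compare_table(deltas, pair_labels, survivor_mask)
    topo_cmp = _compare_table(topo_indices, {}, survivor_mask)

    time = data["time"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=int)
    meld = data["meld"].to_numpy(dtype=float)
    child_pugh = data["child_pugh"].to_numpy(dtype=float)

    features = pd.concat([deltas.reset_index(drop=True), topo_indices.reset_index(drop=True)], axis=1)
    uni_rows, meld_rows, cp_rows = [], [], []
    bivariate_betas: dict[str, tuple[float, float]] = {}  # feature -> (beta_meld, beta_feat)
    for col in features.columns:
        x = features[[col]]
        try:
            res = cox_fit(time, event, x.rename(columns={col: "feat"}))
            uni_rows.extend(_cox_rows(col, res, ["feat"]))
        except ParencliticError as exc:
            warn_log.append(f"univariate Cox skipped for {col}: {exc}")
        try:
            xm = x.copy()
            xm["meld"] = meld
            res = cox_fit(time, event, xm.rename(columns={col: "feat"}))
            meld_rows.extend(_cox_rows(col, res, ["feat", "meld"]))
            bivariate_betas[col] = (res["meld"].beta, res["feat"].beta)
        except ParencliticError as exc:
            warn_log.append(f"bivariate Cox with MELD skipped for {col}: {exc}")
        try:
            xc = x.copy()
            xc["child_pugh"] = child_pugh
            res = cox_fit(time, event, xc.rename(columns={col: "feat"}))
            cp_rows.extend(_cox_rows(col, res, ["feat", "child_pugh"]))
        except ParencliticError as exc:
            warn_log.append(f"bivariate Cox with Child-Pugh skipped for {col}: {exc}")

    # ROC / KM layer: each deviation axis, MELD, and combined MELD-deviation
    # indices built from the bivariate coefficients.
    scores: dict[str, np.ndarray] = {}
    for key in deltas.columns:
        scores[key] = deltas[key].to_numpy(dtype=float)
    scores["meld"] = meld
    for key in deltas.columns:
        if key in bivariate_betas:
            b_meld, b_feat = bivariate_betas[key]
            scores[f"meld_{key}"] = combined_index(
                b_meld, meld, b_feat, deltas[key].to_numpy(dtype=float)
            )

    auc_rows = []
    km_results: dict[str, KmResult] = {}
    for name, sc in scores.items():
        try:
            roc = roc_with_cutoff(sc, event)
        except ParencliticError as exc:
            warn_log.append(f"ROC skipped for {name}: {exc}")
            continue
        auc_rows.append(
            {
                "score": name,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "cutoff": roc.cutoff,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "flipped": roc.flipped,
            }
        )
        ok = ~np.isnan(sc)
        group = (sc[ok] >= roc.cutoff).astype(int)
        try:
            km_results[name] = km_logrank(time[ok], event[ok], group)
        except ParencliticError as exc:
            warn_log.append(f"KM/log-rank skipped for {name}: {exc}")

    return PipelineResult(
        refset=refset,
        deltas=deltas,
        topology=topo,
        delta_comparisons=delta_cmp,
        topology_comparisons=topo_cmp,
        cox_univariate=pd.DataFrame(uni_rows) if uni_rows else _EMPTY_COX.copy(),
        cox_with_meld=pd.DataFrame(meld_rows) if meld_rows else _EMPTY_COX.copy(),
        cox_with_child_pugh=pd.DataFrame(cp_rows) if cp_rows else _EMPTY_COX.copy(),
        auc_table=pd.DataFrame(auc_rows) if auc_rows else _EMPTY_AUC.copy(),
        km_results=km_results,
        warnings=warn_log,
    )


def write_results(result: PipelineResult, outdir: str) -> list[str]:
    """Write every result table as CSV into ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, index=index)
        written.append(path)

    _write(result.refset.screening, "screening.csv")
    _write(result.deltas, "deltas.csv", index=True)
    _write(result.topology, "topology.csv", index=True)
    _write(result.delta_comparisons, "delta_comparisons.csv")
    _write(result.topology_comparisons, "topology_comparisons.csv")
    _write(result.cox_univariate, "cox_univariate.csv")
    _write(result.cox_with_meld, "cox_bivariate_meld.csv")
    _write(result.cox_with_child_pugh, "cox_bivariate_child_pugh.csv")
    _write(result.auc_table, "auc.csv")
    for name, km in sorted(result.km_results.items()):
        for grp, sf in sorted(km.survival.items()):
            _write(sf, f"km_{name}_{grp}.csv")
    if result.warnings:
        with open(os.path.join(outdir, "warnings.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(result.warnings) + "\n")
        written.append(os.path.join(outdir, "warnings.txt"))
    return written
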