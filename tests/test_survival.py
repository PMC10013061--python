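"""Survival-statistics layer: oracles and invariants."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from parenclitic import (
    combined_index,
    cox_fit,
    km_logrank,
    mann_whitney_compare,
    roc_with_cutoff,
)
from parenclitic.errors import NoEventsError, ParencliticError

# ---------------------------------------------------------------- Mann-Whitney


def exact_mannwhitney_p(a, b):
    """Exact two-sided permutation null of the U statistic (midranks)."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    ranks = rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    mu = n_a * (n - n_a) / 2
    obs = abs(u_of(range(n_a)) - mu)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def test_mann_whitney_complete_separation():
    cmp = mann_whitney_compare([1, 2, 3], [10, 11, 12], "x")
    # U is at its extreme; p is as small as 3-vs-3 group sizes allow (~0.1)
    assert cmp.u_stat in (0.0, 9.0)
    assert cmp.p_value < 0.1


def test_mann_whitney_identical_groups():
    cmp = mann_whitney_compare([1, 2, 3, 4], [1, 2, 3, 4], "x")
    assert cmp.p_value > 0.9


@pytest.mark.parametrize(
    "a,b",
    [
        (
            [0.93, -1.85, 1.33, 0.22, -0.42, -1.52, -0.26, -0.77],
            [0.82, 0.63, 0.74, 1.35, 0.64, -0.33, 1.24, 0.31],
        ),
        ([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0], [2.0, 3.0, 3.0, 4.0, 6.0, 7.0, 9.0, 10.0]),
        ([0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5], [1.0, 2.0, 6.0, 7.0, 8.0, 9.0, 9.5, 10.0]),
    ],
)
def test_mann_whitney_close_to_exact_permutation_null(a, b):
    cmp = mann_whitney_compare(a, b, "x")
    assert abs(cmp.p_value - exact_mannwhitney_p(np.array(a), np.array(b))) < 0.02


def test_mann_whitney_summaries_and_errors():
    cmp = mann_whitney_compare([1.0, 2.0, 3.0, np.nan], [4.0, 6.0], "feat")
    assert cmp.feature == "feat"
    assert cmp.n_a == 3 and cmp.n_b == 2
    assert cmp.median_a == 2.0 and cmp.median_b == 5.0
    with pytest.raises(ParencliticError):
        mann_whitney_compare([], [1.0], "x")


# ------------------------------------------------------------------------ Cox


def efron_log_partial_likelihood(beta, time, event, x):
    """Efron-tie partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(tied.sum())
        risk_sum = np.exp(beta * x[at_risk]).sum()
        tied_sum = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for j in range(d):
            ll -= np.log(risk_sum - (j / d) * tied_sum)
    return ll


@pytest.fixture(scope="module")
def cox_fixture():
    rng = np.random.default_rng(99)
    n = 20
    x = rng.normal(0, 1, n)
    time = rng.integers(1, 12, n).astype(float)  # discrete: forces ties
    event = (rng.random(n) < 0.7).astype(int)
    event[0] = 1  # guarantee at least one event
    return time, event, x


def test_cox_beta_matches_efron_grid_oracle(cox_fixture):
    time, event, x = cox_fixture
    res = cox_fit(time, event, pd.DataFrame({"x": x}))
    oracle = minimize_scalar(
        lambda b: -efron_log_partial_likelihood(b, time, event, x),
        bounds=(-5, 5),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert res["x"].beta == pytest.approx(oracle.x, abs=1e-4)


def test_cox_result_fields_consistent(cox_fixture):
    time, event, x = cox_fixture
    res = cox_fit(time, event, pd.DataFrame({"x": x}))
    c = res["x"]
    assert c.hazard_ratio == pytest.approx(np.exp(c.beta))
    assert c.ci_low < c.hazard_ratio < c.ci_high
    assert c.ci_low > 0
    assert res.n == 20 and res.n_events == event.sum()


def test_cox_affine_rescaling_of_covariate(cox_fixture):
    time, event, x = cox_fixture
    res1 = cox_fit(time, event, pd.DataFrame({"x": x}))
    res2 = cox_fit(time, event, pd.DataFrame({"x": 10 * x + 3}))
    assert res2["x"].beta == pytest.approx(res1["x"].beta / 10, rel=1e-5)
    assert res2["x"].sem == pytest.approx(res1["x"].sem / 10, rel=1e-5)
    assert res2["x"].p_value == pytest.approx(res1["x"].p_value, abs=1e-6)


def test_cox_true_hazard_ratio_recovered():
    """Two-group exponential data with true HR 2: beta within 3 SEM of ln 2."""
    rng = np.random.default_rng(11)
    n = 1000
    x = (rng.random(n) < 0.5).astype(float)
    rate = 0.01 * np.exp(np.log(2) * x)
    t = rng.exponential(1 / rate)
    event = (t <= 365).astype(int)
    time = np.minimum(t, 365)
    res = cox_fit(time, event, pd.DataFrame({"x": x}))
    assert abs(res["x"].beta - np.log(2)) < 3 * res["x"].sem


def test_cox_null_covariate_coverage():
    """CI for HR contains 1 in ~95% of simulations under the null."""
    rng = np.random.default_rng(13)
    n, n_sims = 1000, 100
    covered = 0
    for _ in range(n_sims):
        x = rng.normal(0, 1, n)
        t = rng.exponential(100, n)
        event = (t <= 365).astype(int)
        time = np.minimum(t, 365)
        res = cox_fit(time, event, pd.DataFrame({"x": x}))
        if res["x"].ci_low <= 1.0 <= res["x"].ci_high:
            covered += 1
    assert 88 <= covered <= 100


def test_cox_error_conditions():
    with pytest.raises(NoEventsError):
        cox_fit([5.0, 6.0], [0, 0], pd.DataFrame({"x": [1.0, 2.0]}))
    with pytest.raises(ParencliticError, match="constant"):
        cox_fit([5.0, 6.0, 7.0], [1, 0, 1], pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


# -------------------------------------------------------------- combined index


def test_combined_index_arithmetic():
    # bivariate coefficients beta1 (MELD) and beta2 (deviation)
    value = combined_index(0.119, np.array([12.0]), 0.061, np.array([2.08]))[0]
    assert value == pytest.approx(1.55488, abs=1e-12)
    assert round(value, 4) == 1.5549


def test_combined_index_degenerate_coefficients():
    meld = np.array([10.0, 20.0])
    delta = np.array([1.0, 2.0])
    np.testing.assert_allclose(combined_index(0.2, meld, 0.0, delta), 0.2 * meld)
    np.testing.assert_allclose(combined_index(0.0, meld, 0.0, delta), [0.0, 0.0])


# ------------------------------------------------------------------------- ROC


def pair_counting_auc(scores, labels):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_and_null():
    perfect = roc_with_cutoff([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert perfect.auc == 1.0
    assert perfect.cutoff == 4
    assert perfect.sensitivity == 1.0 and perfect.specificity == 1.0
    null = roc_with_cutoff([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
    assert null.auc == 0.5


def test_roc_matches_pair_counting_oracle():
    scores = np.array([1, 2, 2, 3, 4, 5, 5, 6, 7, 8, 8, 9], dtype=float)
    labels = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1])
    res = roc_with_cutoff(scores, labels)
    assert res.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)


def test_auc_equals_normalized_mannwhitney_u():
    rng = np.random.default_rng(21)
    scores = rng.normal(0, 1, 40)
    labels = (rng.random(40) < 0.4).astype(int)
    n1, n0 = labels.sum(), (1 - labels).sum()
    cmp = mann_whitney_compare(scores[labels == 1], scores[labels == 0], "s")
    # mannwhitneyu returns U for the first sample (the positives here)
    assert roc_with_cutoff(scores, labels).auc == pytest.approx(
        cmp.u_stat / (n1 * n0), abs=1e-12
    )


def test_auc_label_flip_antisymmetry():
    rng = np.random.default_rng(22)
    scores = rng.normal(0, 1, 30)  # continuous: no ties
    labels = (rng.random(30) < 0.5).astype(int)
    labels[0], labels[1] = 0, 1
    a1 = roc_with_cutoff(scores, labels).auc
    a2 = roc_with_cutoff(-scores, labels).auc
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)
    assert roc_with_cutoff(-scores, labels).flipped == (a2 < 0.5)


def test_roc_cutoff_tie_break_toward_lower_value():
    # two cutoffs reach J = 0.5; the lower one (sensitivity-favouring) wins
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 0, 1, 1])
    res = roc_with_cutoff(scores, labels)
    assert res.auc == 1.0
    assert res.cutoff == 3.0


def test_roc_requires_both_classes():
    with pytest.raises(ParencliticError):
        roc_with_cutoff([1.0, 2.0], [1, 1])


# ------------------------------------------------------------- KM and log-rank


def test_logrank_matches_hand_tabulated_example():
    # Group A: events at 1, 3, censored 5.  Group B: events at 2, 6, censored 4.
    # Observed-minus-expected over risk sets gives chi2 = 0.36 / 0.74 = 18/37.
    time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
    event = np.array([1, 1, 0, 1, 0, 1])
    group = np.array([0, 0, 0, 1, 1, 1])
    res = km_logrank(time, event, group)
    assert res.chi_square == pytest.approx(18 / 37, abs=1e-6)


def test_logrank_identical_patterns_gives_zero():
    time = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    group = np.array([0, 0, 0, 1, 1, 1])
    res = km_logrank(time, event, group)
    assert res.chi_square == pytest.approx(0.0, abs=1e-9)
    assert res.p_value > 0.99


def test_km_survival_curves_are_valid_step_functions():
    rng = np.random.default_rng(31)
    time = rng.exponential(100, 80).clip(1, 365)
    event = (rng.random(80) < 0.5).astype(int)
    event[:2] = 1
    group = (rng.random(80) < 0.5).astype(int)
    group[:2] = [0, 1]
    res = km_logrank(time, event, group)
    for sf in res.survival.values():
        s = sf["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


def test_km_errors():
    with pytest.raises(NoEventsError):
        km_logrank([1.0, 2.0], [0, 0], [0, 1])
    with pytest.raises(ParencliticError):
        km_logrank([1.0, 2.0], [1, 1], [1, 1])
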