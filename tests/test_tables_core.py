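"""Contingency-table model: reconstruction, panels, intervals, cutoffs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bonedx import study
from bonedx.tables_core import (
    BinaryTestTable,
    DiagnosticCutoff,
    PairedCrossTab,
    ProportionCI,
    accuracy_panel,
    clopper_pearson_ci,
    dichotomize,
    largest_remainder_round,
    marginal_table,
    mercaldo_pv_ci,
    odds_ratio_stats,
    reconstruct_crosstab,
    wald_ci,
    youden_cutoff,
)

import pandas as pd


# ---------------------------------------------------------------------------
# Count reconstruction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "percentages, total, expected",
    [
        # the two study rows, verified against brute-force largest-remainder
        ((48.8, 18.6, 23.3, 9.3), 86, (42, 16, 20, 8)),
        ((27.9, 14.0, 17.1, 41.0), 906, (253, 127, 155, 371)),
        ((100.0, 0.0, 0.0, 0.0), 50, (50, 0, 0, 0)),
    ],
)
def test_largest_remainder_known_values(percentages, total, expected):
    assert tuple(largest_remainder_round(percentages, total)) == expected


@given(
    st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8),
    st.integers(0, 5000),
)
def test_largest_remainder_apportionment_properties(shares, total):
    """Counts sum exactly to the total and never stray a full unit from
    the proportional quota (the defining property of the method)."""
    if sum(shares) == 0:
        shares = [s + 1.0 for s in shares]
    counts = largest_remainder_round(shares, total)
    assert counts.sum() == total
    quotas = np.asarray(shares) / sum(shares) * total
    assert np.all(np.abs(counts - quotas) < 1.0)


def test_reconstruct_study_counts_and_roundtrip(study_xt):
    """Printed percentages × group totals give the published counts, and
    the recomputed percentages agree with the printed ones to print
    rounding (one cell, 371/906 = 40.95%, was printed as 41.0 — 0.051
    points off, a documented print inconsistency of that row)."""
    assert study_xt.cells("diseased") == (42, 16, 20, 8)
    assert study_xt.cells("healthy") == (253, 127, 155, 371)
    assert study_xt.n_d == 86 and study_xt.n_h == 906
    got = study_xt.cell_percentages("diseased")
    assert tuple(round(g, 1) for g in got) == study.PERCENT_FRACTURED
    for g, p in zip(study_xt.cell_percentages("healthy"), study.PERCENT_NONFRACTURED):
        assert abs(g - p) <= 0.06


def test_reconstruct_rejects_bad_inputs():
    with pytest.raises(ValueError, match="diseased"):
        reconstruct_crosstab((50, 30, 15, 2), (25, 25, 25, 25), 86, 906)
    with pytest.raises(ValueError, match="healthy"):
        reconstruct_crosstab((25, 25, 25, 25), (60, 30, 15, 2), 86, 906)
    with pytest.raises(ValueError):
        reconstruct_crosstab((-1, 51, 25, 25), (25, 25, 25, 25), 86, 906)
    with pytest.raises(ValueError):
        reconstruct_crosstab((25, 25, 25, 25), (25, 25, 25, 25), 0, 906)


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------


def test_marginal_tables_study(study_xt):
    tbs = marginal_table(study_xt, "b")
    assert (tbs.tp, tbs.fp, tbs.fn, tbs.tn) == (62, 408, 24, 498)
    bmd = marginal_table(study_xt, "LS-BMD")
    assert (bmd.tp, bmd.fp, bmd.fn, bmd.tn) == (58, 380, 28, 526)
    # totals preserved
    assert tbs.n == bmd.n == study_xt.n == 992


def test_marginal_all_zero():
    xt = PairedCrossTab(0, 0, 0, 0, 0, 0, 0, 0)
    t = xt.marginal("a")
    assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 0)


def test_crosstab_json_roundtrip(study_xt):
    again = PairedCrossTab.from_json(study_xt.to_json())
    assert again == study_xt
    # percent + totals schema
    alt = PairedCrossTab.from_dict(
        {
            "percent_diseased": study.PERCENT_FRACTURED,
            "percent_healthy": study.PERCENT_NONFRACTURED,
            "n_diseased": 86,
            "n_healthy": 906,
        }
    )
    assert alt.cells("diseased") == study_xt.cells("diseased")


def test_crosstab_rejects_negative_counts():
    with pytest.raises(ValueError):
        PairedCrossTab(1, 2, -1, 0, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Accuracy panel
# ---------------------------------------------------------------------------


def test_accuracy_panel_study_values(study_xt):
    """Headline per-test statistics agree with the published panel."""
    tbs = accuracy_panel(marginal_table(study_xt, "b"))
    assert tbs.se.percent() == (72.09, 61.38, 81.23)
    assert tbs.sp.percent() == (54.97, 51.66, 58.24)
    assert tbs.ppv.percent()[0] == 13.19
    assert tbs.npv.percent() == (95.40, 93.63, 96.70)
    assert round(tbs.odds_ratio, 2) == 3.15
    assert (round(tbs.or_lower, 2), round(tbs.or_upper, 2)) == (1.93, 5.14)
    assert tbs.chi2_p < 0.001

    bmd = accuracy_panel(marginal_table(study_xt, "a"))
    assert bmd.se.percent()[0] == 67.44
    assert bmd.ppv.percent()[0] == 13.24
    assert bmd.npv.percent()[0] == 94.95
    assert round(bmd.odds_ratio, 2) == 2.87
    assert round(100 * bmd.positivity_rate, 2) == 44.15  # prints as 44.2


def test_accuracy_panel_perfect_test():
    t = BinaryTestTable(tp=5, fp=0, fn=0, tn=7)
    p = accuracy_panel(t)
    assert p.se.estimate == p.sp.estimate == p.ppv.estimate == p.npv.estimate == 1.0
    assert math.isnan(p.odds_ratio)  # default zero-cell policy: undefined
    or_h, lo, hi, _, _ = odds_ratio_stats(t, zero_cell="haldane")
    assert or_h > 1 and lo < or_h < hi


def test_accuracy_panel_undefined_predictive_values():
    # no positive calls at all: PPV must be flagged NaN, not 0
    t = BinaryTestTable(tp=0, fp=0, fn=10, tn=20)
    p = accuracy_panel(t)
    assert not p.ppv.defined
    assert p.npv.defined


@given(
    st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
)
def test_bayes_identity(tp, fp, fn, tn):
    """Posterior odds = prior odds × positive likelihood ratio, exactly."""
    t = BinaryTestTable(tp=tp, fp=fp, fn=fn, tn=tn)
    lhs = t.ppv / (1 - t.ppv) if t.ppv < 1 else math.inf
    prior_odds = t.prevalence / (1 - t.prevalence)
    rhs = prior_odds * t.se / (1 - t.sp) if t.sp < 1 else math.inf
    if math.isfinite(lhs):
        assert lhs == pytest.approx(rhs, rel=1e-12)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def test_clopper_pearson_study_value():
    assert clopper_pearson_ci(62, 86).percent() == (72.09, 61.38, 81.23)


def test_clopper_pearson_boundaries():
    lo = clopper_pearson_ci(0, 10)
    assert lo.lower == 0.0 and lo.upper < 1.0
    hi = clopper_pearson_ci(10, 10)
    assert hi.upper == 1.0 and hi.lower > 0.0
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(-1, 10)


def test_clopper_pearson_matches_beta_quantile_oracle(rng):
    """1,000 random (k, n): bounds equal direct beta quantiles to 1e-9."""
    for _ in range(1000):
        n = int(rng.integers(1, 500))
        k = int(rng.integers(0, n + 1))
        ci = clopper_pearson_ci(k, n)
        lower = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        upper = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        assert ci.lower == pytest.approx(lower, abs=1e-9)
        assert ci.upper == pytest.approx(upper, abs=1e-9)


def test_clopper_pearson_coverage(rng):
    """Exact intervals are conservative: coverage ≥ 94.5% at p=0.3, n=50."""
    ks = rng.binomial(50, 0.3, size=10_000)
    bounds = {int(k): clopper_pearson_ci(int(k), 50) for k in np.unique(ks)}
    covered = np.mean([bounds[int(k)].lower <= 0.3 <= bounds[int(k)].upper for k in ks])
    assert covered >= 0.945


def test_wald_ci_clipped_to_unit_interval():
    ci = wald_ci(1, 10)
    assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0
    assert wald_ci(0, 10).lower == 0.0


def test_mercaldo_symmetric_case():
    ppv, npv = mercaldo_pv_ci(0.5, 0.5, 100, 100, 0.5)
    assert ppv.estimate == pytest.approx(0.5)
    # symmetric on the logit scale around 0.5
    assert ppv.lower == pytest.approx(1 - ppv.upper, abs=1e-12)
    assert npv.lower == pytest.approx(ppv.lower, abs=1e-12)


def test_mercaldo_boundary_handling():
    with pytest.raises(ValueError, match="adjusted"):
        mercaldo_pv_ci(1.0, 0.8, 50, 50, 0.2)
    ppv, npv = mercaldo_pv_ci(1.0, 0.8, 50, 50, 0.2, adjusted=True)
    assert 0.0 < ppv.lower < ppv.upper < 1.0


def test_mercaldo_prevalence_limit():
    ppv, _ = mercaldo_pv_ci(0.7, 0.6, 86, 906, 1 - 1e-9)
    assert ppv.estimate > 0.999999
    assert ppv.upper > 0.999999


def test_mercaldo_matches_monte_carlo(rng):
    """Analytic bounds for the study TBS inputs agree with a parametric
    Monte-Carlo of (SE, SP) sampling to within one percentage point."""
    se, sp, n_d, n_h, prev = 62 / 86, 498 / 906, 86, 906, 86 / 992
    ppv_ci, npv_ci = mercaldo_pv_ci(se, sp, n_d, n_h, prev)
    assert ppv_ci.lower < 0.1319 < ppv_ci.upper
    ses = rng.binomial(n_d, se, 10_000) / n_d
    sps = rng.binomial(n_h, sp, 10_000) / n_h
    ppvs = prev * ses / (prev * ses + (1 - prev) * (1 - sps))
    lo, hi = np.percentile(ppvs, [2.5, 97.5])
    assert ppv_ci.lower == pytest.approx(lo, abs=0.01)
    assert ppv_ci.upper == pytest.approx(hi, abs=0.01)


# ---------------------------------------------------------------------------
# Youden cutoff
# ---------------------------------------------------------------------------


def _youden_brute_force(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    u = np.unique(scores)
    candidates = [-np.inf, *(((u[:-1] + u[1:]) / 2).tolist()), np.inf]
    best_t, best_j = None, -np.inf
    for t in candidates:
        pos = scores <= t
        se = pos[labels == 1].mean()
        sp = (~pos[labels == 0]).mean()
        j = se + sp - 1
        if j > best_j + 1e-15:
            best_t, best_j = t, j
    return best_t, best_j


def test_youden_perfectly_separated():
    cut = youden_cutoff([1, 2, 3, 4], [1, 1, 0, 0])
    assert cut.value == 2.5 and cut.youden_j == 1.0


def test_youden_single_class_rejected():
    with pytest.raises(ValueError):
        youden_cutoff([1, 2, 3], [1, 1, 1])


def test_youden_matches_exhaustive_scan(rng):
    """Random instances (n ≤ 50): the scan equals brute force over all
    candidate thresholds, including the tie-break toward the smallest."""
    for _ in range(200):
        n = int(rng.integers(2, 51))
        scores = np.round(rng.normal(size=n), 2)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        cut = youden_cutoff(scores, labels)
        t, j = _youden_brute_force(scores, labels)
        assert cut.youden_j == pytest.approx(j, abs=1e-12)
        assert cut.value == t


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------


def _one_row(tbs, bmd, fracture=1):
    return pd.DataFrame({"tbs": [tbs], "ls_bmd": [bmd], "fracture": [fracture]})


def test_dichotomize_boundary_convention():
    """Score equal to the cutoff is a positive test; strictly above is
    negative."""
    xt = dichotomize(_one_row(1.204, 0.9), 0.800, 1.204)
    assert xt.n_np_d == 1  # BMD negative, TBS positive
    xt = dichotomize(_one_row(1.2041, 0.9), 0.800, 1.204)
    assert xt.n_nn_d == 1


def test_dichotomize_drops_missing_and_rejects_empty():
    df = pd.DataFrame(
        {"tbs": [1.1, np.nan], "ls_bmd": [0.7, 0.9], "fracture": [1, 0]}
    )
    xt = dichotomize(df, 0.8, 1.204)
    assert xt.n == 1
    with pytest.raises(ValueError):
        dichotomize(df.iloc[1:], 0.8, 1.204)


def test_dichotomize_uses_cutoff_objects():
    cut = DiagnosticCutoff(1.204, youden_j=0.27)
    xt = dichotomize(_one_row(1.0, 0.7, 0), cut_a := DiagnosticCutoff(0.8), cut)
    assert xt.n_pp_h == 1
    assert cut_a.is_positive(0.8)
    assert not cut_a.is_positive(0.801)


def test_proportion_ci_undefined_flag():
    ci = ProportionCI.undefined()
    assert not ci.defined
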