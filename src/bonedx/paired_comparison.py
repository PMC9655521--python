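"""Paired statistical comparison of two diagnostic tests.

All comparisons run on the same 2×2×2 cross-classification, i.e. both
tests were applied to every subject, so the discordant information is
what carries the signal:

* Sensitivities (and specificities) are compared with the uncorrected
  McNemar chi-square on the discordant cells of the relevant disease
  stratum — the paired analogue of comparing two proportions.
* Predictive values are compared with a generalized score chi-square
  (weighted generalized score construction): a GEE score test of the
  test-indicator coefficient in a marginal logit model for the outcome
  among test-positive (PPV) or test-negative (NPV) calls, with a robust
  sandwich variance clustered by subject.  Predictive values of paired
  tests share subjects *and* the disease outcome, so naive two-sample
  z-tests are invalid; the clustered score handles the overlap.
* Overall accuracy (odds ratios) is compared with a Z-test on the log
  odds-ratio difference using independent-samples Woolf variances — an
  approximation on overlapping data, kept because it is the convention
  in this literature; interpret borderline p-values cautiously.
* Agreement between the two tests' calls is Cohen's kappa, overall or
  within a disease stratum.
* Families of comparisons are adjusted with plain Bonferroni.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tables_core import BinaryTestTable, PairedCrossTab


@dataclass(frozen=True)
class TestComparison:
    """Outcome of one paired comparison."""

    name: str  # mcnemar_se | mcnemar_sp | wgs_ppv | wgs_npv | z_log_or
    statistic: float
    df: int
    p_value: float
    adjusted_p: float | None = None
    note: str = ""

    def verdict(self, alpha: float = 0.05) -> str:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return "significant" if p < alpha else "ns"


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its ingredients."""

    kappa: float
    p_o: float  # observed agreement
    p_e: float  # chance-expected agreement
    stratum: str = "all"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)


# ---------------------------------------------------------------------------
# McNemar-type SE/SP comparison
# ---------------------------------------------------------------------------


def mcnemar_paired(xt: PairedCrossTab, target: str) -> TestComparison:
    """Uncorrected McNemar chi-square comparing the two tests' SE or SP.

    ``target="se"`` uses the diseased stratum's discordant cells;
    ``target="sp"`` the healthy stratum's.  chi² = (b−c)²/(b+c) on 1 df,
    no continuity correction.  With no discordance (b+c = 0) the
    statistic is defined as 0 with p = 1 and a note set.
    """
    if target == "se":
        b, c = xt.n_np_d, xt.n_pn_d  # A−B+ vs A+B− among diseased
    elif target == "sp":
        b, c = xt.n_np_h, xt.n_pn_h  # discordant calls among healthy
    else:
        raise ValueError(f"target must be 'se' or 'sp', got {target!r}")
    if b + c == 0:
        return TestComparison(f"mcnemar_{target}", 0.0, 1, 1.0, note="no discordance")
    chi2 = (b - c) ** 2 / (b + c)
    return TestComparison(f"mcnemar_{target}", chi2, 1, float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Generalized score test for predictive values
# ---------------------------------------------------------------------------


def kosinski_wgs(xt: PairedCrossTab, target: str, variance: str = "pooled") -> TestComparison:
    """Generalized score chi-square comparing paired PPVs or NPVs.

    Construction: every positive call (for PPV; negative call for NPV)
    contributes a record with binary outcome = disease status (= healthy
    status for NPV) and a covariate indicating which test produced the
    call.  A marginal logit model ``logit p = α + β·z`` is scored at the
    null β = 0 (common predictive value), with a sandwich variance that
    sums squared score residuals *per subject*, so the two records of a
    both-positive subject are correlated, not independent.  1 df; the
    statistic is invariant to swapping the test labels.

    ``variance`` selects how the squared residuals are centred:

    * ``"pooled"`` (default): at the null-restricted common estimate.
    * ``"unpooled"``: at each test's own predictive value — the weighted
      variant that is slightly more conservative when the two predictive
      values differ.
    """
    if target == "ppv":
        # successes = diseased among positive calls
        a_s, b_s, c_s = xt.n_pp_d, xt.n_pn_d, xt.n_np_d
        a_f, b_f, c_f = xt.n_pp_h, xt.n_pn_h, xt.n_np_h
    elif target == "npv":
        # calls = negative tests; successes = healthy among them;
        # only-A-negative is the (A−, B+) cell, only-B-negative is (A+, B−)
        a_s, b_s, c_s = xt.n_nn_h, xt.n_np_h, xt.n_pn_h
        a_f, b_f, c_f = xt.n_nn_d, xt.n_np_d, xt.n_pn_d
    else:
        raise ValueError(f"target must be 'ppv' or 'npv', got {target!r}")
    if variance not in ("pooled", "unpooled"):
        raise ValueError(f"variance must be 'pooled' or 'unpooled', got {variance!r}")

    n1 = a_s + b_s + a_f + b_f  # calls made by test A
    n2 = a_s + c_s + a_f + c_f  # calls made by test B
    if n1 == 0 or n2 == 0:
        raise ValueError(f"{target}: at least one test makes no qualifying call")
    d1, d2 = a_s + b_s, a_s + c_s  # successes per test
    if (d1 in (0, n1) and d2 in (0, n2)) and d1 * n2 == d2 * n1:
        return TestComparison(f"wgs_{target}", 0.0, 1, 1.0, note="degenerate: no outcome variation")

    p = (d1 + d2) / (n1 + n2)  # null-restricted common predictive value
    score = d2 - n2 * p  # score for the test-indicator coefficient
    h = n2 / (n1 + n2)  # A_βα / A_αα with model-based information

    if variance == "pooled":
        r1, r0 = (1.0 - p) ** 2, p**2
        b_bb = (a_s + c_s) * r1 + (a_f + c_f) * r0
        b_ab = (2 * a_s + c_s) * r1 + (2 * a_f + c_f) * r0
        b_aa = (4 * a_s + b_s + c_s) * r1 + (4 * a_f + b_f + c_f) * r0
    else:
        p1, p2 = d1 / n1, d2 / n2
        b_bb = (a_s + c_s) * (1 - p2) ** 2 + (a_f + c_f) * p2**2
        b_ab = (
            a_s * (2 - p1 - p2) * (1 - p2)
            + a_f * (p1 + p2) * p2
            + c_s * (1 - p2) ** 2
            + c_f * p2**2
        )
        b_aa = (
            a_s * (2 - p1 - p2) ** 2
            + a_f * (p1 + p2) ** 2
            + b_s * (1 - p1) ** 2
            + b_f * p1**2
            + c_s * (1 - p2) ** 2
            + c_f * p2**2
        )
    var = b_bb - 2.0 * h * b_ab + h * h * b_aa
    if var <= 0.0:
        if abs(score) < 1e-12:
            return TestComparison(f"wgs_{target}", 0.0, 1, 1.0, note="identical tests")
        raise ValueError(f"wgs_{target}: non-positive variance estimate ({var})")
    chi2 = score * score / var
    return TestComparison(f"wgs_{target}", float(chi2), 1, float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Z-test on log odds ratios
# ---------------------------------------------------------------------------


def z_test_log_or(
    t1: BinaryTestTable, t2: BinaryTestTable, zero_cell: str = "error"
) -> TestComparison:
    """Two-sided Z-test on the difference of log odds ratios.

    Z = (ln OR₁ − ln OR₂)/√(V₁+V₂) with Woolf variances Vᵢ = Σ 1/cell.
    The variances treat the two tables as independent samples; applied
    to two tests measured on the same subjects this ignores the overlap
    and is an approximation (noted on the result).
    """
    cells = []
    for t in (t1, t2):
        c = (t.tp, t.fp, t.fn, t.tn)
        if 0 in c:
            if zero_cell == "haldane":
                c = tuple(x + 0.5 for x in c)
            elif zero_cell == "error":
                raise ValueError(f"{t.label}: zero cell; Z-test on log OR undefined")
            else:
                raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
        cells.append(c)
    (a1, b1, c1, d1), (a2, b2, c2, d2) = cells
    log_or1 = math.log(a1 * d1 / (b1 * c1))
    log_or2 = math.log(a2 * d2 / (b2 * c2))
    v1 = 1 / a1 + 1 / b1 + 1 / c1 + 1 / d1
    v2 = 1 / a2 + 1 / b2 + 1 / c2 + 1 / d2
    z = (log_or1 - log_or2) / math.sqrt(v1 + v2)
    return TestComparison(
        "z_log_or",
        float(z),
        0,
        float(2.0 * stats.norm.sf(abs(z))),
        note="independent-samples approximation on overlapping data",
    )


# ---------------------------------------------------------------------------
# Agreement and multiplicity
# ---------------------------------------------------------------------------


def cohens_kappa(xt: PairedCrossTab, stratum: str = "all") -> AgreementResult:
    """Cohen's kappa between the two tests' calls.

    ``stratum`` is ``"all"`` (pooled), ``"diseased"`` or ``"healthy"``.
    With both tests constant (chance agreement 1) kappa is undefined and
    returned as NaN.
    """
    pp, pn, np_, nn = xt.agreement_counts(stratum)
    n = pp + pn + np_ + nn
    if n == 0:
        raise ValueError(f"empty stratum {stratum!r}")
    p_o = (pp + nn) / n
    a_pos = (pp + pn) / n
    b_pos = (pp + np_) / n
    p_e = a_pos * b_pos + (1 - a_pos) * (1 - b_pos)
    if p_e >= 1.0:
        return AgreementResult(float("nan"), p_o, p_e, stratum)
    return AgreementResult((p_o - p_e) / (1.0 - p_e), p_o, p_e, stratum)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, p·m); order-preserving.

    ``m`` defaults to the number of p-values and may exceed it (a family
    larger than the values supplied).
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m={m} smaller than the number of p-values ({len(ps)})")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p!r}")
    return [min(1.0, p * m) for p in ps]
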