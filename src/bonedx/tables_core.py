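"""Contingency-table model and per-test diagnostic accuracy.

Two continuous bone measurements — the trabecular bone score (TBS, a
unitless DXA texture index, roughly 0.9–1.5) and lumbar-spine bone
mineral density (LS-BMD, g/cm²) — are dichotomized at fixed cutoffs and
cross-classified against vertebral fragility fracture status.  The
positivity convention is global and matches clinical usage for both
scores: *a score less than or equal to the cutoff is a positive test*
(low bone quality/quantity flags risk).

The central container is :class:`PairedCrossTab`, the 2×2×2 table of
(test A ±) × (test B ±) × (fractured / non-fractured) counts.  It is the
single source of truth for every downstream statistic: marginal 2×2
tables, accuracy panels with confidence intervals, combination rules,
paired comparisons, and agreement measures.

Confidence intervals
--------------------
* Sensitivity/specificity: exact Clopper–Pearson (beta-quantile) bounds.
* Predictive values: the prevalence-adjusted logit interval of Mercaldo
  (delta-method variance from the diseased and non-diseased sample
  sizes), with a plain count-based Wald interval available because the
  two can disagree noticeably at small positive counts.
* Odds ratio: Wald interval on the log scale, with a Pearson chi-square
  test of association (no continuity correction).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger("bonedx")

#: Canonical cohort CSV schema (header row required, UTF-8).
COHORT_COLUMNS = (
    "id",
    "age",
    "height_cm",
    "weight_kg",
    "bmi",
    "age_menopause",
    "tbs",
    "ls_bmd",
    "fracture",
)

#: Default confidence level for every interval in the package.
DEFAULT_LEVEL = 0.95

#: Tolerance (percentage points) on the sum of printed cell percentages
#: when reconstructing counts from a published cross-classification.
PERCENT_SUM_TOL = 0.2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with a two-sided confidence interval.

    ``method`` tags how the bounds were obtained (``clopper_pearson``,
    ``wald``, ``mercaldo_logit``, ...).  An undefined quantity (zero
    denominator) is represented by NaN fields rather than a silent 0.
    """

    estimate: float
    lower: float
    upper: float
    level: float = DEFAULT_LEVEL
    method: str = "clopper_pearson"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    @classmethod
    def undefined(cls, level: float = DEFAULT_LEVEL, method: str = "undefined") -> "ProportionCI":
        return cls(float("nan"), float("nan"), float("nan"), level, method)

    def percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(estimate, lower, upper) on the 0–100 scale, rounded."""
        return tuple(round(100.0 * x, ndigits) for x in (self.estimate, self.lower, self.upper))


@dataclass(frozen=True)
class BinaryTestTable:
    """2×2 table of one dichotomous test against disease status."""

    tp: int
    fp: int
    fn: int
    tn: int
    label: str = "test"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n_d(self) -> int:
        return self.tp + self.fn

    @property
    def n_h(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_d + self.n_h

    @property
    def se(self) -> float:
        return self.tp / self.n_d if self.n_d else float("nan")

    @property
    def sp(self) -> float:
        return self.tn / self.n_h if self.n_h else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def prevalence(self) -> float:
        return self.n_d / self.n if self.n else float("nan")

    @property
    def positivity(self) -> float:
        return (self.tp + self.fp) / self.n if self.n else float("nan")


@dataclass(frozen=True)
class PairedCrossTab:
    """2×2×2 cross-classification of two paired tests by disease status.

    Cell names: first subscript is test A's call, second is test B's
    (``p`` positive, ``n`` negative); ``d`` diseased (fractured), ``h``
    healthy (non-fractured).  E.g. ``n_np_d`` counts diseased women who
    are test-A negative and test-B positive.
    """

    n_pp_d: int
    n_pn_d: int
    n_np_d: int
    n_nn_d: int
    n_pp_h: int
    n_pn_h: int
    n_np_h: int
    n_nn_h: int
    test_a: str = "LS-BMD"
    test_b: str = "TBS"

    _CELLS = ("n_pp_d", "n_pn_d", "n_np_d", "n_nn_d", "n_pp_h", "n_pn_h", "n_np_h", "n_nn_h")

    def __post_init__(self) -> None:
        for name in self._CELLS:
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    # -- totals -------------------------------------------------------------

    @property
    def n_d(self) -> int:
        return self.n_pp_d + self.n_pn_d + self.n_np_d + self.n_nn_d

    @property
    def n_h(self) -> int:
        return self.n_pp_h + self.n_pn_h + self.n_np_h + self.n_nn_h

    @property
    def n(self) -> int:
        return self.n_d + self.n_h

    @property
    def prevalence(self) -> float:
        return self.n_d / self.n if self.n else float("nan")

    # -- views --------------------------------------------------------------

    def marginal(self, which: str) -> BinaryTestTable:
        """Collapse over the other test; see :func:`marginal_table`."""
        return marginal_table(self, which)

    def cells(self, stratum: str) -> tuple[int, int, int, int]:
        """(pp, pn, np, nn) counts for ``stratum`` in {'diseased', 'healthy'}."""
        if stratum == "diseased":
            return (self.n_pp_d, self.n_pn_d, self.n_np_d, self.n_nn_d)
        if stratum == "healthy":
            return (self.n_pp_h, self.n_pn_h, self.n_np_h, self.n_nn_h)
        raise ValueError(f"unknown stratum {stratum!r}")

    def agreement_counts(self, stratum: str = "all") -> tuple[int, int, int, int]:
        """(both+, A+B−, A−B+, both−) pooled or within one disease stratum."""
        if stratum == "all":
            d = self.cells("diseased")
            h = self.cells("healthy")
            return tuple(x + y for x, y in zip(d, h))
        return self.cells(stratum)

    def cell_percentages(self, stratum: str) -> tuple[float, float, float, float]:
        counts = self.cells(stratum)
        total = sum(counts)
        if total == 0:
            raise ValueError(f"empty {stratum} stratum")
        return tuple(100.0 * c / total for c in counts)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "test_a": self.test_a,
            "test_b": self.test_b,
            "diseased": dict(zip(("pp", "pn", "np", "nn"), self.cells("diseased"))),
            "healthy": dict(zip(("pp", "pn", "np", "nn"), self.cells("healthy"))),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "PairedCrossTab":
        """Build from the counts form or the percent-plus-totals form."""
        if "diseased" in data and "pp" in data.get("diseased", {}):
            d, h = data["diseased"], data["healthy"]
            return cls(
                n_pp_d=d["pp"], n_pn_d=d["pn"], n_np_d=d["np"], n_nn_d=d["nn"],
                n_pp_h=h["pp"], n_pn_h=h["pn"], n_np_h=h["np"], n_nn_h=h["nn"],
                test_a=data.get("test_a", "test A"),
                test_b=data.get("test_b", "test B"),
            )
        if "percent_diseased" in data:
            return reconstruct_crosstab(
                data["percent_diseased"],
                data["percent_healthy"],
                data["n_diseased"],
                data["n_healthy"],
                test_a=data.get("test_a", "test A"),
                test_b=data.get("test_b", "test B"),
            )
        raise ValueError("unrecognized crosstab schema: expected counts or percent+totals form")

    @classmethod
    def from_json(cls, text: str) -> "PairedCrossTab":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DiagnosticCutoff:
    """Dichotomization threshold; a score ≤ ``value`` is a positive test.

    ``youden_j`` stores J = SE + SP − 1 at the cutoff when it was chosen
    by maximizing the Youden index on labelled data.
    """

    value: float
    youden_j: float | None = None

    def __post_init__(self) -> None:
        if self.youden_j is not None and not (-1.0 <= self.youden_j <= 1.0):
            raise ValueError(f"youden_j outside [-1, 1]: {self.youden_j}")

    def is_positive(self, score) -> np.ndarray | bool:
        return np.asarray(score) <= self.value


@dataclass(frozen=True)
class AccuracyPanel:
    """Full accuracy readout of one (possibly combined) dichotomous test."""

    label: str
    se: ProportionCI
    sp: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI
    odds_ratio: float
    or_lower: float
    or_upper: float
    chi2: float
    chi2_p: float
    prevalence: float
    positivity_rate: float
    n_d: int
    n_h: int
    rule: str = "none"

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "rule": self.rule,
            "n_d": self.n_d,
            "n_h": self.n_h,
            "prevalence": self.prevalence,
            "positivity_rate": self.positivity_rate,
            "odds_ratio": self.odds_ratio,
            "or_lower": self.or_lower,
            "or_upper": self.or_upper,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
        }
        for name in ("se", "sp", "ppv", "npv"):
            ci: ProportionCI = getattr(self, name)
            out[name] = ci.estimate
            out[f"{name}_lower"] = ci.lower
            out[f"{name}_upper"] = ci.upper
            out[f"{name}_ci_method"] = ci.method
        return out


# ---------------------------------------------------------------------------
# Count reconstruction from printed percentages
# ---------------------------------------------------------------------------


def largest_remainder_round(percentages: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to percentages.

    Each count is the floor of percentage × total / 100; the leftover
    units go to the cells with the largest fractional remainders (ties
    broken toward earlier cells).  The result always sums to ``total``.
    """
    shares = np.asarray(percentages, dtype=float)
    if shares.ndim != 1 or shares.size == 0:
        raise ValueError("percentages must be a non-empty 1-D sequence")
    if np.any(shares < 0) or not np.all(np.isfinite(shares)):
        raise ValueError("percentages must be finite and non-negative")
    if total < 0 or int(total) != total:
        raise ValueError(f"total must be a non-negative integer, got {total!r}")
    s = shares.sum()
    if s == 0:
        if total:
            raise ValueError("cannot apportion a positive total over all-zero percentages")
        return np.zeros(shares.size, dtype=int)
    quotas = shares / s * total  # normalize so leftover is always in [0, k)
    counts = np.floor(quotas).astype(int)
    leftover = int(total - counts.sum())
    if leftover:
        remainders = quotas - counts
        # stable sort descending: ties go to the earlier cell
        order = np.argsort(-remainders, kind="stable")
        counts[order[:leftover]] += 1
    return counts


def reconstruct_crosstab(
    percent_diseased: Sequence[float],
    percent_healthy: Sequence[float],
    n_diseased: int,
    n_healthy: int,
    test_a: str = "LS-BMD",
    test_b: str = "TBS",
    tol: float = PERCENT_SUM_TOL,
) -> PairedCrossTab:
    """Rebuild integer cell counts from printed cell percentages.

    Percentages are given per disease group in (pp, pn, np, nn) order and
    must sum to 100 within ``tol`` points (printed rounding).  Counts are
    apportioned by largest-remainder rounding constrained to the group
    total, so each group sums exactly and the recomputed percentages
    round back to the printed ones.
    """
    groups = {"diseased": (percent_diseased, n_diseased), "healthy": (percent_healthy, n_healthy)}
    counts = {}
    for name, (pct, total) in groups.items():
        pct = np.asarray(pct, dtype=float)
        if pct.shape != (4,):
            raise ValueError(f"{name}: expected 4 cell percentages, got shape {pct.shape}")
        if np.any(pct < 0):
            raise ValueError(f"{name}: negative cell percentage")
        if total <= 0 or int(total) != total:
            raise ValueError(f"{name}: group total must be a positive integer, got {total!r}")
        if abs(pct.sum() - 100.0) > tol:
            raise ValueError(
                f"{name}: cell percentages sum to {pct.sum():.2f}, outside 100 ± {tol}"
            )
        counts[name] = largest_remainder_round(pct, int(total))
    d, h = counts["diseased"], counts["healthy"]
    xt = PairedCrossTab(*d, *h, test_a=test_a, test_b=test_b)
    logger.info(
        "reconstructed crosstab: diseased %s (n=%d), healthy %s (n=%d)",
        tuple(d), xt.n_d, tuple(h), xt.n_h,
    )
    return xt


def marginal_table(xt: PairedCrossTab, which: str) -> BinaryTestTable:
    """Collapse the paired table over the other test.

    ``which`` is ``"a"`` (or the test-A label) or ``"b"``.
    """
    key = which.lower()
    if key in ("a", xt.test_a.lower()):
        return BinaryTestTable(
            tp=xt.n_pp_d + xt.n_pn_d,
            fn=xt.n_np_d + xt.n_nn_d,
            fp=xt.n_pp_h + xt.n_pn_h,
            tn=xt.n_np_h + xt.n_nn_h,
            label=xt.test_a,
        )
    if key in ("b", xt.test_b.lower()):
        return BinaryTestTable(
            tp=xt.n_pp_d + xt.n_np_d,
            fn=xt.n_pn_d + xt.n_nn_d,
            fp=xt.n_pp_h + xt.n_np_h,
            tn=xt.n_pn_h + xt.n_nn_h,
            label=xt.test_b,
        )
    raise ValueError(f"which must identify test A or test B, got {which!r}")


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def clopper_pearson_ci(k: int, n: int, level: float = DEFAULT_LEVEL) -> ProportionCI:
    """Exact (beta-quantile) binomial confidence interval for k/n."""
    if n <= 0 or k < 0 or k > n or int(k) != k or int(n) != n:
        raise ValueError(f"invalid binomial counts k={k!r}, n={n!r}")
    lower, upper = proportion_confint(int(k), int(n), alpha=1.0 - level, method="beta")
    # statsmodels returns NaN at the k=0 / k=n boundary ends; the exact
    # interval is closed there.
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    return ProportionCI(k / n, float(lower), float(upper), level, "clopper_pearson")


def wald_ci(k: int, n: int, level: float = DEFAULT_LEVEL) -> ProportionCI:
    """Normal-approximation interval for k/n, clipped to [0, 1]."""
    if n <= 0 or k < 0 or k > n:
        raise ValueError(f"invalid binomial counts k={k!r}, n={n!r}")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return ProportionCI(p, max(0.0, p - half), min(1.0, p + half), level, "wald")


def mercaldo_pv_ci(
    se: float,
    sp: float,
    n_d: int,
    n_h: int,
    prevalence: float,
    level: float = DEFAULT_LEVEL,
    adjusted: bool = False,
) -> tuple[ProportionCI, ProportionCI]:
    """Prevalence-adjusted logit intervals for PPV and NPV.

    Point estimates come from Bayes' theorem at the supplied prevalence;
    the variance of the logit-transformed predictive value is obtained by
    the delta method from the binomial variances of SE (on ``n_d``
    subjects) and SP (on ``n_h``):

        Var logit(PPV) = (1−SE)/(n_d·SE) + SP/(n_h·(1−SP))
        Var logit(NPV) = SE/(n_d·(1−SE)) + (1−SP)/(n_h·SP)

    At SE or SP of exactly 0 or 1 the logit is infinite; with
    ``adjusted=True`` a 0.5-count continuity adjustment is applied to the
    implied binomial counts (the boundary-safe variant), otherwise a
    ValueError is raised.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence!r}")
    if n_d <= 0 or n_h <= 0:
        raise ValueError("n_d and n_h must be positive")
    for name, v in (("se", se), ("sp", sp)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    at_boundary = se in (0.0, 1.0) or sp in (0.0, 1.0)
    if at_boundary and not adjusted:
        raise ValueError(
            "SE or SP is exactly 0 or 1; the logit interval is undefined "
            "(use adjusted=True for the continuity-adjusted variant)"
        )
    if adjusted:
        se = (se * n_d + 0.5) / (n_d + 1.0)
        sp = (sp * n_h + 0.5) / (n_h + 1.0)

    z = stats.norm.ppf(0.5 + level / 2.0)
    pi, q = prevalence, 1.0 - prevalence

    ppv = pi * se / (pi * se + q * (1.0 - sp))
    var_ppv = (1.0 - se) / (n_d * se) + sp / (n_h * (1.0 - sp))
    lo, hi = _logit_interval(ppv, var_ppv, z)
    ppv_ci = ProportionCI(ppv, lo, hi, level, "mercaldo_logit")

    npv = q * sp / (q * sp + pi * (1.0 - se))
    var_npv = se / (n_d * (1.0 - se)) + (1.0 - sp) / (n_h * sp)
    lo, hi = _logit_interval(npv, var_npv, z)
    npv_ci = ProportionCI(npv, lo, hi, level, "mercaldo_logit")
    return ppv_ci, npv_ci


def _logit_interval(p: float, var_logit: float, z: float) -> tuple[float, float]:
    logit = math.log(p / (1.0 - p))
    half = z * math.sqrt(var_logit)
    expit = lambda x: 1.0 / (1.0 + math.exp(-x))
    return expit(logit - half), expit(logit + half)


# ---------------------------------------------------------------------------
# Odds ratio and the accuracy panel
# ---------------------------------------------------------------------------


def odds_ratio_stats(
    t: BinaryTestTable,
    level: float = DEFAULT_LEVEL,
    zero_cell: str = "undefined",
) -> tuple[float, float, float, float, float]:
    """(OR, lower, upper, chi2, p) for a 2×2 table.

    OR is the cross-product ratio with a Wald interval on the log scale;
    the association test is the Pearson chi-square without continuity
    correction.  ``zero_cell`` chooses the policy when a cell is empty:
    ``"undefined"`` (NaN OR/CI with a warning logged) or ``"haldane"``
    (add 0.5 to every cell for the OR and its CI).
    """
    cells = (t.tp, t.fn, t.fp, t.tn)
    table = np.array([[t.tp, t.fn], [t.fp, t.tn]], dtype=float)
    if table.sum() and all(m > 0 for m in (*table.sum(0), *table.sum(1))):
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = float("nan"), float("nan")
    if 0 in cells:
        if zero_cell == "haldane":
            a, b, c, d = (x + 0.5 for x in cells)
        elif zero_cell == "undefined":
            logger.warning("odds ratio undefined for %s: zero cell in %s", t.label, cells)
            return float("nan"), float("nan"), float("nan"), chi2, p
        else:
            raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    else:
        a, b, c, d = cells
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - half), math.exp(log_or + half), chi2, p


def accuracy_panel(
    t: BinaryTestTable,
    level: float = DEFAULT_LEVEL,
    pv_ci_method: str = "mercaldo_logit",
    zero_cell: str = "undefined",
    rule: str = "none",
) -> AccuracyPanel:
    """Full accuracy panel for one dichotomous test.

    SE/SP carry exact Clopper–Pearson intervals.  PPV/NPV point estimates
    are the count ratios tp/(tp+fp) and tn/(tn+fn) — identical to Bayes'
    theorem evaluated at the table's own prevalence — with bounds from
    ``pv_ci_method`` (``mercaldo_logit`` or ``wald``).
    """
    if t.n_d == 0 or t.n_h == 0:
        raise ValueError(f"{t.label}: both disease groups must be non-empty")
    se_ci = clopper_pearson_ci(t.tp, t.n_d, level)
    sp_ci = clopper_pearson_ci(t.tn, t.n_h, level)

    if pv_ci_method == "mercaldo_logit":
        try:
            ppv_ci, npv_ci = mercaldo_pv_ci(t.se, t.sp, t.n_d, t.n_h, t.prevalence, level)
        except ValueError:
            ppv_ci, npv_ci = mercaldo_pv_ci(
                t.se, t.sp, t.n_d, t.n_h, t.prevalence, level, adjusted=True
            )
        # report the count-based point (equal to Bayes at own prevalence
        # up to float round-off; exact count ratio is the panel contract)
        ppv_ci = replace(ppv_ci, estimate=t.ppv) if not math.isnan(t.ppv) else ProportionCI.undefined(level)
        npv_ci = replace(npv_ci, estimate=t.npv) if not math.isnan(t.npv) else ProportionCI.undefined(level)
    elif pv_ci_method == "wald":
        ppv_ci = (
            wald_ci(t.tp, t.tp + t.fp, level) if t.tp + t.fp else ProportionCI.undefined(level)
        )
        npv_ci = (
            wald_ci(t.tn, t.tn + t.fn, level) if t.tn + t.fn else ProportionCI.undefined(level)
        )
    else:
        raise ValueError(f"unknown pv_ci_method {pv_ci_method!r}")
    if not ppv_ci.defined:
        logger.warning("%s: PPV undefined (no positive calls)", t.label)
    if not npv_ci.defined:
        logger.warning("%s: NPV undefined (no negative calls)", t.label)

    or_, or_lo, or_hi, chi2, p = odds_ratio_stats(t, level, zero_cell)
    return AccuracyPanel(
        label=t.label,
        se=se_ci,
        sp=sp_ci,
        ppv=ppv_ci,
        npv=npv_ci,
        odds_ratio=or_,
        or_lower=or_lo,
        or_upper=or_hi,
        chi2=chi2,
        chi2_p=p,
        prevalence=t.prevalence,
        positivity_rate=t.positivity,
        n_d=t.n_d,
        n_h=t.n_h,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Cutoff selection and dichotomization
# ---------------------------------------------------------------------------


def youden_cutoff(scores: Iterable[float], labels: Iterable[int]) -> DiagnosticCutoff:
    """Cutoff maximizing the Youden index J = SE + SP − 1.

    Candidates are the midpoints between adjacent distinct observed
    scores plus −inf/+inf sentinels (all-negative / all-positive);
    positivity is score ≤ threshold.  Ties take the smallest threshold.
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length non-empty 1-D sequences")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both disease classes must be present to select a cutoff")
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    diseased = labels == 1
    pos = scores[:, None] <= candidates[None, :]
    se = pos[diseased].mean(axis=0)
    sp = (~pos[~diseased]).mean(axis=0)
    j = se + sp - 1.0
    best = int(np.argmax(j))  # candidates ascend, argmax takes the first ⇒ smallest
    return DiagnosticCutoff(value=float(candidates[best]), youden_j=float(j[best]))


def dichotomize(
    cohort: pd.DataFrame,
    cutoff_a: DiagnosticCutoff | float,
    cutoff_b: DiagnosticCutoff | float,
    test_a_col: str = "ls_bmd",
    test_b_col: str = "tbs",
    disease_col: str = "fracture",
    test_a: str | None = None,
    test_b: str | None = None,
) -> PairedCrossTab:
    """Apply both cutoffs (score ≤ cutoff ⇒ positive) and tally the 8 cells.

    Rows with missing values in any of the three columns are dropped and
    counted in the log.  An empty cohort after filtering is an error.
    """
    if not isinstance(cutoff_a, DiagnosticCutoff):
        cutoff_a = DiagnosticCutoff(float(cutoff_a))
    if not isinstance(cutoff_b, DiagnosticCutoff):
        cutoff_b = DiagnosticCutoff(float(cutoff_b))
    needed = [test_a_col, test_b_col, disease_col]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing columns {missing_cols}")
    sub = cohort[needed]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        logger.info("dichotomize: dropped %d rows with missing values", n_dropped)
    if kept.empty:
        raise ValueError("no complete rows left after dropping missing values")
    a_pos = np.asarray(kept[test_a_col], float) <= cutoff_a.value
    b_pos = np.asarray(kept[test_b_col], float) <= cutoff_b.value
    dis = np.asarray(kept[disease_col], int) == 1
    cnt = lambda m: int(m.sum())
    return PairedCrossTab(
        n_pp_d=cnt(a_pos & b_pos & dis),
        n_pn_d=cnt(a_pos & ~b_pos & dis),
        n_np_d=cnt(~a_pos & b_pos & dis),
        n_nn_d=cnt(~a_pos & ~b_pos & dis),
        n_pp_h=cnt(a_pos & b_pos & ~dis),
        n_pn_h=cnt(a_pos & ~b_pos & ~dis),
        n_np_h=cnt(~a_pos & b_pos & ~dis),
        n_nn_h=cnt(~a_pos & ~b_pos & ~dis),
        test_a=test_a or test_a_col,
        test_b=test_b or test_b_col,
    )
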