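"""Combination of two dichotomized tests and sequential subgroup analysis.

Two ways to merge paired binary tests into one decision:

* **OR rule** (believe the positive): combined test is positive if at
  least one component is positive.  Sensitivity can only rise,
  specificity can only fall.
* **AND rule** (believe the negative): combined test is positive only if
  both components are positive.  Specificity rises, sensitivity falls.

Each rule has two modes.  The *empirical* mode (default) tallies the
combined calls directly from the observed 2×2×2 table and therefore
honours whatever dependence the two tests have within each disease
group.  The *independence* mode applies the textbook closed forms

    OR:  SE = SE₁ + SE₂ − SE₁·SE₂    SP = SP₁·SP₂
    AND: SE = SE₁·SE₂                SP = SP₁ + SP₂ − SP₁·SP₂

which hold only under conditional independence given disease status;
the gap between the two modes measures conditional dependence and the
independence mode is intended for what-if analyses only.

The subgroup analysis evaluates one test *within the stratum of
subjects negative on the other* — the sequential-testing question "does
the second test add information among first-test negatives?".
"""

from __future__ import annotations

from dataclasses import dataclass

from .tables_core import (
    DEFAULT_LEVEL,
    AccuracyPanel,
    BinaryTestTable,
    PairedCrossTab,
    accuracy_panel,
)

VALID_RULES = ("OR", "AND")


@dataclass(frozen=True)
class CombinationRule:
    """How to merge the two component calls."""

    rule: str  # "OR" | "AND"
    mode: str = "empirical"  # "empirical" | "independence"

    def __post_init__(self) -> None:
        if self.rule not in VALID_RULES:
            raise ValueError(f"rule must be one of {VALID_RULES}, got {self.rule!r}")
        if self.mode not in ("empirical", "independence"):
            raise ValueError(f"mode must be 'empirical' or 'independence', got {self.mode!r}")


@dataclass(frozen=True)
class SubgroupResult:
    """One test's accuracy restricted to the other test's negatives."""

    conditioning_test: str
    conditioning_state: str
    table: BinaryTestTable
    prevalence: float
    panel: AccuracyPanel


def combine_empirical(xt: PairedCrossTab, rule: CombinationRule | str) -> BinaryTestTable:
    """Collapse the paired table under the OR or AND rule.

    OR rule: a subject is a combined positive unless negative on both
    tests.  AND rule: a combined positive requires both positives.
    """
    name = rule.rule if isinstance(rule, CombinationRule) else str(rule).upper()
    if name == "OR":
        return BinaryTestTable(
            tp=xt.n_pp_d + xt.n_pn_d + xt.n_np_d,
            fn=xt.n_nn_d,
            fp=xt.n_h - xt.n_nn_h,
            tn=xt.n_nn_h,
            label=f"{xt.test_a} OR {xt.test_b}",
        )
    if name == "AND":
        return BinaryTestTable(
            tp=xt.n_pp_d,
            fn=xt.n_d - xt.n_pp_d,
            fp=xt.n_pp_h,
            tn=xt.n_h - xt.n_pp_h,
            label=f"{xt.test_a} AND {xt.test_b}",
        )
    raise ValueError(f"rule must be one of {VALID_RULES}, got {name!r}")


def combine_independence(
    se1: float, sp1: float, se2: float, sp2: float, rule: CombinationRule | str
) -> tuple[float, float]:
    """Closed-form combined (SE, SP) assuming conditional independence."""
    for name, v in (("se1", se1), ("sp1", sp1), ("se2", se2), ("sp2", sp2)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    name = rule.rule if isinstance(rule, CombinationRule) else str(rule).upper()
    if name == "OR":
        return se1 + se2 - se1 * se2, sp1 * sp2
    if name == "AND":
        return se1 * se2, sp1 + sp2 - sp1 * sp2
    raise ValueError(f"rule must be one of {VALID_RULES}, got {name!r}")


def combined_panel(
    xt: PairedCrossTab,
    rule: CombinationRule | str,
    level: float = DEFAULT_LEVEL,
) -> AccuracyPanel:
    """Accuracy panel of the empirically combined test."""
    name = rule.rule if isinstance(rule, CombinationRule) else str(rule).upper()
    return accuracy_panel(combine_empirical(xt, name), level=level, rule=name)


def subgroup_analysis(
    xt: PairedCrossTab,
    conditioning_test: str,
    state: str = "negative",
    level: float = DEFAULT_LEVEL,
) -> SubgroupResult:
    """Accuracy of one test within the other's chosen stratum.

    ``conditioning_test`` is ``"a"``/``"b"`` or a test label; the inner
    2×2 table restricts the *other* test to subjects with the given
    ``state`` on the conditioning test.  Only the ``"negative"`` state is
    part of the supported sequential-testing workflow; ``"positive"``
    conditioning is exposed for exploration but is experimental.
    """
    key = conditioning_test.lower()
    if key in ("a", xt.test_a.lower()):
        cond, inner = "a", xt.test_b
    elif key in ("b", xt.test_b.lower()):
        cond, inner = "b", xt.test_a
    else:
        raise ValueError(f"conditioning_test must identify test A or B, got {conditioning_test!r}")
    if state not in ("negative", "positive"):
        raise ValueError(f"state must be 'negative' or 'positive', got {state!r}")
    neg = state == "negative"

    # cell names (pp, pn, np, nn): first letter = test A's call, second = B's
    if cond == "a":  # stratify on A; inner cells are (B+, B−) within the stratum
        pos_cell, neg_cell = ("n_np", "n_nn") if neg else ("n_pp", "n_pn")
    else:  # stratify on B; inner cells are (A+, A−) within the stratum
        pos_cell, neg_cell = ("n_pn", "n_nn") if neg else ("n_pp", "n_np")
    tp = getattr(xt, f"{pos_cell}_d")
    fn = getattr(xt, f"{neg_cell}_d")
    fp = getattr(xt, f"{pos_cell}_h")
    tn = getattr(xt, f"{neg_cell}_h")
    cond_label = xt.test_a if cond == "a" else xt.test_b
    if tp + fn + fp + tn == 0:
        raise ValueError(f"empty stratum: no subjects are {cond_label}-{state}")
    table = BinaryTestTable(
        tp=tp, fp=fp, fn=fn, tn=tn, label=f"{inner} | {cond_label}-{state}"
    )
    if table.n_d == 0 or table.n_h == 0:
        # accuracy_panel would reject; still return the table with a
        # degenerate panel error raised there if requested
        raise ValueError(
            f"stratum {cond_label}-{state} lacks one disease group "
            f"(n_d={table.n_d}, n_h={table.n_h})"
        )
    panel = accuracy_panel(table, level=level, rule=f"subgroup:{cond_label}-{state}")
    return SubgroupResult(
        conditioning_test=cond_label,
        conditioning_state=state,
        table=table,
        prevalence=table.prevalence,
        panel=panel,
    )
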