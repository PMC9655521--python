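"""Built-in summary data of the motivating case–control study.

A retrospective case–control study of 992 postmenopausal women (86 with
a radiologically documented vertebral fragility fracture, 906 without)
referred for DXA.  Both bone tests were dichotomized at Youden-index
cutoffs fitted on the full sample — TBS ≤ 1.204 and LS-BMD ≤ 0.800 g/cm²
are positive tests — and the published report gives the paired
cross-classification as cell percentages per disease group, baseline
means ± SD per group, and a panel of accuracy statistics.

Those printed values are the package's reference inputs: the cell
percentages and group sizes reconstruct the full 2×2×2 count table
(every headline statistic is recomputable from it), the baseline moments
parameterize the synthetic cohort generator, and the published statistic
values drive the replication report.
"""

from __future__ import annotations

from .tables_core import PairedCrossTab, reconstruct_crosstab

TEST_A = "LS-BMD"  #: test A = lumbar-spine BMD (g/cm²)
TEST_B = "TBS"     #: test B = trabecular bone score (unitless)

#: Dichotomization cutoffs (score ≤ cutoff ⇒ positive test).
CUTOFF_BMD = 0.800   # g/cm², corresponds to a T-score of −2.3
CUTOFF_TBS = 1.204

#: Group sizes.
N_FRACTURED = 86
N_NONFRACTURED = 906

#: Published cell percentages of the paired classification, in
#: (pp, pn, np, nn) order with the first letter the LS-BMD call and the
#: second the TBS call, per disease group.
PERCENT_FRACTURED = (48.8, 18.6, 23.3, 9.3)
PERCENT_NONFRACTURED = (27.9, 14.0, 17.1, 41.0)

#: T-score validation checkpoint: an LS-BMD of 0.800 g/cm² was reported
#: as a T-score of −2.3 (reference mean/SD are scanner-specific and are
#: deliberately not defaulted anywhere).
T_SCORE_CHECKPOINT = (0.800, -2.3)

#: Baseline characteristics, mean and SD per group (fractured,
#: non-fractured), as published.  Units: age/menopause years, height cm,
#: weight kg, BMI kg/m², LS-BMD g/cm², TBS unitless.
BASELINE = {
    "age": ((69.6, 6.8), (68.4, 6.8)),
    "height_cm": ((158.1, 6.4), (159.6, 6.1)),
    "weight_kg": ((62.6, 10.6), (63.4, 10.4)),
    "bmi": ((25.0, 4.1), (24.8, 3.7)),
    "age_menopause": ((48.4, 5.5), (49.5, 4.6)),
    "tbs": ((1.165, 0.095), (1.214, 0.100)),
    "ls_bmd": ((0.771, 0.127), (0.828, 0.120)),
}


def study_crosstab() -> PairedCrossTab:
    """Reconstruct the study's 2×2×2 count table from the printed
    percentages and group totals (largest-remainder rounding)."""
    return reconstruct_crosstab(
        PERCENT_FRACTURED,
        PERCENT_NONFRACTURED,
        N_FRACTURED,
        N_NONFRACTURED,
        test_a=TEST_A,
        test_b=TEST_B,
    )


#: Published statistic values used by the replication report.  Each
#: entry: key -> (published value, absolute tolerance, note).  Percent
#: quantities are on the 0–100 scale with tolerance 0.05 (print
#: rounding); odds ratios and kappas use 0.01 except kappa at 0.002.
PUBLISHED = {
    "TBS sensitivity %": (72.09, 0.05, ""),
    "TBS specificity %": (54.97, 0.05, ""),
    "TBS PPV %": (13.19, 0.05, ""),
    "TBS NPV %": (95.40, 0.05, ""),
    "TBS odds ratio": (3.15, 0.01, ""),
    "TBS positivity %": (47.40, 0.05, ""),
    "LS-BMD sensitivity %": (67.44, 0.05, ""),
    "LS-BMD specificity %": (58.06, 0.05, ""),
    "LS-BMD PPV %": (13.24, 0.05, ""),
    "LS-BMD NPV %": (94.95, 0.05, ""),
    "LS-BMD odds ratio": (2.87, 0.01, ""),
    "LS-BMD positivity %": (44.20, 0.05, ""),
    "OR-rule sensitivity %": (90.70, 0.05, ""),
    "OR-rule NPV %": (97.89, 0.05, ""),
    "OR-rule PPV %": (12.73, 0.05, ""),
    "OR-rule positivity %": (61.79, 0.05, ""),
    "OR-rule odds ratio": (6.76, 0.01, ""),
    "AND-rule sensitivity %": (48.84, 0.05, ""),
    "AND-rule specificity %": (72.08, 0.05, ""),
    "AND-rule PPV %": (14.24, 0.05, ""),
    "AND-rule NPV %": (93.69, 0.05, ""),
    "AND-rule positivity %": (29.73, 0.05, ""),
    "AND-rule odds ratio": (2.46, 0.01, ""),
    "LS-BMD-negative stratum prevalence %": (5.05, 0.05, ""),
    "TBS in LS-BMD-negatives: sensitivity %": (71.43, 0.05, ""),
    "TBS in LS-BMD-negatives: specificity %": (70.53, 0.05, ""),
    "TBS in LS-BMD-negatives: NPV %": (97.89, 0.05, ""),
    "TBS in LS-BMD-negatives: odds ratio": (5.98, 0.01, ""),
    "TBS-negative stratum prevalence %": (4.60, 0.05, ""),
    "LS-BMD in TBS-negatives: sensitivity %": (66.67, 0.05, ""),
    "LS-BMD in TBS-negatives: specificity %": (74.50, 0.05, ""),
    "LS-BMD in TBS-negatives: NPV %": (97.89, 0.05, ""),
    "LS-BMD in TBS-negatives: odds ratio": (5.84, 0.01, ""),
    "Cohen kappa, pooled": (0.355, 0.002, ""),
    "Cohen kappa, non-fractured": (0.367, 0.002, ""),
    "AND-rule PPV vs prevalence: Pearson R": (0.997, 0.002, ""),
    "OR-rule NPV vs prevalence: Pearson R": (-0.993, 0.002, ""),
}

#: Published values that the reconstructed counts contradict; reported
#: side by side, never asserted.  key -> (published, computed-from-counts
#: description).
FLAGGED = {
    "TBS in LS-BMD-negatives: PPV %": (
        11.19,
        "counts give 20/175 = 11.43%; the printed subgroup PPVs appear "
        "swapped/truncated between the two subgroup analyses",
    ),
    "LS-BMD in TBS-negatives: PPV %": (
        1.43,
        "counts give 16/143 = 11.19%; apparent truncation of a leading digit",
    ),
    "Cohen kappa, fractured": (
        0.010,
        "counts give ≈0.010, matching the concordance-table footnote; the "
        "running text prints 0.100 for the same quantity",
    ),
    "OR-rule specificity %": (
        41.00,
        "counts give 371/906 = 40.95%; 0.05-point print rounding",
    ),
}
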