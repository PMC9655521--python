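# Methods

## Setting and data model

The package analyses a retrospective case–control design: 992
postmenopausal women (86 with a radiologically documented vertebral
fragility fracture, 906 without), each measured on two continuous bone
tests — the trabecular bone score (TBS, unitless, ≈0.9–1.5) and
lumbar-spine bone mineral density (LS-BMD, g/cm²).  Both are
dichotomized with the convention *score ≤ cutoff ⇒ positive test*
(default cutoffs TBS 1.204 and LS-BMD 0.800 g/cm², the Youden-optimal
values of the source study; 0.800 g/cm² corresponds to a T-score of
−2.3 on the study scanner).  The object every statistic is computed
from is the 2×2×2 table of (LS-BMD ±) × (TBS ±) × (fractured /
non-fractured) counts (`PairedCrossTab`).

Because the source study is published only as summary tables, the
package reconstructs the full count table from the printed per-group
cell percentages and group sizes using largest-remainder rounding
constrained to the group total.  For the given inputs this yields
(42, 16, 20, 8) fractured and (253, 127, 155, 371) non-fractured
(pp, pn, np, nn; first letter LS-BMD), which regenerate every headline
statistic of the study exactly.  One printed cell is internally
inconsistent: 371/906 = 40.95% was printed as 41.0%, an error of 0.051
points that no integer count can reproduce; it is reported, not forced.

## Statistics

**Accuracy panel.**  SE = tp/(tp+fn) and SP = tn/(tn+fp) carry exact
Clopper–Pearson (beta-quantile) intervals.  PPV and NPV point estimates
are the count ratios (identical to Bayes' theorem at the table's own
prevalence); their default intervals are the prevalence-adjusted logit
intervals of Mercaldo, with delta-method variances

    Var logit PPV = (1−SE)/(n_d·SE) + SP/(n_h·(1−SP))
    Var logit NPV = SE/(n_d·(1−SE)) + (1−SP)/(n_h·SP)

back-transformed to (0, 1).  At SE/SP of exactly 0 or 1 a 0.5-count
continuity adjustment is applied (the boundary-safe variant); a plain
count-based Wald interval is available as an option, because published
predictive-value intervals are often of either family and the two
disagree at small positive counts.  The odds ratio is the cross-product
ratio with a Wald log-scale interval (variance Σ 1/cell) and a Pearson
χ² association test without continuity correction.  Zero cells make
the OR undefined by default (logged); an optional Haldane–Anscombe
+0.5 policy is provided.

**Combination rules.**  The empirical mode tallies combined calls from
the joint counts and is the default: it honours the conditional
dependence the two tests actually have (they share a DXA acquisition
and measure correlated aspects of the same bone).  The independence
closed forms are provided for what-if analysis only; on the study data
they give OR-rule SE 90.9% versus the empirical 90.7%, a visible
dependence gap.  Useful identities, asserted in the tests: the OR rule
classifies as negative exactly the both-negative subjects, so its NPV
equals the NPV of the double-negative stratum (371/379 = 97.89% here);
OR-negatives are AND-positives of the negated tests.

**Subgroup (sequential) analysis.**  One test evaluated within the
stratum of subjects negative on the other, with the stratum's own
prevalence — the "does the second test add information after a negative
first test?" question.  Only negative-state conditioning is part of the
supported workflow; positive-state conditioning is exposed but
experimental.

**Paired comparisons.**  SE and SP of the two tests are compared with
the uncorrected McNemar χ² on the relevant stratum's discordant cells
((b−c)²/(b+c), 1 df) — on the reconstructed counts this gives 0.444
(SE) and 2.780 (SP), versus 0.446/2.788 printed from the original
unrounded data.  Predictive values are compared with a generalized
score χ² (weighted generalized score construction): each positive call
(negative call, for NPV) contributes a record with outcome = disease
status and a test-indicator covariate; the marginal logit model is
scored at the null of a common predictive value with a sandwich
variance clustered by subject, which accounts for the shared subjects
and outcomes that invalidate naive two-sample tests.  The
null-restricted (pooled) residual centring is the default; a
test-specific (unpooled) variant is switchable.  The statistic is
invariant to swapping the test labels, and its size is verified by
simulation (≤7% rejections at nominal 5%).  Odds ratios are compared
with a Z-test on the log-OR difference with independent-samples Woolf
variances — an approximation on overlapping data, kept because it is
the field's convention; the result carries an explicit note and
borderline p-values (0.055 here, vs 0.063 published) should be read as
verdicts, not precise probabilities.  Agreement is Cohen's kappa,
pooled or per stratum; multiplicity is plain Bonferroni
(min(1, p·m)).

**Prevalence sweep.**  PPV/NPV are evaluated over a grid of pre-test
prevalences (default 2–40% in 18 steps including the sample's 8.67%),
with Mercaldo-style intervals computed holding the study's n_d/n_h
fixed as the prevalence varies.  This is deliberately approximate: a
hypothetical population contributes no sampling error of its own, and
the exact variance bookkeeping at transplanted prevalences is not
well-defined — the intervals quantify uncertainty in SE/SP only.
Regression summaries (predictive value on prevalence, both percent
scale) report signed Pearson R, R², and the regression p-value; on the
study inputs the AND-rule PPV tracks prevalence with R = 0.997 and the
OR-rule NPV with R = −0.993.

## Synthetic cohort generator

Within each disease group, (TBS, LS-BMD) is bivariate normal with the
published group means/SDs (fractured: TBS 1.165 ± 0.095, BMD
0.771 ± 0.127; non-fractured: 1.214 ± 0.100, 0.828 ± 0.120; n = 86 /
906) and a correlation ρ per group.  ρ is not published; it is
calibrated by Brent root-finding so that the bivariate-normal orthant
probability P(TBS ≤ 1.204, BMD ≤ 0.800) equals the published
joint-positive cell of that group (48.8% fractured, 27.9%
non-fractured), after checking the target lies strictly inside the
Fréchet bounds implied by the two Gaussian marginals.  The calibrated
defaults are ρ ≈ 0.63 (fractured) and ρ ≈ 0.56 (non-fractured).
Covariates (age, height, weight, BMI, age at menopause) are independent
normals at the published group moments — adequate to exercise the
pipeline, not a joint anthropometric model.  Generation is
deterministic given a seed, and CSV output is byte-reproducible.

**Known residual misfit.**  A Gaussian tail at the published
fractured-group moments implies marginal positivities of 65.9% (TBS)
and 59.0% (BMD), versus the observed 72.1% and 67.4%.  Marginals do not
depend on ρ, so the generator reproduces the fractured group's
joint-positive cell but *not* its off-joint cells (the both-negative
cell lands near 24% versus the observed 9.3%), and the simulated
OR-rule sensitivity is accordingly ≈76% rather than 90.7%.  The real
fractured-group score distributions are evidently left-skewed relative
to a normal with the same moments; nothing in the published summaries
pins that shape down, so the generator keeps the published moments and
documents the misfit rather than distorting parameters.  Passing
synthetic-cohort tests therefore demonstrate correct plumbing,
calibration of the dependence, and recovery of the non-fractured
classification — not a full reproduction of the fractured group's tail
behaviour.  The non-fractured group (91% of subjects) is reproduced
within sampling error in all four cells.

The optional T-score column uses a user-supplied (reference mean,
reference SD); no scanner-specific default is claimed.  The published
(0.800 g/cm² ↔ −2.3) pair is stored as a validation checkpoint only.

## Numerical and design choices

* Confidence level defaults to 0.95 everywhere; percentages are printed
  to 2 decimals in CSV output, with a full-precision JSON twin.
* Youden cutoffs scan midpoints between adjacent distinct scores plus
  ±∞ sentinels; ties take the smallest threshold.
* Count reconstruction tolerates printed percentage sums of 100 ± 0.2.
* ρ calibration: Brent's method on [−0.999, 0.999], 1e-9 on ρ, residual
  checked to 1e-6 on the probability scale; targets at or beyond the
  Fréchet bounds are rejected with the bounds in the message.
* Baseline tables use Levene's test (centre = mean) to choose between
  pooled-variance and Welch t-tests at 0.05, mirroring the source
  study's workflow; a summary-statistics t-test variant covers the case
  where only published moments are available.
* Degenerate inputs are flagged, not silently zeroed: undefined
  PPV/NPV become NaN with a log warning, kappa with chance agreement 1
  is NaN, empty strata raise with the stratum named.

## Replicated and non-replicated published values

The replication report (written by `bonedx replicate`) passes all 37
count-derivable published statistics at print-rounding tolerance
(0.05 points on percentages, 0.01 on odds ratios, 0.002 on kappa).
Four published values disagree with the published counts themselves and
are flagged, never asserted: the two subgroup PPVs (printed 11.19% and
1.43%, versus 11.43% and 11.19% from the counts — an apparent swap plus
a truncated digit), the fractured-stratum kappa (0.100 in the running
text versus 0.010 in the table footnote and from the counts), and the
OR-rule specificity (41.00% printed, 40.95% from counts).  Printed
PPV/NPV interval bounds are not asserted either: the published table
footnote and methods text attribute them to different interval
families, and neither family reproduces every printed bound, so both
are implemented and reported.

## Problem sizes

Simulation-based checks use 10⁴ tables of n = 5,000 (combination
convergence), 2,000 tables of n = 500 (score-test size), 10⁴ binomial
replicates (interval coverage and Monte-Carlo interval checks), and
synthetic cohorts at 100× the study size (moment and cell recovery) —
sizes chosen so each check's Monte-Carlo error is well below the
tolerance it asserts while the whole suite runs in seconds.
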