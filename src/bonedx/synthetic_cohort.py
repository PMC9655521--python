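"""Synthetic patient-level cohorts with the study's statistical structure.

The analysis pipeline only ever sees a patient-level table of two
continuous bone scores plus fracture status, so a generator that
reproduces the published group-conditional first and second moments —
and, crucially, the *dependence* between the two scores within each
disease group — lets every stage run end-to-end without patient data.

Model: within each disease group, (TBS, LS-BMD) is bivariate normal
with the group's published means/SDs and a Gaussian-copula correlation
ρ.  ρ is not printed anywhere, but the published joint-positive cell
fraction of each group pins it down: ρ is calibrated by root-finding so
that the bivariate-normal orthant probability
P(TBS ≤ cutoff, BMD ≤ cutoff) matches the target cell.  Covariates
(age, height, weight, BMI, age at menopause) are independent normals —
adequate for exercising the pipeline, not a joint anthropometric model.

Known residual misfit: a Gaussian tail at the published fractured-group
moments implies a TBS positivity of ≈66% against the observed 72.1%, so
exact cell fractions are matched only in expectation per group via ρ,
and marginal positivities are approximate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import study
from .tables_core import COHORT_COLUMNS

#: ρ search interval; targets implying |ρ| beyond this are rejected as
#: numerically at the Fréchet boundary.
RHO_LIMIT = 0.999


@dataclass(frozen=True)
class GroupParams:
    """Moments of one disease group."""

    n: int
    tbs_mean: float
    tbs_sd: float
    bmd_mean: float
    bmd_sd: float
    rho: float | None = None  # None ⇒ calibrate to the study's joint-positive cell

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group size must be positive, got {self.n}")
        if self.tbs_sd <= 0 or self.bmd_sd <= 0:
            raise ValueError("SDs must be positive")
        if self.rho is not None and not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")


def _default_covariates() -> dict:
    return {name: study.BASELINE[name] for name in
            ("age", "height_cm", "weight_kg", "bmi", "age_menopause")}


@dataclass(frozen=True)
class CohortParams:
    """Full generator configuration; defaults are the study conditions."""

    fractured: GroupParams = GroupParams(
        n=study.N_FRACTURED,
        tbs_mean=study.BASELINE["tbs"][0][0],
        tbs_sd=study.BASELINE["tbs"][0][1],
        bmd_mean=study.BASELINE["ls_bmd"][0][0],
        bmd_sd=study.BASELINE["ls_bmd"][0][1],
    )
    nonfractured: GroupParams = GroupParams(
        n=study.N_NONFRACTURED,
        tbs_mean=study.BASELINE["tbs"][1][0],
        tbs_sd=study.BASELINE["tbs"][1][1],
        bmd_mean=study.BASELINE["ls_bmd"][1][0],
        bmd_sd=study.BASELINE["ls_bmd"][1][1],
    )
    #: covariate name -> ((mean, sd) fractured, (mean, sd) non-fractured)
    covariates: dict = field(default_factory=_default_covariates)
    #: optional (reference mean, reference SD) to emit an ls_bmd_t_score
    #: column; scanner-specific, so no default is claimed.
    t_score_ref: tuple[float, float] | None = None

    def scaled(self, k: int) -> "CohortParams":
        """Same distributions with both group sizes multiplied by k."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            fractured=replace(self.fractured, n=self.fractured.n * k),
            nonfractured=replace(self.nonfractured, n=self.nonfractured.n * k),
        )


# ---------------------------------------------------------------------------
# Dependence calibration
# ---------------------------------------------------------------------------


def bivariate_orthant(z_a: float, z_b: float, rho: float) -> float:
    """P(Z_a ≤ z_a, Z_b ≤ z_b) for standard bivariate normal with corr ρ."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([z_a, z_b]))


def calibrate_rho(
    target_joint_positive: float,
    cutoff_a: float,
    cutoff_b: float,
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    tol: float = 1e-6,
) -> float:
    """Correlation ρ reproducing a target joint-positive probability.

    Positivity is score ≤ cutoff on both axes, so the target must be an
    achievable orthant probability: between the Fréchet bounds
    max(0, p_a + p_b − 1) and min(p_a, p_b) given the two Gaussian
    marginal positive probabilities p_a, p_b.  Root-found to ``tol`` on
    the probability scale; targets needing |ρ| ≥ 0.999 are rejected.
    """
    z_a = (cutoff_a - mean_a) / sd_a
    z_b = (cutoff_b - mean_b) / sd_b
    p_a = float(stats.norm.cdf(z_a))
    p_b = float(stats.norm.cdf(z_b))
    lo_bound = max(0.0, p_a + p_b - 1.0)
    hi_bound = min(p_a, p_b)
    if not (lo_bound < target_joint_positive < hi_bound):
        raise ValueError(
            f"target {target_joint_positive:.4f} outside the achievable "
            f"(Fréchet) interval ({lo_bound:.4f}, {hi_bound:.4f}) for marginal "
            f"positive probabilities {p_a:.4f} and {p_b:.4f}"
        )

    def f(rho: float) -> float:
        return bivariate_orthant(z_a, z_b, rho) - target_joint_positive

    f_lo, f_hi = f(-RHO_LIMIT), f(RHO_LIMIT)
    if not (f_lo < 0.0 < f_hi):
        raise ValueError(
            f"target {target_joint_positive:.4f} requires |rho| ≥ {RHO_LIMIT} "
            "(numerically at the Fréchet boundary)"
        )
    rho = optimize.brentq(f, -RHO_LIMIT, RHO_LIMIT, xtol=1e-9)
    # polish on the probability scale
    if abs(f(rho)) > tol:
        raise RuntimeError(f"rho calibration did not converge: residual {f(rho):.2e}")
    return float(rho)


@lru_cache(maxsize=None)
def study_rho(group: str) -> float:
    """ρ calibrated to the study's joint-positive cell for one group."""
    if group == "fractured":
        gp, target = CohortParams().fractured, study.PERCENT_FRACTURED[0] / 100.0
    elif group == "nonfractured":
        gp, target = CohortParams().nonfractured, study.PERCENT_NONFRACTURED[0] / 100.0
    else:
        raise ValueError(f"group must be 'fractured' or 'nonfractured', got {group!r}")
    return calibrate_rho(
        target,
        study.CUTOFF_BMD,
        study.CUTOFF_TBS,
        gp.bmd_mean,
        gp.bmd_sd,
        gp.tbs_mean,
        gp.tbs_sd,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_group(
    gp: GroupParams, rho: float, cov_specs: dict, group_idx: int, rng: np.random.Generator
) -> pd.DataFrame:
    cov = np.array(
        [
            [gp.tbs_sd**2, rho * gp.tbs_sd * gp.bmd_sd],
            [rho * gp.tbs_sd * gp.bmd_sd, gp.bmd_sd**2],
        ]
    )
    scores = rng.multivariate_normal([gp.tbs_mean, gp.bmd_mean], cov, size=gp.n)
    data = {"tbs": scores[:, 0], "ls_bmd": scores[:, 1]}
    for name, spec in cov_specs.items():
        mean, sd = spec[group_idx]
        data[name] = rng.normal(mean, sd, size=gp.n)
    df = pd.DataFrame(data)
    df["fracture"] = 1 - group_idx  # group_idx 0 = fractured
    return df


def generate_cohort(params: CohortParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort; deterministic for a given seed.

    Returns a DataFrame with the canonical cohort schema (fractured
    rows first).  Group correlations left as ``None`` in the params are
    calibrated to the study's joint-positive cell fractions at the
    standard cutoffs.
    """
    params = params or CohortParams()
    rho_f = params.fractured.rho
    rho_n = params.nonfractured.rho
    # rho left unset: calibrate to the study's joint-positive cell
    # fractions under this group's own moments at the standard cutoffs
    if rho_f is None:
        rho_f = calibrate_rho(
            study.PERCENT_FRACTURED[0] / 100.0,
            study.CUTOFF_BMD,
            study.CUTOFF_TBS,
            params.fractured.bmd_mean,
            params.fractured.bmd_sd,
            params.fractured.tbs_mean,
            params.fractured.tbs_sd,
        )
    if rho_n is None:
        rho_n = calibrate_rho(
            study.PERCENT_NONFRACTURED[0] / 100.0,
            study.CUTOFF_BMD,
            study.CUTOFF_TBS,
            params.nonfractured.bmd_mean,
            params.nonfractured.bmd_sd,
            params.nonfractured.tbs_mean,
            params.nonfractured.tbs_sd,
        )

    rng = np.random.default_rng(seed)
    frames = [
        _draw_group(params.fractured, rho_f, params.covariates, 0, rng),
        _draw_group(params.nonfractured, rho_n, params.covariates, 1, rng),
    ]
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df = df[cols]
    if params.t_score_ref is not None:
        mu_ref, sd_ref = params.t_score_ref
        df["ls_bmd_t_score"] = (df["ls_bmd"] - mu_ref) / sd_ref
    return df


# ---------------------------------------------------------------------------
# Baseline comparison (two-sample t and Levene per variable)
# ---------------------------------------------------------------------------


def baseline_comparison(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-wise baseline table with t-test and Levene test per variable.

    For every numeric variable (id and fracture excluded): group means ±
    SD, pooled mean ± SD, Levene's test for equal variances (centred at
    the mean), and a two-sample t-test — pooled-variance when Levene is
    non-significant at 0.05, Welch otherwise.  A variable with zero
    variance in both groups is flagged, not fatal.
    """
    if "fracture" not in cohort.columns:
        raise ValueError("cohort lacks a 'fracture' column")
    g1 = cohort[cohort["fracture"] == 1]
    g0 = cohort[cohort["fracture"] == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both disease groups need at least 2 rows")
    rows = []
    variables = [
        c for c in cohort.columns
        if c not in ("id", "fracture") and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    for var in variables:
        x1 = np.asarray(g1[var].dropna(), float)
        x0 = np.asarray(g0[var].dropna(), float)
        row = {
            "variable": var,
            "fractured_mean": x1.mean(),
            "fractured_sd": x1.std(ddof=1),
            "nonfractured_mean": x0.mean(),
            "nonfractured_sd": x0.std(ddof=1),
            "pooled_mean": np.concatenate([x1, x0]).mean(),
            "pooled_sd": np.concatenate([x1, x0]).std(ddof=1),
        }
        if x1.std(ddof=1) == 0 and x0.std(ddof=1) == 0:
            row.update(levene_stat=np.nan, levene_p=np.nan, t_stat=np.nan,
                       t_p=np.nan, equal_var=np.nan, flag="zero variance")
        else:
            lev_stat, lev_p = stats.levene(x1, x0, center="mean")
            equal_var = bool(lev_p >= 0.05)
            t_stat, t_p = stats.ttest_ind(x1, x0, equal_var=equal_var)
            row.update(levene_stat=lev_stat, levene_p=lev_p, t_stat=t_stat,
                       t_p=t_p, equal_var=equal_var, flag="")
        rows.append(row)
    return pd.DataFrame(rows)


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test from summary statistics (t, two-sided p)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------


def write_cohort_csv(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the canonical cohort CSV; the seed is recorded in a header
    comment so the file is self-describing and byte-reproducible."""
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    cohort.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (comment lines starting with '#' are skipped)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("tbs", "ls_bmd", "fracture") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns {missing}")
    return df
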