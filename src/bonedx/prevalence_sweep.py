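"""Post-test probabilities as a function of pre-test prevalence.

Sensitivity and specificity are (to first order) properties of the test;
the predictive values are not — they move with the pre-test probability
π through Bayes' theorem:

    PPV(π) = π·SE / (π·SE + (1−π)(1−SP))
    NPV(π) = (1−π)·SP / ((1−π)·SP + π(1−SE))

The sweep evaluates each test (and each combination rule) over a grid of
prevalences, attaching Mercaldo-style logit intervals computed with the
*study's* diseased/non-diseased sample sizes held fixed — the variance
bookkeeping a screening exercise uses when transplanting an observed
SE/SP to a hypothetical population (an approximation: the hypothetical
population contributes no sampling error of its own).

A linear regression of predictive value on prevalence (both on the
percent scale) summarizes how strongly each post-test probability tracks
the pre-test probability; Pearson R is reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_core import DEFAULT_LEVEL, mercaldo_pv_ci

#: Default prevalence grid (proportions): 2–40% with the study's own
#: prevalence 8.67% and a finer step around the clinically plausible
#: 8–26% band.
DEFAULT_GRID = (
    0.02, 0.04, 0.06, 0.08, 0.0867, 0.10, 0.12, 0.14, 0.15, 0.16,
    0.18, 0.20, 0.22, 0.24, 0.25, 0.26, 0.30, 0.40,
)


def ppv_at(se, sp, prevalence):
    """Positive predictive value at prevalence π (vectorized).

    Undefined where the denominator vanishes (π = 0 with SP = 1 never
    produces a positive); returned as NaN there.
    """
    se = np.asarray(se, float)
    sp = np.asarray(sp, float)
    pi = np.asarray(prevalence, float)
    num = pi * se
    den = num + (1.0 - pi) * (1.0 - sp)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def npv_at(se, sp, prevalence):
    """Negative predictive value at prevalence π (vectorized)."""
    se = np.asarray(se, float)
    sp = np.asarray(sp, float)
    pi = np.asarray(prevalence, float)
    num = (1.0 - pi) * sp
    den = num + pi * (1.0 - se)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PrevalenceCurve:
    """Predictive values (with CIs) of several tests over a prevalence grid.

    ``ppv``/``npv`` map test label → (estimate, lower, upper) arrays
    aligned with ``grid``.
    """

    grid: np.ndarray
    labels: tuple[str, ...]
    ppv: dict
    npv: dict
    se: dict
    sp: dict
    n_d: int
    n_h: int
    level: float

    def to_frame(self, measure: str) -> pd.DataFrame:
        """Wide table (one row per prevalence) of estimates and bounds."""
        if measure not in ("ppv", "npv"):
            raise ValueError(f"measure must be 'ppv' or 'npv', got {measure!r}")
        data = {"prevalence_pct": 100.0 * self.grid}
        store = getattr(self, measure)
        for label in self.labels:
            est, lo, hi = store[label]
            data[f"{label} {measure.upper()} %"] = 100.0 * est
            data[f"{label} lower %"] = 100.0 * lo
            data[f"{label} upper %"] = 100.0 * hi
        return pd.DataFrame(data)


@dataclass(frozen=True)
class SweepRegression:
    """OLS of a predictive value on prevalence (percent scale)."""

    target: str
    pearson_r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.pearson_r)


def sweep(
    tests: Sequence[tuple[str, float, float]],
    grid: Sequence[float] = DEFAULT_GRID,
    n_d: int = 86,
    n_h: int = 906,
    level: float = DEFAULT_LEVEL,
) -> PrevalenceCurve:
    """Evaluate PPV/NPV (with Mercaldo-style CIs) on a prevalence grid.

    ``tests`` is a sequence of (label, SE, SP).  The grid must be
    strictly increasing proportions in (0, 1).  ``n_d``/``n_h`` are the
    sample sizes behind the SE/SP estimates and drive the interval
    widths at every grid point.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("prevalence grid is empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if not tests:
        raise ValueError("no tests supplied")

    labels, ppv, npv, se_map, sp_map = [], {}, {}, {}, {}
    for label, se, sp in tests:
        p_est = np.empty(grid.size)
        p_lo = np.empty(grid.size)
        p_hi = np.empty(grid.size)
        n_est = np.empty(grid.size)
        n_lo = np.empty(grid.size)
        n_hi = np.empty(grid.size)
        boundary = se in (0.0, 1.0) or sp in (0.0, 1.0)
        for i, pi in enumerate(grid):
            if boundary:
                # closed-form points still defined; intervals degenerate
                p_est[i] = ppv_at(se, sp, pi)
                n_est[i] = npv_at(se, sp, pi)
                p_lo[i] = p_hi[i] = p_est[i]
                n_lo[i] = n_hi[i] = n_est[i]
            else:
                ppv_ci, npv_ci = mercaldo_pv_ci(se, sp, n_d, n_h, pi, level)
                p_est[i], p_lo[i], p_hi[i] = ppv_ci.estimate, ppv_ci.lower, ppv_ci.upper
                n_est[i], n_lo[i], n_hi[i] = npv_ci.estimate, npv_ci.lower, npv_ci.upper
        labels.append(label)
        ppv[label] = (p_est, p_lo, p_hi)
        npv[label] = (n_est, n_lo, n_hi)
        se_map[label] = float(se)
        sp_map[label] = float(sp)
    return PrevalenceCurve(
        grid=grid,
        labels=tuple(labels),
        ppv=ppv,
        npv=npv,
        se=se_map,
        sp=sp_map,
        n_d=int(n_d),
        n_h=int(n_h),
        level=level,
    )


def sweep_regression(curve: PrevalenceCurve, measure: str, label: str) -> SweepRegression:
    """Regress one test's predictive value on prevalence over the grid.

    Both variables are on the percent scale; returns signed Pearson R,
    R² (= R² of the simple regression), and the regression p-value.  A
    constant target has no defined correlation and yields NaN fields.
    """
    if measure not in ("ppv", "npv"):
        raise ValueError(f"measure must be 'ppv' or 'npv', got {measure!r}")
    if label not in getattr(curve, measure):
        raise ValueError(f"unknown test label {label!r}")
    if curve.grid.size < 3:
        raise ValueError("need at least 3 grid points for a regression")
    x = 100.0 * curve.grid
    y = 100.0 * getattr(curve, measure)[label][0]
    target = f"{measure}_{label}"
    if np.allclose(y, y[0]):
        return SweepRegression(target, float("nan"), float("nan"), float("nan"), 0.0, float(y[0]))
    res = stats.linregress(x, y)
    return SweepRegression(
        target=target,
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )
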