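"""Adaptive two-group testing and effect sizes.

The screening strategy for a small two-group cohort: test each variable or
miRNA for equality of variance with a folded two-tailed Fisher F test, then
route to the test whose assumptions the data support.

* ``clinical`` mode (medical/neuropsychological/neuroimaging variables):
  equal variances -> Student's t; unequal -> Welch's t.
* ``mirna`` mode (expression values): equal variances -> Student's t;
  unequal -> Shapiro-Wilk normality per group; both normal -> Welch's t;
  otherwise Mann-Whitney U.

All p-values are two-tailed and deliberately uncorrected: the screen's goal
is candidate discovery in a small sample, and multiplicity control is
applied later, in the exploratory correlation stage only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_VARIANCE = 0.05
ALPHA_NORMALITY = 0.05


@dataclass
class VarianceTest:
    f: float
    p: float
    df: tuple[int, int]
    flags: tuple[str, ...] = ()


@dataclass
class DiffResult:
    """Per-feature two-group outcome with the evidence for the chosen test."""

    feature: str
    control_mean: float
    case_mean: float
    percent_change: float
    variance_test_p: float
    chosen_test: Literal["student", "welch", "mannwhitney"]
    test_p: float
    n_control: int
    n_case: int
    normality_p: tuple[float, float] | None = None
    flags: tuple[str, ...] = ()


def variance_equality_test(x, y) -> VarianceTest:
    """Folded two-tailed F test: larger sample variance over smaller.

    Both groups constant -> F and p undefined (NaN), flagged ``degenerate``.
    One group constant -> F infinite, p -> 0, flagged ``constant-group``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values for a variance test")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return VarianceTest(np.nan, np.nan, (len(x) - 1, len(y) - 1), ("degenerate",))
    if vx >= vy:
        num, den, dfn, dfd = vx, vy, len(x) - 1, len(y) - 1
    else:
        num, den, dfn, dfd = vy, vx, len(y) - 1, len(x) - 1
    if den == 0:
        return VarianceTest(np.inf, 0.0, (dfn, dfd), ("constant-group",))
    f = num / den
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return VarianceTest(f, p, (dfn, dfd), ())


def percent_change(control_mean: float, case_mean: float) -> float:
    """100 x (case - control) / control, reported to one decimal.

    Undefined (NaN) when the control mean is zero.
    """
    if control_mean == 0:
        return float("nan")
    return round(100.0 * (case_mean - control_mean) / control_mean, 1)


def adaptive_group_test(
    x,
    y,
    mode: Literal["clinical", "mirna"] = "mirna",
    feature: str = "",
) -> DiffResult:
    """Run the variance-gated decision tree on control (x) vs case (y) values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"{feature or 'feature'}: each group needs >= 3 finite values")
    if mode not in ("clinical", "mirna"):
        raise ValueError(f"unknown mode {mode!r}")

    flags: list[str] = []
    vt = variance_equality_test(x, y)
    flags.extend(vt.flags)
    normality: tuple[float, float] | None = None

    if "degenerate" in vt.flags:
        # Both groups constant: variances trivially equal.
        chosen = "student"
    elif vt.p > ALPHA_VARIANCE:
        chosen = "student"
    elif mode == "clinical":
        chosen = "welch"
    else:
        sx = stats.shapiro(x).pvalue if len(np.unique(x)) > 1 else 0.0
        sy = stats.shapiro(y).pvalue if len(np.unique(y)) > 1 else 0.0
        normality = (sx, sy)
        chosen = "welch" if (sx > ALPHA_NORMALITY and sy > ALPHA_NORMALITY) else "mannwhitney"

    if chosen == "student":
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
            flags.append("constant-data")
        else:
            p = stats.ttest_ind(x, y, equal_var=True).pvalue
    elif chosen == "welch":
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
    else:
        pooled = np.r_[x, y]
        tie_frac = 1.0 - len(np.unique(pooled)) / len(pooled)
        if tie_frac > 0.5:
            flags.append("tie-heavy")
            method = "asymptotic"  # normal approximation with tie correction
        else:
            method = "auto"
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue

    return DiffResult(
        feature=feature,
        control_mean=float(x.mean()),
        case_mean=float(y.mean()),
        percent_change=percent_change(float(x.mean()), float(y.mean())),
        variance_test_p=float(vt.p),
        chosen_test=chosen,
        test_p=float(p),
        n_control=len(x),
        n_case=len(y),
        normality_p=normality,
        flags=tuple(flags),
    )


def diff_results_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    """Tabulate DiffResults in report form."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "control_mean": [r.control_mean for r in results],
            "case_mean": [r.case_mean for r in results],
            "percent_change": [r.percent_change for r in results],
            "variance_test_p": [r.variance_test_p for r in results],
            "chosen_test": [r.chosen_test for r in results],
            "test_p": [r.test_p for r in results],
            "n_control": [r.n_control for r in results],
            "n_case": [r.n_case for r in results],
        }
    )


def adaptive_test_matrix(
    values: pd.DataFrame,
    groups: pd.Series,
    mode: Literal["clinical", "mirna"] = "mirna",
    case_label: str = "AUD",
    control_label: str = "control",
) -> pd.DataFrame:
    """Adaptive test for every row of a feature x sample matrix."""
    ctrl_cols = groups.index[groups == control_label]
    case_cols = groups.index[groups == case_label]
    results = []
    for feat, row in values.iterrows():
        results.append(
            adaptive_group_test(
                row[ctrl_cols].to_numpy(), row[case_cols].to_numpy(),
                mode=mode, feature=str(feat),
            )
        )
    return diff_results_frame(results)


def normalize_volumes(region_volumes: pd.DataFrame, whole_brain: pd.Series) -> pd.DataFrame:
    """Divide each subject's regional volumes by that subject's whole-brain
    volume (rows = subjects), removing global shrinkage from regional effects."""
    wb = whole_brain.reindex(region_volumes.index)
    if wb.isna().any():
        missing = list(region_volumes.index[wb.isna()])
        raise ValueError(f"missing whole-brain volume for subjects: {missing}")
    if (wb <= 0).any():
        raise ValueError("whole-brain volumes must be positive")
    return region_volumes.div(wb, axis=0)
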