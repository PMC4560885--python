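"""Pearson correlation screen with R->T significance and BH-FDR control.

miRNA expression is screened against clinical, neuroimaging and drinking
variables within a group context (case, control, or all subjects).  Missing
values are handled by pairwise deletion (each pair keeps its own N).  A
Pearson coefficient is converted to a t statistic,

    t = R * sqrt((N - 2) / (1 - R^2)),   df = N - 2,

giving a two-tailed p.  Two screening modes exist:

* targeted — nominally significant variables against Tier A/B miRNAs,
  uncorrected (the pairs are pre-selected by the parametric screen);
* exploratory — all policy-allowed miRNA x variable pairs, with
  Benjamini-Hochberg FDR over the whole family within one group context.

The pair policy excludes uninformative within-class pairs (miRNA-miRNA,
region-region) and restricts drinking variables to the case group, since
controls do not drink.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class PearsonResult(NamedTuple):
    r: float
    n: int
    flags: tuple[str, ...] = ()


@dataclass
class PairPolicy:
    """Which variable pairs a screen may test.

    ``classes`` maps variable/miRNA names to a class label ('mirna',
    'region', 'clinical', 'drinking'); pairs whose class pair is in
    ``excluded`` are skipped, and 'drinking' variables are only tested in
    the case-group context.
    """

    classes: Mapping[str, str] = field(default_factory=dict)
    excluded: frozenset[frozenset[str]] = frozenset(
        {frozenset({"mirna"}), frozenset({"region"})}
    )
    drinking_groups: frozenset[str] = frozenset({"AUD"})

    def allows(self, class_a: str, class_b: str, group: str) -> bool:
        if frozenset({class_a, class_b}) in self.excluded:
            return False
        if "drinking" in (class_a, class_b) and group not in self.drinking_groups:
            return False
        return True


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation on pairwise-complete observations.

    Returns (R, N).  Fewer than 3 complete pairs or a constant retained
    vector makes R undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[keep], y[keep]
    n = int(keep.sum())
    if n < 3:
        return PearsonResult(np.nan, n, ("too-few-pairs",))
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return PearsonResult(np.nan, n, ("constant-vector",))
    r = float(np.corrcoef(xs, ys)[0, 1])
    return PearsonResult(r, n, ())


def r_to_t_p(r: float, n: int) -> tuple[float, float]:
    """Significance of a Pearson coefficient via the R->T transformation."""
    if n < 3:
        raise ValueError("need N >= 3")
    if abs(r) > 1:
        raise ValueError("|R| must be <= 1")
    if abs(r) == 1:
        return (np.inf if r > 0 else -np.inf, 0.0)  # exact fit
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(
    expression: pd.DataFrame,
    variables: pd.DataFrame,
    policy: PairPolicy,
    groups: pd.Series,
    group: str = "AUD",
    mode: str = "exploratory",
    mirna_subset: Sequence[str] | None = None,
    variable_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlate miRNA expression rows against variable columns.

    ``expression`` is features x samples; ``variables`` is samples x
    variables; ``groups`` labels each sample.  ``group`` selects the
    context: a group label, or 'all' for the combined cohort.  In targeted
    mode no multiplicity correction is applied (fdr = NaN); in exploratory
    mode BH-FDR is computed over the full family of testable pairs.
    """
    if mode not in ("exploratory", "targeted"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(groups.unique()) | {"all"}
    if group not in known:
        raise ValueError(f"unknown group label {group!r}")
    shared = [s for s in expression.columns if s in variables.index]
    if not shared:
        raise ValueError("expression and variables share no sample ids")
    g = groups.reindex(shared)
    cols = shared if group == "all" else [s for s in shared if g[s] == group]

    mirnas = list(mirna_subset) if mirna_subset is not None else list(expression.index)
    varnames = (
        list(variable_subset) if variable_subset is not None else list(variables.columns)
    )
    records = []
    for m in mirnas:
        cm = policy.classes.get(m, "mirna")
        x_full = expression.loc[m, cols].to_numpy(dtype=float)
        for v in varnames:
            cv = policy.classes.get(v, "clinical")
            if not policy.allows(cm, cv, group):
                continue
            res = pearson_r(x_full, variables.loc[cols, v].to_numpy(dtype=float))
            if res.flags:
                continue
            t, p = r_to_t_p(res.r, res.n)
            records.append((m, v, group, res.r, res.n, t, p))
    out = pd.DataFrame(
        records, columns=["mirna", "variable", "group", "r", "n", "t", "p"]
    )
    if mode == "exploratory":
        out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    else:
        out["fdr"] = np.nan
    return out
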