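"""Cross-platform biomarker tiers.

Sequencing is the primary quantification; the array re-measures the same
features with less sensitivity, serving as cross-platform validation:

* Tier A — sequencing p < 0.05, array p < 0.10, and directionally
  consistent percent changes on both platforms (stringent, cross-validated).
* Tier B — sequencing p < 0.05 with directionally consistent array change
  regardless of the array p-value.
* Tier C — miRNAs whose exploratory correlation with any clinical or
  neuroimaging variable in the case group survives BH FDR < 0.05.

"Consistent" requires both percent changes nonzero with the same sign; a
zero array change is conservatively treated as inconsistent.  Tiers are
exclusive strata with precedence A > B > C; a Tier A/B miRNA that also
meets the Tier C rule keeps A/B and records the correlation as secondary
evidence.  Features absent from the array platform cannot reach A or B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEQ_ALPHA = 0.05
ARRAY_ALPHA = 0.10
FDR_THRESHOLD = 0.05


@dataclass
class TierAssignment:
    feature: str
    tier: str  # "A" | "B" | "C" | "none"
    seq_p: float = math.nan
    seq_pct_change: float = math.nan
    array_p: float = math.nan
    array_pct_change: float = math.nan
    direction_consistent: bool = False
    evidence: Mapping | None = None  # triggering correlation record for Tier C


def _coerce_results(results) -> pd.DataFrame:
    """Accept a DataFrame (feature/test_p/percent_change columns) or an
    iterable of DiffResult-like objects."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(
            {
                "feature": [r.feature for r in results],
                "test_p": [r.test_p for r in results],
                "percent_change": [r.percent_change for r in results],
            }
        )
    if df["feature"].duplicated().any():
        dupes = sorted(df.loc[df["feature"].duplicated(), "feature"].unique())
        raise ValueError(f"duplicate feature ids: {dupes}")
    return df.set_index("feature")


def assign_tiers(seq_results, array_results,
                 seq_alpha: float = SEQ_ALPHA,
                 array_alpha: float = ARRAY_ALPHA) -> list[TierAssignment]:
    """Assign Tier A/B/none from paired per-platform differential results.

    Features are matched by id; sequencing features missing from the array
    remain untiered (no imputation).
    """
    seq = _coerce_results(seq_results)
    arr = _coerce_results(array_results)
    out = []
    for feat, row in seq.iterrows():
        sp, spc = float(row["test_p"]), float(row["percent_change"])
        if feat in arr.index:
            ap = float(arr.loc[feat, "test_p"])
            apc = float(arr.loc[feat, "percent_change"])
            consistent = (
                np.isfinite(spc) and np.isfinite(apc)
                and spc != 0 and apc != 0
                and np.sign(spc) == np.sign(apc)
            )
        else:
            ap = apc = math.nan
            consistent = False
        if sp < seq_alpha and consistent and ap < array_alpha:
            tier = "A"
        elif sp < seq_alpha and consistent:
            tier = "B"
        else:
            tier = "none"
        out.append(
            TierAssignment(
                feature=str(feat), tier=tier, seq_p=sp, seq_pct_change=spc,
                array_p=ap, array_pct_change=apc, direction_consistent=bool(consistent),
            )
        )
    return out


def assign_tier_c(
    correlations: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    case_label: str = "AUD",
) -> list[TierAssignment]:
    """Tier C from the exploratory correlation screen.

    A miRNA gains Tier C iff any of its correlation records in the
    case-group context has FDR below the threshold.  ``correlations`` must
    carry columns mirna/variable/group/r/n/p/fdr.
    """
    required = {"mirna", "group", "fdr"}
    missing = required - set(correlations.columns)
    if missing:
        raise ValueError(f"correlation records lack columns: {sorted(missing)}")
    if correlations["fdr"].isna().any():
        raise ValueError("correlation records lack FDR values")
    hits = correlations[
        (correlations["group"] == case_label) & (correlations["fdr"] < fdr_threshold)
    ]
    out = []
    for feat, block in hits.groupby("mirna", sort=True):
        best = block.loc[block["fdr"].idxmin()]
        out.append(
            TierAssignment(feature=str(feat), tier="C", evidence=best.to_dict())
        )
    return out


def merge_tiers(
    ab: Sequence[TierAssignment], c: Sequence[TierAssignment]
) -> list[TierAssignment]:
    """Combine A/B assignments with Tier C, precedence A > B > C.

    A feature already in A or B keeps its tier; a matching Tier C record is
    attached as secondary evidence.
    """
    by_feat = {t.feature: t for t in ab}
    out = list(ab)
    for tc in c:
        existing = by_feat.get(tc.feature)
        if existing is None or existing.tier == "none":
            if existing is not None:
                out.remove(existing)
            merged = TierAssignment(
                feature=tc.feature, tier="C", evidence=tc.evidence,
                seq_p=existing.seq_p if existing else math.nan,
                seq_pct_change=existing.seq_pct_change if existing else math.nan,
                array_p=existing.array_p if existing else math.nan,
                array_pct_change=existing.array_pct_change if existing else math.nan,
            )
            out.append(merged)
            by_feat[tc.feature] = merged
        else:
            existing.evidence = tc.evidence
    return out


def tiers_frame(assignments: Iterable[TierAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [t.feature for t in assignments],
            "tier": [t.tier for t in assignments],
            "seq_p": [t.seq_p for t in assignments],
            "seq_pct_change": [t.seq_pct_change for t in assignments],
            "array_p": [t.array_p for t in assignments],
            "array_pct_change": [t.array_pct_change for t in assignments],
            "direction_consistent": [t.direction_consistent for t in assignments],
        }
    )
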