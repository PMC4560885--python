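"""The biomarker discovery model: data in, fitted results out.

:class:`SerumBiomarkerModel` holds a two-platform expression dataset (raw
sequencing counts plus matched array intensities) and a subject table;
``fit()`` runs the screening pipeline — detection filtering, RPM
normalization, adaptive two-group tests per platform and per clinical
variable, cross-platform tier assignment, and the targeted/exploratory
correlation screens — and returns a :class:`SerumBiomarkerResults` carrying
the per-feature estimates, tier table, correlation records and a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import correlate, groupstats, quantify, tiers
from .cluster import ClusterTree, cluster_profiles


class SerumBiomarkerModel:
    """Two-group, two-platform serum miRNA biomarker screen.

    Parameters
    ----------
    seq_counts : DataFrame
        Raw integer counts, features x samples (primary platform).
    array_intensity : DataFrame or None
        Matched positive intensities, features x samples (validation
        platform).  Without it no feature can reach Tier A or B.
    subjects : DataFrame
        Indexed by sample id, with a group column plus clinical /
        neuroimaging / drinking variables.
    variable_classes : mapping, optional
        Variable name -> class ('clinical' | 'region' | 'drinking') for the
        correlation pair policy; unknown variables default to 'clinical'.
    """

    def __init__(
        self,
        seq_counts: pd.DataFrame,
        array_intensity: pd.DataFrame | None,
        subjects: pd.DataFrame,
        variable_classes: Mapping[str, str] | None = None,
        group_col: str = "group",
        case_label: str = "AUD",
        control_label: str = "control",
    ) -> None:
        missing = [s for s in seq_counts.columns if s not in subjects.index]
        if missing:
            raise ValueError(f"samples missing from subject table: {missing}")
        self.seq_counts = seq_counts
        self.array_intensity = array_intensity
        self.subjects = subjects
        self.group_col = group_col
        self.case_label = case_label
        self.control_label = control_label
        self.variable_classes = dict(variable_classes or {})

    @classmethod
    def from_cohort(cls, cohort) -> "SerumBiomarkerModel":
        """Build from a :class:`seromir.simulate.SyntheticCohort`."""
        return cls(
            seq_counts=cohort.seq_counts,
            array_intensity=cohort.array_intensity,
            subjects=cohort.subjects,
            variable_classes=cohort.variable_classes,
        )

    @property
    def groups(self) -> pd.Series:
        return self.subjects[self.group_col]

    def variable_frame(self) -> pd.DataFrame:
        return self.subjects.drop(columns=[self.group_col])

    def fit(
        self,
        min_subjects: int = 5,
        seq_alpha: float = 0.05,
        array_alpha: float = 0.10,
        fdr_threshold: float = 0.05,
        correlations: bool = True,
    ) -> "SerumBiomarkerResults":
        groups = self.groups
        filtered = quantify.detection_filter(self.seq_counts, min_subjects=min_subjects)
        rpm = quantify.rpm_normalize(filtered)
        seq_diff = groupstats.adaptive_test_matrix(
            rpm.values, groups, mode="mirna",
            case_label=self.case_label, control_label=self.control_label,
        )
        if self.array_intensity is not None:
            arr = self.array_intensity.loc[
                self.array_intensity.index.intersection(filtered.index)
            ]
            array_diff = groupstats.adaptive_test_matrix(
                arr, groups, mode="mirna",
                case_label=self.case_label, control_label=self.control_label,
            )
        else:
            array_diff = groupstats.diff_results_frame([])

        # Clinical-style variables: adaptive clinical tree; variables with
        # fewer than 3 finite values in either group (e.g. case-only
        # drinking indices) are screened out of the two-group comparison.
        var_rows = []
        variables = self.variable_frame()
        ctrl_ids = groups.index[groups == self.control_label]
        case_ids = groups.index[groups == self.case_label]
        for v in variables.columns:
            x = variables.loc[ctrl_ids, v].to_numpy(dtype=float)
            y = variables.loc[case_ids, v].to_numpy(dtype=float)
            if np.isfinite(x).sum() < 3 or np.isfinite(y).sum() < 3:
                continue
            var_rows.append(groupstats.adaptive_group_test(x, y, mode="clinical", feature=v))
        variable_diff = groupstats.diff_results_frame(var_rows)

        ab = tiers.assign_tiers(
            seq_diff, array_diff if len(array_diff) else pd.DataFrame(
                columns=["feature", "test_p", "percent_change"]
            ),
            seq_alpha=seq_alpha, array_alpha=array_alpha,
        )

        targeted = exploratory = None
        if correlations and variables.shape[1]:
            policy = correlate.PairPolicy(classes=dict(self.variable_classes))
            sig_vars = (
                variable_diff.loc[variable_diff["test_p"] < 0.05, "feature"].tolist()
                if len(variable_diff) else []
            )
            ab_feats = [t.feature for t in ab if t.tier in ("A", "B")]
            drinking = [
                v for v, c in self.variable_classes.items() if c == "drinking"
            ]
            frames = []
            if ab_feats:
                for ctx in (self.case_label, self.control_label, "all"):
                    targets = sig_vars + (drinking if ctx == self.case_label else [])
                    if not targets:
                        continue
                    frames.append(
                        correlate.correlation_screen(
                            rpm.values, variables, policy, groups, group=ctx,
                            mode="targeted", mirna_subset=ab_feats,
                            variable_subset=[t for t in targets if t in variables.columns],
                        )
                    )
            targeted = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["mirna", "variable", "group", "r", "n", "t", "p", "fdr"])
            )
            exploratory = correlate.correlation_screen(
                rpm.values, variables, policy, groups,
                group=self.case_label, mode="exploratory",
            )
            tier_c = tiers.assign_tier_c(
                exploratory, fdr_threshold=fdr_threshold, case_label=self.case_label
            )
            assignments = tiers.merge_tiers(ab, tier_c)
        else:
            assignments = ab

        return SerumBiomarkerResults(
            model=self,
            rpm=rpm,
            seq_diff=seq_diff,
            array_diff=array_diff,
            variable_diff=variable_diff,
            tier_assignments=assignments,
            targeted_correlations=targeted,
            exploratory_correlations=exploratory,
            thresholds={
                "min_subjects": min_subjects, "seq_alpha": seq_alpha,
                "array_alpha": array_alpha, "fdr_threshold": fdr_threshold,
            },
        )


@dataclass
class SerumBiomarkerResults:
    """Fitted screen: per-feature differential estimates, tiers, correlations."""

    model: SerumBiomarkerModel
    rpm: quantify.ExpressionMatrix
    seq_diff: pd.DataFrame
    array_diff: pd.DataFrame
    variable_diff: pd.DataFrame
    tier_assignments: list
    targeted_correlations: pd.DataFrame | None
    exploratory_correlations: pd.DataFrame | None
    thresholds: dict = field(default_factory=dict)

    @property
    def tiers(self) -> pd.DataFrame:
        return tiers.tiers_frame(self.tier_assignments)

    @property
    def tier_counts(self) -> dict[str, int]:
        t = self.tiers
        return {k: int((t["tier"] == k).sum()) for k in ("A", "B", "C")}

    def tier_features(self, *which: str) -> list[str]:
        t = self.tiers
        return t.loc[t["tier"].isin(which), "feature"].tolist()

    def cluster(self, scale_mode: str = "zscore") -> ClusterTree:
        """Cluster Tier A/B miRNA RPM profiles together with the nominally
        significant variables across subjects (the mixed-profile tree)."""
        feats = self.tier_features("A", "B")
        blocks = []
        if feats:
            blocks.append(self.rpm.values.loc[feats])
        if len(self.variable_diff):
            sig = self.variable_diff.loc[self.variable_diff["test_p"] < 0.05, "feature"]
            vars_t = self.model.variable_frame()[list(sig)].T
            vars_t = vars_t.loc[:, self.rpm.values.columns.intersection(vars_t.columns)]
            if len(vars_t):
                blocks.append(vars_t.reindex(columns=self.rpm.values.columns))
        if not blocks:
            raise ValueError("nothing to cluster: no Tier A/B features or significant variables")
        mat = pd.concat(blocks).dropna(axis=1)
        return cluster_profiles(mat, scale_mode=scale_mode)

    def summary(self) -> str:
        n_ctrl = int((self.model.groups == self.model.control_label).sum())
        n_case = int((self.model.groups == self.model.case_label).sum())
        counts = self.tier_counts
        lines = [
            "Serum miRNA biomarker screen",
            "=" * 44,
            f"Samples: {n_ctrl} {self.model.control_label} vs {n_case} {self.model.case_label}",
            f"Features after detection filter: {len(self.seq_diff)}"
            f" (min subjects = {self.thresholds.get('min_subjects')})",
            f"Nominally significant (seq, p < {self.thresholds.get('seq_alpha')}):"
            f" {int((self.seq_diff['test_p'] < self.thresholds.get('seq_alpha', 0.05)).sum())}",
            f"Tier A: {counts['A']}   Tier B: {counts['B']}   Tier C: {counts['C']}",
        ]
        t = self.tiers
        picked = t[t["tier"].isin(["A", "B"])].sort_values(["tier", "seq_p"])
        if len(picked):
            lines.append("-" * 44)
            lines.append(f"{'feature':<18}{'tier':<6}{'seq %ch':>9}{'seq p':>8}{'arr %ch':>9}{'arr p':>8}")
            for _, r in picked.iterrows():
                lines.append(
                    f"{r['feature']:<18}{r['tier']:<6}{r['seq_pct_change']:>9.1f}"
                    f"{r['seq_p']:>8.3f}{r['array_pct_change']:>9.1f}{r['array_p']:>8.3f}"
                )
        return "\n".join(lines)
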