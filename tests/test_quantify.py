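"""Read counting, normalization, detection filtering and maturity trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seromir.quantify import (
    Precursor,
    ReadAlignment,
    detection_filter,
    maturity_trend,
    percent_of_total,
    quantify_alignments,
    relative_mature_windows,
    rpm_normalize,
)
from seromir.simulate import generate_annotation, generate_reads


def read(start, end, strand="+", chrom="chr1"):
    return ReadAlignment(chrom=chrom, start=start, end=end, strand=strand)


class TestQuantifyAlignments:
    def test_read_identical_to_5p_counts_only_5p(self, precursor):
        counts = quantify_alignments([read(1015, 1039)], [precursor])
        assert counts["miR-x-5p"] == 1
        assert counts["miR-x-3p"] == 0
        assert counts["mir-x"] == 0

    def test_opposite_strand_read_is_not_counted(self, precursor):
        counts = quantify_alignments([read(1015, 1039, strand="-")], [precursor])
        assert counts.sum() == 0

    def test_partial_overlap_falls_back_to_precursor(self, precursor):
        # Read overlapping the hairpin loop only: no mature call.
        counts = quantify_alignments([read(1045, 1067)], [precursor])
        assert counts["mir-x"] == 1
        assert counts["miR-x-5p"] == 0

    def test_ninety_percent_rule_boundary(self, precursor):
        # 22 nt read shifted so overlap with -5p is exactly 20 (>= 19.8) vs 19.
        assert quantify_alignments([read(1013, 1035)], [precursor])["miR-x-5p"] == 1
        assert quantify_alignments([read(1012, 1034)], [precursor])["miR-x-5p"] == 0

    def test_agrees_with_exhaustive_scan(self, annotation):
        """Counting oracle: brute-force per-read interval arithmetic."""
        rng = np.random.default_rng(7)
        reads = [
            ReadAlignment(
                chrom="chr1",
                start=int(s),
                end=int(s) + 22,
                strand="+" if rng.random() < 0.5 else "-",
            )
            for s in rng.integers(980, 2140, size=50)
        ]
        counts = quantify_alignments(reads, annotation)
        expected = {f: 0 for f in counts.index}
        for r in reads:
            for p in annotation:
                if r.strand != p.strand:
                    continue
                L = r.end - r.start
                assigned = None
                for arm, iv in (("5p", p.mature5p), ("3p", p.mature3p)):
                    ov = max(0, min(r.end, iv[1]) - max(r.start, iv[0]))
                    if ov >= 0.9 * L and assigned is None:
                        assigned = p.mature_ids[arm]
                if assigned is None and max(0, min(r.end, p.end) - max(r.start, p.start)) > 0:
                    assigned = p.precursor_id
                if assigned is not None:
                    expected[assigned] += 1
        assert counts.to_dict() == expected

    def test_generated_half_mature_reads_within_binomial_bounds(self, precursor):
        n = 400
        reads = generate_reads([precursor], mature_fraction=0.5, n_reads=n, seed=11)
        counts = quantify_alignments(reads, [precursor])
        mature = counts["miR-x-5p"] + counts["miR-x-3p"]
        # Background (uniform) reads also satisfy the 90% rule with a
        # geometric probability; enumerate it exactly.
        L = 22
        q = np.mean(
            [
                quantify_alignments([read(s, s + L)], [precursor])[
                    ["miR-x-5p", "miR-x-3p"]
                ].sum()
                > 0
                for s in range(precursor.start, precursor.end - L + 1)
            ]
        )
        p_mature = 0.5 + 0.5 * q
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p_mature)
        assert lo <= mature <= hi

    def test_duplicate_feature_ids_rejected(self, precursor):
        with pytest.raises(ValueError, match="duplicate"):
            quantify_alignments([], [precursor, precursor])


class TestNormalization:
    def test_rpm_arithmetic(self):
        counts = pd.DataFrame({"s": [50, 2_000_000 - 50]}, index=["a", "b"])
        assert rpm_normalize(counts).values.loc["a", "s"] == pytest.approx(25.0)

    def test_rpm_is_identity_on_million_total(self):
        counts = pd.DataFrame({"s": [250_000, 750_000]}, index=["a", "b"])
        out = rpm_normalize(counts).values
        assert np.allclose(out["s"], [250_000, 750_000])

    def test_rpm_columns_sum_to_million(self, small_counts):
        out = rpm_normalize(small_counts).values
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_percent_arithmetic_and_conservation(self):
        counts = pd.DataFrame({"s": [50, 950]}, index=["a", "b"])
        out = percent_of_total(counts)
        assert out.values.loc["a", "s"] == pytest.approx(5.0)
        assert out.values["s"].sum() == pytest.approx(100.0)

    def test_rpm_and_percent_differ_by_1e4(self, small_counts):
        rpm = rpm_normalize(small_counts).values
        pct = percent_of_total(small_counts).values
        assert np.allclose(rpm, pct * 1e4)

    def test_zero_column_flagged_not_fatal(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        out = rpm_normalize(counts)
        assert out.zero_columns == ("s2",)
        assert (out.values["s2"] == 0).all()


class TestDetectionFilter:
    @pytest.mark.parametrize("n_detected,kept", [(4, False), (5, True), (6, True)])
    def test_min_subjects_boundary(self, n_detected, kept):
        row = [1] * n_detected + [0] * (30 - n_detected)
        counts = pd.DataFrame([row], index=["mir-a"], columns=[f"s{i}" for i in range(30)])
        out = detection_filter(counts, min_subjects=5)
        assert ("mir-a" in out.index) is kept

    def test_all_zero_matrix_empties(self):
        counts = pd.DataFrame(0, index=["a", "b"], columns=[f"s{i}" for i in range(6)])
        assert len(detection_filter(counts, min_subjects=5)) == 0

    def test_order_preserved(self, small_counts):
        out = detection_filter(small_counts, min_subjects=1)
        assert list(out.index) == [f for f in small_counts.index if f in out.index]

    def test_min_subjects_larger_than_cohort_rejected(self, small_counts):
        with pytest.raises(ValueError):
            detection_filter(small_counts, min_subjects=99)


class TestMaturityTrend:
    def test_all_mature_reads_give_fraction_one(self, annotation):
        reads = generate_reads(annotation, mature_fraction=1.0, n_reads=300, seed=2)
        prof = maturity_trend(reads, annotation)
        assert prof.mature_fraction == 1.0

    def test_single_midpoint_read_lands_in_central_bin(self, precursor):
        reads = [read(1049, 1071)]  # midpoint 1060, relative 0.5
        prof = maturity_trend(reads, [precursor], n_bins=100)
        assert prof.aggregate[50] == 1
        assert prof.aggregate.sum() == 1

    def test_mature_fraction_invariant_to_strand_flip(self, precursor):
        reads = generate_reads([precursor], mature_fraction=0.7, n_reads=500, seed=3)
        flipped_prec = Precursor(
            precursor_id="mir-x", chrom="chr1", start=1000, end=1120, strand="-",
            mature5p=(1081, 1105), mature3p=(1015, 1039),
        )
        flipped_reads = [
            ReadAlignment(chrom=r.chrom, start=r.start, end=r.end, strand="-")
            for r in reads
        ]
        a = maturity_trend(reads, [precursor])
        b = maturity_trend(flipped_reads, [flipped_prec])
        assert a.mature_fraction == b.mature_fraction

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            maturity_trend([], [])

    def test_relative_windows_are_strand_aware(self, annotation):
        for prec in annotation:
            win = relative_mature_windows(prec)
            assert win["5p"][1] <= 0.5 <= win["3p"][0]


class TestPrecursorValidation:
    def test_mature_outside_precursor_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Precursor("m", "c", 100, 200, "+", mature5p=(90, 120))

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Precursor("m", "c", 100, 200, "+", mature5p=(110, 140), mature3p=(130, 160))
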