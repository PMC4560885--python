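"""Ground-truth fidelity and determinism of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seromir.groupstats import adaptive_test_matrix
from seromir.quantify import relative_mature_windows, rpm_normalize
from seromir.simulate import (
    CohortConfig,
    generate_annotation,
    generate_brain_image,
    generate_cohort,
    generate_reads,
    study_config,
)


class TestCohortConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_control": 0},
            {"n_case": -1},
            {"n_differential": 10, "n_features": 5},
            {"fold_changes": -2.0, "n_differential": 1},
            {"array_attenuation": 1.5},
            {"dispersion": 0.0},
            {"planted_correlations": [(0, 0, 1.0)]},
            {"planted_correlations": [(999, 0, 0.5)]},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs).validate()


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(n_features=50, seed=123)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.seq_counts, b.seq_counts)
        pd.testing.assert_frame_equal(a.array_intensity, b.array_intensity)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_counts_nonnegative_integers_and_truth_complete(self):
        c = generate_cohort(CohortConfig(n_features=80, n_differential=6, seed=1))
        assert (c.seq_counts.to_numpy() >= 0).all()
        assert np.issubdtype(c.seq_counts.to_numpy().dtype, np.integer)
        assert len(c.truth.differential) == 6
        assert set(c.truth.differential) <= set(c.seq_counts.index)

    def test_null_config_has_empty_truth(self):
        c = generate_cohort(CohortConfig(n_differential=0, n_features=40, seed=2))
        assert c.truth.differential == {}

    def test_array_effects_are_attenuated_seq_effects(self):
        """The array log2 effect on a planted feature is the sequencing
        log2 fold scaled by the attenuation factor (averaged over seeds)."""
        lfcs = []
        for seed in range(8):
            cfg = CohortConfig(
                n_features=60, n_differential=4, fold_changes=4.0,
                array_attenuation=0.25, seed=seed,
            )
            c = generate_cohort(cfg)
            ctrl = c.subjects.index[c.subjects.group == "control"]
            aud = c.subjects.index[c.subjects.group == "AUD"]
            for fid in c.truth.differential:
                arr = np.log2(c.array_intensity.loc[fid])
                lfcs.append(arr[aud].mean() - arr[ctrl].mean())
        assert np.mean(lfcs) == pytest.approx(0.25 * 2.0, abs=0.1)

    def test_planted_fold_change_recovered_in_percent_change(self):
        """Fold 2.5 corresponds to +150% in normalized expression; recovery
        bias stays under 10% of the effect across 20 replicates."""
        errs = []
        for seed in range(20):
            cfg = CohortConfig(n_features=200, n_differential=10, fold_changes=2.5,
                               seed=300 + seed)
            c = generate_cohort(cfg)
            diff = adaptive_test_matrix(
                rpm_normalize(c.seq_counts).values, c.subjects.group
            ).set_index("feature")
            errs.extend(diff.loc[f, "percent_change"] - 150.0 for f in c.truth.differential)
        assert abs(np.mean(errs)) < 15.0

    def test_planted_correlation_holds_in_expectation(self):
        rs = []
        for seed in range(10):
            cfg = CohortConfig(
                n_features=100, n_differential=0,
                planted_correlations=[(5, 0, 0.9)], seed=seed,
            )
            c = generate_cohort(cfg)
            rpm = rpm_normalize(c.seq_counts).values
            fid, vid, _ = c.truth.correlations[0]
            aud = c.subjects.index[c.subjects.group == "AUD"]
            rs.append(np.corrcoef(rpm.loc[fid, aud], c.subjects.loc[aud, vid])[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.1)

    def test_null_cohort_overall_type_one_error_is_calibrated(self):
        """Pooled over branches, the adaptive test rejects ~5% of null
        features at p < 0.05 (99% binomial bounds, 1000 features)."""
        rejections = total = 0
        for seed in range(5):
            c = generate_cohort(
                CohortConfig(n_features=200, n_differential=0, seed=4000 + seed)
            )
            diff = adaptive_test_matrix(rpm_normalize(c.seq_counts).values, c.subjects.group)
            rejections += int((diff["test_p"] < 0.05).sum())
            total += len(diff)
        half = 2.5758 * np.sqrt(0.05 * 0.95 / total)
        assert abs(rejections / total - 0.05) <= half

    def test_drinking_variables_case_only(self):
        c = generate_cohort(CohortConfig(n_features=30, seed=3))
        drink = [v for v, cl in c.variable_classes.items() if cl == "drinking"]
        assert drink
        ctrl = c.subjects[c.subjects.group == "control"]
        aud = c.subjects[c.subjects.group == "AUD"]
        assert ctrl[drink].isna().all().all()
        assert aud[drink].notna().all().all()

    def test_study_config_mirrors_reference_design(self):
        cfg = study_config(seed=9)
        assert (cfg.n_control, cfg.n_case) == (10, 20)
        assert cfg.n_features == 500 and cfg.n_differential == 16
        folds = cfg.fold_vector()
        assert ((folds >= 2) | (folds <= 0.5)).all()


class TestGenerateReads:
    def test_full_maturity_puts_every_read_in_a_mature_window(self, annotation):
        reads = generate_reads(annotation, mature_fraction=1.0, n_reads=500, seed=4)
        by_id = {p.precursor_id: p for p in annotation}
        # match each read to its precursor by coordinates
        for r in reads:
            prec = next(
                p for p in annotation if p.start <= r.start and r.end <= p.end
            )
            inside = any(
                iv[0] <= r.start and r.end <= iv[1]
                for iv in (prec.mature5p, prec.mature3p)
                if iv is not None
            )
            assert inside

    def test_zero_maturity_read_starts_are_uniform(self, precursor):
        reads = generate_reads([precursor], mature_fraction=0.0, n_reads=10_000, seed=5)
        starts = np.array([r.start for r in reads])
        lo, hi = precursor.start, precursor.end - 22
        edges = np.linspace(lo, hi + 1, 11)
        observed, _ = np.histogram(starts, bins=edges)
        assert stats.chisquare(observed).pvalue > 0.01

    def test_zero_reads_gives_empty_set(self, annotation):
        assert generate_reads(annotation, 0.5, 0, seed=6) == []

    def test_same_seed_identical(self, annotation):
        a = generate_reads(annotation, 0.7, 200, seed=7)
        b = generate_reads(annotation, 0.7, 200, seed=7)
        assert a == b

    def test_invalid_fraction_rejected(self, annotation):
        with pytest.raises(ValueError):
            generate_reads(annotation, 1.2, 10, seed=0)

    def test_generated_annotation_windows_are_mirrored(self):
        ann = generate_annotation(10, seed=8)
        for p in ann:
            win = relative_mature_windows(p)
            lo5, hi5 = win["5p"]
            lo3, hi3 = win["3p"]
            assert lo5 == pytest.approx(1 - hi3)
            assert hi5 == pytest.approx(1 - lo3)


class TestGenerateBrainImage:
    def test_noiseless_fraction_is_pixel_exact(self):
        img, truth = generate_brain_image(64, 64, 0.10, noise_sd=0.0, seed=9)
        sulci = (img.pixels == 50) & img.brain_mask
        assert sulci.sum() / img.brain_mask.sum() == pytest.approx(truth.sulcal_fraction)
        assert truth.sulcal_fraction == pytest.approx(0.10, abs=0.005)

    def test_same_seed_identical_images(self):
        a, _ = generate_brain_image(48, 48, 0.2, noise_sd=5.0, seed=10)
        b, _ = generate_brain_image(48, 48, 0.2, noise_sd=5.0, seed=10)
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            generate_brain_image(64, 64, frac)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            generate_brain_image(16, 64, 0.1)
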