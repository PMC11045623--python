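"""Calibration fitting, trimming, blank masking, references, recovery."""

import numpy as np
import pytest

from atscreen.params import WorkflowParams
from atscreen.quantify import (Exclusion, blank_mask, error_quantification,
                               fit_calibration, matrix_correction,
                               quantify_sample, recovery, validate_references)

LEVELS = np.array([0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 1000.0])


class TestErrorQuantification:
    def test_perfect_line_is_zero(self):
        assert error_quantification(2.0, 0.0, LEVELS, 2.0 * LEVELS) == 0.0

    def test_symmetric_deviation(self):
        # predictions 9 and 11 against actual 10: median of {10, 10} = 10
        assert error_quantification(1.0, 0.0, [10.0, 10.0], [9.0, 11.0]) \
            == pytest.approx(10.0)

    def test_median_of_three(self):
        # predictions {9, 21, 40} for {10, 20, 40}: median of {10, 5, 0} = 5
        assert error_quantification(1.0, 0.0, [10.0, 20.0, 40.0],
                                    [9.0, 21.0, 40.0]) == pytest.approx(5.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            error_quantification(0.0, 0.0, [1.0], [1.0])


class TestFitCalibration:
    def test_exact_line_perfect_fit(self):
        fit = fit_calibration(LEVELS[:6], 2.0 * LEVELS[:6])
        assert fit is not None
        assert fit.slope == pytest.approx(2.0)
        assert fit.error_quant == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_inversion_round_trip_all_variants(self):
        from atscreen.quantify import _VARIANTS, _fit_variant
        conc = LEVELS[:6]
        rr = 3.0 * conc + 0.0
        for origin, weighting in _VARIANTS.values():
            s, i, _, _ = _fit_variant(conc, rr, origin, weighting)
            back = (rr - i) / s
            assert np.allclose(back, conc)

    def test_noisy_slope_recovered_within_5pct(self):
        # 8 levels, 5% multiplicative noise: median slope over seeds within
        # 5% of truth, every accepted fit meeting the error and R2 gates
        slopes = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            rr = 2.0 * LEVELS * np.exp(rng.normal(0, 0.05, len(LEVELS)))
            fit = fit_calibration(LEVELS, rr)
            assert fit is not None
            assert fit.error_quant < 30.0
            assert fit.r2 >= 0.95
            slopes.append(fit.slope)
        assert np.median(slopes) == pytest.approx(2.0, rel=0.05)

    def test_gross_outlier_removed_by_cooks_trimming(self):
        rr = 2.0 * LEVELS
        rr[-1] *= 10.0
        fit = fit_calibration(LEVELS, rr)
        assert fit is not None
        assert any(lvl == 1000.0 for lvl, _ in fit.removed_levels)
        assert len(fit.included_levels) >= 4
        assert fit.slope == pytest.approx(2.0, rel=0.05)

    def test_too_few_levels_gives_none(self):
        assert fit_calibration([1.0, 10.0, 100.0], [2.0, 20.0, 200.0]) is None

    def test_trimming_respects_min_points(self):
        rng = np.random.default_rng(5)
        rr = 2.0 * LEVELS * np.exp(rng.normal(0, 0.3, len(LEVELS)))
        fit = fit_calibration(LEVELS, rr, WorkflowParams(max_error_quant=5.0,
                                                         min_r2=0.0))
        if fit is not None:
            assert len(fit.included_levels) >= 4

    def test_cutoffs_from_retained_extremes(self):
        fit = fit_calibration(LEVELS[:6], 2.0 * LEVELS[:6])
        assert fit.x_cutoff == pytest.approx(2.0 * 0.1)
        assert fit.y_cutoff == pytest.approx(0.1)

    def test_slope_bias_small_over_seeded_replicates(self):
        # parameter recovery: mean slope bias < 2% at 5% noise, 8 levels
        slopes, errors = [], []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            rr = 2.0 * LEVELS * np.exp(rng.normal(0, 0.05, len(LEVELS)))
            fit = fit_calibration(LEVELS, rr)
            if fit is not None:
                slopes.append(fit.slope)
                errors.append(fit.error_quant)
        assert len(slopes) >= 90
        assert abs(np.mean(slopes) / 2.0 - 1.0) < 0.02
        assert np.median(errors) < 10.0


class TestBlankMask:
    def test_clean_blanks_no_masking(self):
        adj, masked, mean = blank_mask([400.0, 150.0], [0.0, 0.0, 0.0])
        assert not masked.any()
        assert mean == 0.0
        assert np.allclose(adj, [400.0, 150.0])

    def test_contaminated_blanks_subtract_and_keep_strong(self):
        adj, masked, mean = blank_mask([400.0], [100.0, 120.0, 0.0])
        assert mean == pytest.approx(73.333, rel=1e-3)
        assert not masked[0]
        assert adj[0] == pytest.approx(326.667, rel=1e-3)

    def test_weak_sample_masked(self):
        _, masked, _ = blank_mask([150.0], [100.0, 120.0, 0.0])
        assert masked[0]           # 150 <= 3 x 73.3

    def test_exactly_one_third_does_not_trigger(self):
        adj, masked, mean = blank_mask([400.0], [100.0, 0.0, 0.0])
        assert mean == 0.0 and not masked.any()

    def test_mask_decision_deterministic(self):
        out1 = blank_mask([400.0, 150.0], [100.0, 120.0, 0.0])
        out2 = blank_mask([400.0, 150.0], [100.0, 120.0, 0.0])
        assert np.array_equal(out1[1], out2[1])
        assert np.allclose(out1[0], out2[0])


class TestMatrixCorrection:
    def test_identical_groups_factor_one(self):
        assert matrix_correction([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) \
            == pytest.approx(1.0)

    def test_suppression_to_half_gives_two(self):
        assert matrix_correction([0.5, 0.5], [1.0, 1.0]) == pytest.approx(2.0)

    def test_planted_suppression_recovered(self):
        rng = np.random.default_rng(3)
        solvent = np.exp(rng.normal(0, 0.05, 4))
        matrix = 0.7 * np.exp(rng.normal(0, 0.05, 4))
        f = matrix_correction(matrix, solvent)
        assert f == pytest.approx(1 / 0.7, rel=0.10)

    def test_missing_group_factor_one(self):
        assert matrix_correction([], [1.0]) == 1.0


class TestValidateReferences:
    def test_tight_set_all_valid(self):
        assert validate_references([100.0, 102.0, 98.0]).all()

    def test_outlier_removed(self):
        mask = validate_references([100.0, 102.0, 98.0, 250.0])
        assert list(mask) == [True, True, True, False]

    def test_identical_values_all_valid(self):
        assert validate_references([5.0, 5.0, 5.0, 5.0]).all()

    def test_fewer_than_three_kept_with_warning(self):
        assert validate_references([1.0, 100.0]).all()


class TestRecovery:
    def test_at_reference_median_is_100(self):
        assert recovery(1.0, [1.0, 1.1, 0.9]) == pytest.approx(100.0)

    def test_half_is_50(self):
        assert recovery(0.5, [1.0, 1.0]) == pytest.approx(50.0)

    def test_example_80pct(self):
        assert recovery(0.8, [1.0, 1.1, 0.9]) == pytest.approx(80.0)

    def test_zero_median_undefined(self):
        assert recovery(1.0, [0.0, 0.0]) is None


class TestQuantifySample:
    def _fit(self):
        return fit_calibration(LEVELS[:6], 2.0 * LEVELS[:6])

    def test_ratio_at_level_returns_level_conc(self):
        qr = quantify_sample("a", "s", 2.0 * 5.0, self._fit())
        assert qr.concentration == pytest.approx(5.0)
        assert qr.exclusion is Exclusion.NONE

    def test_below_cutoff_excluded(self):
        qr = quantify_sample("a", "s", 0.01, self._fit())
        assert qr.concentration is None
        assert qr.exclusion is Exclusion.BELOW_CALIBRATION

    def test_above_range_excluded(self):
        qr = quantify_sample("a", "s", 1e6, self._fit())
        assert qr.exclusion is Exclusion.ABOVE_CALIBRATION

    def test_check_excluded_unless_allowed(self):
        qr = quantify_sample("a", "s", 10.0, self._fit(), check=True)
        assert qr.exclusion is Exclusion.CHECK_STATUS
        qr2 = quantify_sample("a", "s", 10.0, self._fit(), check=True,
                              allow_check=True)
        assert qr2.concentration is not None

    def test_masked_wins(self):
        qr = quantify_sample("a", "s", 10.0, self._fit(), masked=True)
        assert qr.exclusion is Exclusion.MASKED_BY_BACKGROUND
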