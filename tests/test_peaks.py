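"""Peak walker, merged-peak splitting, consensus and selection."""

import math

import numpy as np
import pytest

from atscreen.baseline import estimate_baseline
from atscreen.params import WorkflowParams
from atscreen.peaks import (build_consensus, find_peaks, select_peak,
                            split_merged, Peak)
from atscreen.sax import encode_sax

from conftest import gaussian_trace, make_eic


def detect(t, y, **kw):
    eic = make_eic(t, y)
    stats = estimate_baseline(make_eic(t, y, background=True))
    return eic, stats, find_peaks(eic, stats, WorkflowParams(), **kw)


class TestFindPeaks:
    def test_single_gaussian_apex_matches_argmax(self, time_axis):
        rng = np.random.default_rng(0)
        y = np.maximum(gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 10.0)
                       + rng.normal(0, 2, len(time_axis)), 0)
        eic, stats, peaks = detect(time_axis, y)
        assert len(peaks) == 1
        assert peaks[0].apex_idx == int(np.argmax(y))
        assert peaks[0].height == y.max()

    def test_small_shoulder_bump_stays_in_one_peak(self, time_axis):
        y = gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 10.0)
        y[207:209] *= 1.2          # +20% for 2 points on the falling flank
        _, _, peaks = detect(time_axis, y)
        assert len(peaks) == 1
        assert peaks[0].start_idx < 207 < peaks[0].end_idx

    def test_well_separated_gaussians_give_two_disjoint_peaks(self, time_axis):
        y = gaussian_trace(time_axis, 1.5, 1000.0, 0.05, 10.0) \
            + gaussian_trace(time_axis, 2.5, 800.0, 0.05)
        _, _, peaks = detect(time_axis, y)
        assert len(peaks) == 2
        assert peaks[0].end_idx < peaks[1].start_idx

    def test_area_close_to_closed_form(self, time_axis):
        y = gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 0.0) + 1e-9
        _, _, peaks = detect(time_axis, y)
        assert peaks[0].area == pytest.approx(
            1000.0 * 0.05 * math.sqrt(2 * math.pi), rel=0.05)

    def test_empty_window_gives_no_peaks(self, time_axis):
        y = gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 10.0)
        eic = make_eic(time_axis, y)
        stats = estimate_baseline(make_eic(time_axis, y, background=True))
        assert find_peaks(eic, stats, WorkflowParams(), window=(3.9, 3.95)) == []


class TestSplitMerged:
    def _pair(self, time_axis, h2=1000.0, sep_sigma=3.0):
        return gaussian_trace(time_axis, 2.0, 1000.0, 0.05) \
            + gaussian_trace(time_axis, 2.0 + sep_sigma * 0.05, h2, 0.05) + 10.0

    def test_merged_pair_split_at_brute_force_valley(self, time_axis):
        y = self._pair(time_axis)
        eic, stats, peaks = detect(time_axis, y)
        assert len(peaks) == 2
        out = split_merged(peaks, eic)
        a, b = out
        valley = a.apex_idx + int(np.argmin(y[a.apex_idx:b.apex_idx + 1]))
        assert abs(a.end_idx - valley) <= 1
        assert abs(b.start_idx - valley) <= 1
        assert a.split_enforced and b.split_enforced

    def test_disjoint_peaks_unchanged(self, time_axis):
        y = gaussian_trace(time_axis, 1.5, 1000.0, 0.05, 10.0) \
            + gaussian_trace(time_axis, 2.5, 800.0, 0.05)
        eic, stats, peaks = detect(time_axis, y)
        out = split_merged(peaks, eic)
        assert [(p.start_idx, p.end_idx) for p in out] \
            == [(p.start_idx, p.end_idx) for p in peaks]
        assert not any(p.split_enforced for p in out)

    def test_galaxolide_style_pair_assigned_correctly(self, time_axis):
        # same m/z, small RT gap, 10:1 height ratio: both peaks must be
        # found with the right apexes and split cleanly
        y = gaussian_trace(time_axis, 2.0, 1000.0, 0.05) \
            + gaussian_trace(time_axis, 2.25, 100.0, 0.05) + 10.0
        eic, stats, peaks = detect(time_axis, y)
        out = split_merged(peaks, eic)
        assert len(out) == 2
        assert out[0].apex_rt == pytest.approx(2.0, abs=0.01)
        assert out[1].apex_rt == pytest.approx(2.25, abs=0.01)
        assert out[0].end_idx <= out[1].start_idx

    def test_partition_and_area_additivity(self, time_axis):
        y = self._pair(time_axis, h2=900.0)
        eic, stats, peaks = detect(time_axis, y)
        out = split_merged(peaks, eic)
        a, b = out
        # interiors do not overlap; children tile the parent region
        assert a.end_idx <= b.start_idx
        from atscreen.eic import integrate_area
        total = integrate_area(eic, a.start_idx, b.end_idx)
        assert a.area + b.area == pytest.approx(total, rel=1e-9)

    def test_below_cutoff_pairs_bypass_splitting(self, time_axis):
        y = self._pair(time_axis)
        eic, stats, peaks = detect(time_axis, y)
        out = split_merged(peaks, eic, cutoff_height=5000.0)
        assert not any(p.split_enforced for p in out)


class TestConsensus:
    def _peak(self, eic, start, apex, end):
        from atscreen.eic import integrate_area
        return Peak(start, apex, end, float(eic.rt[apex]),
                    float(eic.intensity[apex]), integrate_area(eic, start, end))

    def test_identical_references_reproduce_any_one(self, time_axis):
        y = gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 10.0)
        eics = {f"r{i}": make_eic(time_axis, y) for i in range(3)}
        pks = {sid: self._peak(e, 185, 200, 215) for sid, e in eics.items()}
        c = build_consensus("a", pks, eics)
        assert c.expected_rt == pytest.approx(2.0)
        assert c.left_width == pytest.approx(0.15)
        assert c.rt_range == (pytest.approx(1.85), pytest.approx(2.15))

    def test_median_apex(self, time_axis):
        eics, pks = {}, {}
        for i, idx in enumerate((100, 102, 104)):   # apexes 1.00, 1.02, 1.04 min
            y = gaussian_trace(time_axis, time_axis[idx], 100.0, 0.05, 1.0)
            e = make_eic(time_axis, y)
            eics[f"r{i}"] = e
            pks[f"r{i}"] = self._peak(e, idx - 10, idx, idx + 10)
        c = build_consensus("a", pks, eics)
        assert c.expected_rt == pytest.approx(time_axis[102])

    def test_median_width_and_widest_range(self, time_axis):
        y = gaussian_trace(time_axis, 2.0, 100.0, 0.05, 1.0)
        eics = {f"r{i}": make_eic(time_axis, y) for i in range(3)}
        spans = {"r0": (195, 200, 205), "r1": (194, 200, 206), "r2": (185, 200, 215)}
        pks = {sid: self._peak(eics[sid], *spans[sid]) for sid in eics}
        c = build_consensus("a", pks, eics)
        assert c.left_width == pytest.approx(0.06)
        assert c.rt_range == (pytest.approx(time_axis[185]),
                              pytest.approx(time_axis[215]))

    def test_no_references_returns_none(self):
        assert build_consensus("a", {}, {}) is None

    def test_shape_from_highest_reference(self, time_axis):
        y1 = gaussian_trace(time_axis, 2.0, 100.0, 0.05, 1.0)
        y2 = gaussian_trace(time_axis, 2.0, 1000.0, 0.05, 1.0)
        eics = {"lo": make_eic(time_axis, y1), "hi": make_eic(time_axis, y2)}
        pks = {sid: self._peak(e, 185, 200, 215) for sid, e in eics.items()}
        c = build_consensus("a", pks, eics,
                            shape_encoder=lambda seg: encode_sax(seg, 5))
        expected = encode_sax(y2[185:216], 5)
        assert c.shape.letters == expected.letters


class TestSelectPeak:
    def _mk(self, apex_rt, height):
        return Peak(0, 1, 2, apex_rt, height, 1.0)

    def test_single_qualifying_peak_returned(self):
        p = self._mk(2.0, 500.0)
        assert select_peak([p], 2.0, (1.5, 2.5), lod=100.0) is p

    def test_tie_goes_to_higher_peak(self):
        lo = self._mk(1.9, 100.0)
        hi = self._mk(2.1, 500.0)
        assert select_peak([lo, hi], 2.0, (1.5, 2.5)) is hi

    def test_all_below_cutoff_gives_none(self):
        p = self._mk(2.0, 50.0)
        assert select_peak([p], 2.0, (1.5, 2.5), cutoff_height=100.0) is None

    def test_nearest_wins_over_higher(self):
        near = self._mk(2.02, 100.0)
        far = self._mk(2.4, 900.0)
        assert select_peak([near, far], 2.0, (1.5, 2.5)) is near
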