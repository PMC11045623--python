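"""EIC extraction, integration, density and the smoothing contract."""

import math

import numpy as np
import pytest

from atscreen.eic import (ScanMap, SmoothedInputError, background_window,
                          data_density, extract_eic, integrate_area,
                          read_scan_map, smooth_for_shape)
from atscreen.synth import PeakSpec, make_chromatogram, write_mzml

from conftest import make_eic, gaussian_trace


@pytest.fixture
def written_file(tmp_path):
    t, cents = make_chromatogram([PeakSpec(243.1743, 5.0, 1000.0, sigma=0.05)],
                                 rt_range=(4.0, 6.0), spacing=0.02,
                                 baseline=0.0, noise_sd=0.0, seed=1)
    return write_mzml(tmp_path / "x.mzML", t, cents), t, cents


class TestReadScanMap:
    def test_scan_count_preserved(self, written_file):
        path, t, _ = written_file
        sm = read_scan_map(path)
        assert sm.n_scans == len(t)
        assert np.allclose(sm.scan_times, t)

    def test_round_trip_recovers_planted_triples(self, written_file):
        path, t, cents = written_file
        sm = read_scan_map(path)
        eic = extract_eic(sm, 243.1743, (4.0, 6.0))
        expected = np.array([i[1][0] if len(i[1]) else 0.0 for i in cents])
        assert np.allclose(eic.intensity, expected)

    def test_out_of_order_scans_rejected_or_sorted(self, tmp_path):
        t = [1.0, 3.0, 2.0]
        cents = [(np.array([100.0]), np.array([float(i + 1)])) for i in range(3)]
        path = write_mzml(tmp_path / "o.mzML", t, cents)
        with pytest.raises(ValueError):
            read_scan_map(path)
        sm = read_scan_map(path, sort_scans=True)
        assert list(sm.scan_times) == [1.0, 2.0, 3.0]
        eic = extract_eic(sm, 100.0, (1.0, 3.0))
        assert list(eic.intensity) == [1.0, 3.0, 2.0]

    def test_unreadable_file_is_fatal_with_name(self, tmp_path):
        bad = tmp_path / "trunc.mzML"
        bad.write_text("<mzML><run><spectrumList>")
        with pytest.raises(ValueError, match="trunc.mzML"):
            read_scan_map(bad)


class TestExtractEIC:
    def _scan_map(self, centroids):
        return ScanMap.from_scans("s", [1.0], [centroids])

    def test_exact_match_at_5ppm(self):
        sm = self._scan_map((np.array([243.1743]), np.array([1000.0])))
        eic = extract_eic(sm, 243.1743, (0.5, 1.5), tol=5.0)
        assert eic.intensity[0] == 1000.0

    def test_two_centroids_in_tolerance_are_summed(self):
        mz = 243.1743
        sm = self._scan_map((np.array([mz * (1 - 2e-6), mz * (1 + 2e-6)]),
                             np.array([600.0, 400.0])))
        eic = extract_eic(sm, mz, (0.5, 1.5), tol=5.0)
        assert eic.intensity[0] == pytest.approx(1000.0)

    def test_offset_beyond_tolerance_is_excluded(self):
        mz = 243.1743
        sm = self._scan_map((np.array([mz * (1 + 10e-6)]), np.array([1000.0])))
        eic = extract_eic(sm, mz, (0.5, 1.5), tol=5.0)
        assert eic.intensity[0] == 0.0

    def test_empty_window_gives_empty_eic(self):
        sm = self._scan_map((np.array([100.0]), np.array([1.0])))
        eic = extract_eic(sm, 100.0, (5.0, 6.0))
        assert eic.is_empty

    def test_scan_order_invariance(self):
        t = [1.0, 2.0, 3.0]
        cents = [(np.array([100.0]), np.array([v])) for v in (5.0, 7.0, 3.0)]
        a = ScanMap.from_scans("s", t, cents)
        b = ScanMap.from_scans("s", t[::-1], cents[::-1], sort_scans=True)
        ea = extract_eic(a, 100.0, (0.0, 4.0))
        eb = extract_eic(b, 100.0, (0.0, 4.0))
        assert np.array_equal(ea.intensity, eb.intensity)


class TestBackgroundWindow:
    def test_extension_by_factor(self):
        assert background_window((10.0, 11.0), 1.5) == (9.75, 11.25)

    def test_factor_one_is_identity(self):
        assert background_window((10.0, 11.0), 1.0) == (10.0, 11.0)

    def test_clipping_at_run_start(self):
        assert background_window((0.1, 1.1), 1.5, scan_range=(0.0, 20.0)) \
            == (0.0, 1.35)

    def test_nesting_with_growing_factor(self):
        small = background_window((5.0, 6.0), 1.2)
        big = background_window((5.0, 6.0), 2.0)
        assert big[0] <= small[0] and big[1] >= small[1]


class TestIntegrateArea:
    def test_triangle(self):
        eic = make_eic([0.0, 1.0, 2.0], [0.0, 10.0, 0.0])
        assert integrate_area(eic, 0, 2) == pytest.approx(10.0)

    def test_rectangle(self):
        eic = make_eic([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert integrate_area(eic, 0, 2) == pytest.approx(10.0)

    def test_gaussian_close_to_closed_form(self):
        t = np.arange(0.0, 2.0, 0.01)
        eic = make_eic(t, gaussian_trace(t, 1.0, 1000.0, 0.05))
        area = integrate_area(eic, 0, len(t) - 1)
        assert area == pytest.approx(1000.0 * 0.05 * math.sqrt(2 * math.pi),
                                     rel=0.02)

    def test_piecewise_linear_is_exact(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 5, 30))
        t += np.arange(30) * 1e-6
        y = rng.uniform(0, 100, 30)
        eic = make_eic(t, y)
        manual = sum((y[i] + y[i + 1]) / 2 * (t[i + 1] - t[i]) for i in range(29))
        assert integrate_area(eic, 0, 29) == pytest.approx(manual, rel=1e-12)

    def test_smoothed_input_rejected(self):
        t = np.arange(0.0, 1.0, 0.01)
        sm = smooth_for_shape(make_eic(t, gaussian_trace(t, 0.5, 100.0, 0.05)))
        with pytest.raises(SmoothedInputError):
            integrate_area(sm, 0, 10)


class TestSmoothForShape:
    def test_flat_trace_unchanged_values(self):
        t = np.arange(0.0, 1.0, 0.01)
        out = smooth_for_shape(make_eic(t, np.full(len(t), 42.0)))
        assert out.is_smoothed
        assert np.allclose(out.intensity, 42.0)

    def test_spike_attenuated_and_densified(self):
        eic = make_eic([0.0, 0.1, 0.2, 0.3, 0.4], [0, 0, 100, 0, 0])
        out = smooth_for_shape(eic)
        assert len(out) >= len(eic)
        assert out.intensity.max() < 100

    def test_short_trace_returned_with_warning(self):
        eic = make_eic([0.0, 0.1], [1.0, 2.0])
        with pytest.warns(UserWarning):
            out = smooth_for_shape(eic)
        assert out is eic


class TestDataDensity:
    def test_uniform_spacings(self):
        t1 = np.arange(0.0, 2.0, 0.01)
        assert data_density(make_eic(t1, np.ones(len(t1)))) == pytest.approx(10, abs=1)
        t2 = np.arange(0.0, 2.0, 0.05)
        assert data_density(make_eic(t2, np.ones(len(t2)))) == pytest.approx(2, abs=1)

    def test_matches_brute_force_on_mixed_spacing(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 3, 120))
        eic = make_eic(t, np.ones(120))
        brute = np.median([np.sum((t >= ti) & (t < ti + 0.1)) for ti in t])
        assert data_density(eic) == pytest.approx(brute)
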