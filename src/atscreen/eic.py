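"""Extracted ion chromatograms (EICs) from centroided MS1 data.

The data layer of the workflow: read a centroided mzML file into a
:class:`ScanMap`, pull out one intensity trace per target *m/z*
(:func:`extract_eic`), widen windows for background estimation
(:func:`background_window`), and integrate areas by the trapezoidal rule.
Smoothing exists only to help the shape-dependent stages; quantitative
operations always consume the raw trace and refuse smoothed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mzml_io import iter_spectra


class SmoothedInputError(ValueError):
    """Raised when a quantitative operation receives a smoothed trace."""


@dataclass
class ScanMap:
    """All MS1 centroids of one sample, indexed for fast EIC extraction.

    ``scan_times`` are minutes, strictly increasing. Centroids are stored
    flattened and sorted by m/z so that extraction is a pair of binary
    searches followed by a scatter-add into scans.
    """

    sample_id: str
    scan_times: np.ndarray            # (n_scans,) minutes, strictly increasing
    mz: np.ndarray                    # (n_centroids,) sorted ascending
    intensity: np.ndarray             # (n_centroids,)
    scan_index: np.ndarray            # (n_centroids,) scan of each centroid
    ms_level: int = 1

    def __post_init__(self) -> None:
        if len(self.scan_times) == 0:
            raise ValueError(f"{self.sample_id}: no scans")
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError(f"{self.sample_id}: scan times not strictly increasing")
        if len(self.intensity) and self.intensity.min() < 0:
            raise ValueError(f"{self.sample_id}: negative centroid intensity")

    @property
    def n_scans(self) -> int:
        return len(self.scan_times)

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.scan_times[0]), float(self.scan_times[-1])

    @property
    def scan_spacing(self) -> float:
        """Median time between consecutive scans (minutes)."""
        if self.n_scans < 2:
            return 0.0
        return float(np.median(np.diff(self.scan_times)))

    @classmethod
    def from_scans(cls, sample_id: str, scan_times, centroids,
                   ms_level: int = 1, sort_scans: bool = False) -> "ScanMap":
        """Build from per-scan (m/z, intensity) centroid arrays.

        ``centroids`` is a sequence of (mz_array, intensity_array) pairs, one
        per scan. With ``sort_scans`` scans arriving out of time order are
        re-ordered; otherwise they raise.
        """
        times = np.asarray(scan_times, dtype=float)
        if sort_scans and len(times) and np.any(np.diff(times) <= 0):
            order = np.argsort(times, kind="stable")
            times = times[order]
            centroids = [centroids[i] for i in order]
        mzs, ints, idx = [], [], []
        for i, (m, y) in enumerate(centroids):
            m = np.asarray(m, dtype=float)
            y = np.asarray(y, dtype=float)
            mzs.append(m)
            ints.append(y)
            idx.append(np.full(len(m), i, dtype=np.int64))
        mz = np.concatenate(mzs) if mzs else np.empty(0)
        inten = np.concatenate(ints) if ints else np.empty(0)
        scan_idx = np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)
        order = np.argsort(mz, kind="stable")
        return cls(sample_id=sample_id, scan_times=times, mz=mz[order],
                   intensity=inten[order], scan_index=scan_idx[order],
                   ms_level=ms_level)


@dataclass
class EIC:
    """One analyte ion trace in one sample.

    ``rt``/``intensity`` are parallel arrays inside ``window`` (minutes,
    inclusive bounds). Background EICs carry ``is_background``; smoothed
    copies carry ``is_smoothed`` and must never feed height/area math.
    """

    analyte_id: str
    sample_id: str
    mz_target: float
    tol: float
    tol_is_da: bool
    rt: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float]
    is_background: bool = False
    is_smoothed: bool = False

    def __post_init__(self) -> None:
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt and intensity length mismatch")
        if len(self.rt) > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("EIC retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rt)

    @property
    def is_empty(self) -> bool:
        return len(self.rt) == 0

    @property
    def scan_spacing(self) -> float:
        if len(self.rt) < 2:
            return 0.0
        return float(np.median(np.diff(self.rt)))


def read_scan_map(path: str | Path, ms_level: int = 1,
                  sort_scans: bool = False) -> ScanMap:
    """Read a centroided mzML file into a :class:`ScanMap`.

    Only spectra at ``ms_level`` are kept; a file without any is rejected, as
    are profile-mode spectra (the workflow operates on centroids).
    """
    path = Path(path)
    times, centroids = [], []
    for spec in iter_spectra(path):
        if spec.ms_level != ms_level:
            continue
        if spec.is_profile:
            raise ValueError(f"{path.name}: profile-mode spectrum found; "
                             "centroid the data first")
        times.append(spec.scan_time)
        centroids.append((spec.mz, spec.intensity))
    if not times:
        raise ValueError(f"{path.name}: no MS{ms_level} scans")
    return ScanMap.from_scans(path.stem, times, centroids,
                              ms_level=ms_level, sort_scans=sort_scans)


def mz_halfwidth(mz: float, tol: float, tol_is_da: bool) -> float:
    """Absolute m/z half-window for a tolerance given in ppm or Da."""
    return tol if tol_is_da else mz * tol * 1e-6


def extract_eic(scan_map: ScanMap, mz: float, window: tuple[float, float],
                tol: float = 5.0, tol_is_da: bool = False,
                analyte_id: str = "", is_background: bool = False) -> EIC:
    """Extract the intensity trace of ``mz`` ± tolerance inside an RT window.

    Every scan inside the window contributes one point: the sum of matching
    centroid intensities, or an explicit zero when none match, so point counts
    reflect the acquisition rate. An empty window overlap yields an empty EIC.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = window
    in_win = np.nonzero((scan_map.scan_times >= lo) & (scan_map.scan_times <= hi))[0]
    if len(in_win) == 0:
        return EIC(analyte_id, scan_map.sample_id, mz, tol, tol_is_da,
                   np.empty(0), np.empty(0), (lo, hi), is_background=is_background)
    half = mz_halfwidth(mz, tol, tol_is_da)
    a = np.searchsorted(scan_map.mz, mz - half, side="left")
    b = np.searchsorted(scan_map.mz, mz + half, side="right")
    per_scan = np.bincount(scan_map.scan_index[a:b],
                           weights=scan_map.intensity[a:b],
                           minlength=scan_map.n_scans)
    return EIC(analyte_id, scan_map.sample_id, mz, tol, tol_is_da,
               scan_map.scan_times[in_win].astype(float), per_scan[in_win],
               (lo, hi), is_background=is_background)


def background_window(window: tuple[float, float], factor: float,
                      scan_range: tuple[float, float] | None = None
                      ) -> tuple[float, float]:
    """Widen an RT window symmetrically to ``factor`` times its width.

    The result is centred on the input window and clipped to the acquisition
    range when given; width is preserved as far as the clipping allows.
    """
    if factor < 1.0:
        raise ValueError("background extension factor must be >= 1")
    lo, hi = window
    extra = (hi - lo) * (factor - 1.0) / 2.0
    out_lo, out_hi = lo - extra, hi + extra
    if scan_range is not None:
        out_lo = max(out_lo, scan_range[0])
        out_hi = min(out_hi, scan_range[1])
    return out_lo, out_hi


def smooth_for_shape(eic: EIC) -> EIC:
    """Densified, smoothed copy of an EIC for shape analysis only.

    Linear interpolation onto a grid of half the native spacing followed by a
    5-point centred moving average. The raw EIC is untouched; the output is
    tagged so quantitative operations can refuse it.
    """
    if len(eic) < 3:
        warnings.warn(f"EIC {eic.analyte_id}/{eic.sample_id}: fewer than 3 points, "
                      "not smoothed")
        return eic
    step = eic.scan_spacing / 2.0
    grid = np.arange(eic.rt[0], eic.rt[-1] + step / 2, step)
    dense = np.interp(grid, eic.rt, eic.intensity)
    kernel = np.ones(5) / 5.0
    pad = np.pad(dense, 2, mode="edge")
    smoothed = np.convolve(pad, kernel, mode="valid")
    return replace(eic, rt=grid, intensity=smoothed, is_smoothed=True)


def integrate_area(eic: EIC, start_idx: int, end_idx: int) -> float:
    """Trapezoidal peak area (intensity x minutes) over inclusive index bounds."""
    if eic.is_smoothed:
        raise SmoothedInputError("integrate_area requires the raw EIC; "
                                 "smoothed traces are shape-only")
    if not 0 <= start_idx < end_idx < len(eic):
        raise IndexError(f"invalid integration bounds [{start_idx}, {end_idx}] "
                         f"for EIC of {len(eic)} points")
    sl = slice(start_idx, end_idx + 1)
    return float(np.trapezoid(eic.intensity[sl], eic.rt[sl]))


def data_density(eic: EIC, window_min: float = 0.1) -> float:
    """Data density: points per ``window_min`` minutes (default 0.1 min).

    For every point, count raw points inside the half-open interval
    [t, t + window_min); the density is the median of these counts.
    """
    if len(eic) < 2:
        raise ValueError("data density needs at least 2 points")
    rt = eic.rt
    counts = np.searchsorted(rt, rt + window_min, side="left") - np.arange(len(rt))
    return float(np.median(counts))
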