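"""Local-maxima peak detection with plateau and bump rules.

The walker seeds at the highest intensity in the search window and follows
decreasing intensities outward on both sides. A run of non-decreasing values
is tolerated for up to ``density_factor`` times the data density; the run is
cancelled (the peak continues) when the intensity drops more than
``intensity_factor_decrease`` relative to the last value assigned to the
peak. If the tolerance runs out, a plateau is assumed and the bound is placed
at its start. A sustained rise beyond ``intensity_factor_increase`` lasting
more than ``increase_density_fraction`` of the data density terminates the
walk (a new peak is starting). Merged peaks are split at the valley between
touching walks, and consensus peaks aggregate reference detections for
screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .baseline import BaselineStats
from .eic import EIC, data_density, integrate_area
from .params import WorkflowParams
from .sax import SAXSeq


@dataclass
class Peak:
    """A detected chromatographic peak on a raw EIC."""

    start_idx: int
    apex_idx: int
    end_idx: int
    apex_rt: float
    height: float          # raw apex intensity
    area: float            # intensity * minutes, trapezoidal
    plateau_truncated: bool = False
    split_enforced: bool = False
    zigzag_region: bool = False
    below_cutoff: bool = False

    def __post_init__(self) -> None:
        if not self.start_idx <= self.apex_idx <= self.end_idx:
            raise ValueError("peak indices out of order")

    @property
    def n_points(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class ConsensusPeak:
    """Unified peak characteristics aggregated over reference samples.

    Expected RT and widths are medians over the references; ``rt_range``
    spans the outermost bounds seen in any reference; the shape comes from
    the highest-intensity reference so the SAX letters are least affected by
    noise. ``height_by_level`` feeds the intensity-dependent shift analysis.
    """

    analyte_id: str
    expected_rt: float
    left_width: float
    right_width: float
    rt_range: tuple[float, float]
    shape: SAXSeq | None = None
    height_by_level: dict[float, float] = field(default_factory=dict)
    apex_by_level: dict[float, float] = field(default_factory=dict)
    max_height: float = 0.0
    scan_spacing: float = 0.0

    @property
    def width(self) -> float:
        return self.left_width + self.right_width


def _walk(y: np.ndarray, apex: int, step: int, lo: int, hi: int,
          max_flat: int, max_inc: int, f_dec: float, f_inc: float
          ) -> tuple[int, bool]:
    """Walk one flank of a peak; returns (bound index, plateau_truncated).

    Decreasing intensities are assigned to the peak. A non-decreasing value
    starts a tolerated run of at most ``max_flat`` points; a drop below
    (1 - f_dec) times the last assigned value cancels the run (the peak
    continues through it), exhausting it places the bound at the run start.
    Once a value exceeds (1 + f_inc) times the last assigned value while the
    signal has been rising for more than ``max_inc`` points, a new peak is
    assumed and the walk stops at the last assigned bound.
    """
    last = y[apex]
    bound = apex
    i = apex
    in_plateau = False
    flat = 0
    rise_run = 0
    prev = last
    while lo <= i + step <= hi:
        i += step
        v = y[i]
        if not in_plateau:
            if v < last:
                bound, last = i, v
            else:
                in_plateau = True
                flat, rise_run = 1, 1
                if flat > max_flat:
                    return bound, True
        else:
            flat += 1
            rise_run = rise_run + 1 if v >= prev else 0
            if v > (1 + f_inc) * last and rise_run > max_inc:
                return bound, False          # sustained rise: next peak starts
            if v < (1 - f_dec) * last:
                # real decrease resumed: the run belongs to the peak
                bound, last = i, v
                in_plateau = False
                flat = rise_run = 0
            elif flat > max_flat:
                return bound, True           # steady plateau: truncate
        prev = v
    return bound, in_plateau


def find_peaks(eic: EIC, stats: BaselineStats, params: WorkflowParams | None = None,
               window: tuple[float, float] | None = None,
               min_seed_intensity: float | None = None) -> list[Peak]:
    """Detect peaks by seeded walks from local maxima, highest first.

    Local maxima above ``min_seed_intensity`` (default: the in-sample LOD)
    are visited in descending intensity order; a maximum already absorbed by
    an earlier walk (a shoulder bump) does not seed again. Walks from
    distinct summits may meet or overlap — :func:`split_merged` resolves the
    contact at the valley. Returns peaks sorted by apex retention time.
    """
    from scipy.signal import find_peaks as _local_maxima

    params = params or WorkflowParams()
    if eic.is_empty or len(eic) < 3:
        return []
    y = eic.intensity
    if window is None:
        lo_i, hi_i = 0, len(y) - 1
    else:
        lo_i = int(np.searchsorted(eic.rt, window[0], side="left"))
        hi_i = int(np.searchsorted(eic.rt, window[1], side="right")) - 1
        if hi_i - lo_i < 2:
            return []
    density = data_density(eic)
    max_flat = math.ceil(params.density_factor * density)
    max_inc = math.ceil(params.increase_density_fraction * density)
    floor = stats.lod if min_seed_intensity is None else min_seed_intensity

    seg = y[lo_i:hi_i + 1]
    seeds, _ = _local_maxima(seg, plateau_size=(None, None))
    seeds = seeds + lo_i
    seeds = seeds[y[seeds] > max(floor, 0.0)]
    seeds = seeds[np.argsort(y[seeds], kind="stable")[::-1]]

    # apex localisation is a shape decision: the raw argmax wanders under
    # noise, so the summit is taken from a 5-point moving average refined by
    # a local quadratic vertex; height is still read from the raw trace
    y_smooth = np.convolve(np.pad(y, 2, mode="edge"), np.ones(5) / 5.0,
                           mode="valid")

    def _refine_apex(left: int, right: int) -> int:
        i0 = left + int(np.argmax(y_smooth[left:right + 1]))
        a, b = max(left, i0 - 4), min(right, i0 + 4) + 1
        if b - a < 5:
            return i0
        coef = np.polyfit(np.arange(a, b), y[a:b], 2)
        if coef[0] >= 0:
            return i0
        vertex = -coef[1] / (2.0 * coef[0])
        return int(round(np.clip(vertex, left, right)))

    assigned = np.zeros(len(y), dtype=bool)
    peaks: list[Peak] = []
    for seed in seeds:
        if assigned[seed]:
            continue
        left, lt = _walk(y, seed, -1, lo_i, hi_i, max_flat, max_inc,
                         params.intensity_factor_decrease,
                         params.intensity_factor_increase)
        right, rt_trunc = _walk(y, seed, +1, lo_i, hi_i, max_flat, max_inc,
                                params.intensity_factor_decrease,
                                params.intensity_factor_increase)
        apex = _refine_apex(left, right) if right > left else int(seed)
        area = integrate_area(eic, left, right) if right > left else 0.0
        peaks.append(Peak(int(left), int(apex), int(right), float(eic.rt[apex]),
                          float(y[apex]), area, plateau_truncated=lt or rt_trunc))
        assigned[left:right + 1] = True
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def split_merged(peaks: list[Peak], eic: EIC,
                 cutoff_height: float = 0.0) -> list[Peak]:
    """Enforce split points where the walks of two peaks touch or overlap.

    For each adjacent pair whose bounds meet, the minimum intensity in the
    contact region becomes the shared boundary; both peaks are flagged and
    their areas re-integrated. Peaks below ``cutoff_height`` bypass splitting:
    below that intensity fluctuating patterns are fully allowed.
    """
    if len(peaks) < 2:
        return list(peaks)
    y = eic.intensity
    out = [Peak(**vars(p)) for p in sorted(peaks, key=lambda p: p.apex_rt)]
    for a, b in zip(out, out[1:]):
        if a.end_idx < b.start_idx - 1:
            continue
        if a.height < cutoff_height and b.height < cutoff_height:
            continue
        lo = min(max(a.apex_idx + 1, b.start_idx), b.apex_idx)
        hi = max(min(b.apex_idx - 1, a.end_idx), a.apex_idx)
        lo, hi = min(lo, hi), max(lo, hi)
        valley = lo + int(np.argmin(y[lo:hi + 1]))
        a.end_idx = valley
        b.start_idx = valley
        a.apex_idx = min(a.apex_idx, valley)
        b.apex_idx = max(b.apex_idx, valley)
        a.split_enforced = b.split_enforced = True
    for p in out:
        if p.split_enforced:
            p.area = integrate_area(eic, p.start_idx, p.end_idx) \
                if p.end_idx > p.start_idx else 0.0
            p.apex_rt = float(eic.rt[p.apex_idx])
            p.height = float(y[p.apex_idx])
    return out


def build_consensus(analyte_id: str,
                    ref_peaks: dict[str, Peak],
                    ref_eics: dict[str, EIC],
                    levels: dict[str, float] | None = None,
                    shape_encoder=None) -> ConsensusPeak | None:
    """Aggregate reference detections into one consensus peak.

    Medians unify apex RT and flank widths; the RT range spans all reference
    bounds; the SAX shape is encoded from the highest reference peak when an
    encoder is supplied. Returns None when no reference detected the analyte
    (the analyte is then unscreenable).
    """
    if not ref_peaks:
        return None
    apexes, lws, rws, los, his = [], [], [], [], []
    best_sample, best_h = None, -np.inf
    for sid, pk in ref_peaks.items():
        rt = ref_eics[sid].rt
        apexes.append(pk.apex_rt)
        lws.append(pk.apex_rt - rt[pk.start_idx])
        rws.append(rt[pk.end_idx] - pk.apex_rt)
        los.append(rt[pk.start_idx])
        his.append(rt[pk.end_idx])
        if pk.height > best_h:
            best_h, best_sample = pk.height, sid
    shape = None
    if shape_encoder is not None:
        pk = ref_peaks[best_sample]
        seg = ref_eics[best_sample].intensity[pk.start_idx:pk.end_idx + 1]
        if len(seg) >= 2:
            shape = shape_encoder(seg)
    spacing = ref_eics[best_sample].scan_spacing
    height_by_level, apex_by_level = {}, {}
    for sid, pk in ref_peaks.items():
        if levels and sid in levels:
            height_by_level[levels[sid]] = pk.height
            apex_by_level[levels[sid]] = pk.apex_rt
    return ConsensusPeak(analyte_id,
                         expected_rt=float(np.median(apexes)),
                         left_width=float(np.median(lws)),
                         right_width=float(np.median(rws)),
                         rt_range=(float(min(los)), float(max(his))),
                         shape=shape,
                         height_by_level=height_by_level,
                         apex_by_level=apex_by_level,
                         max_height=float(best_h),
                         scan_spacing=spacing)


def select_peak(peaks: list[Peak], expected_rt: float,
                window: tuple[float, float], cutoff_height: float = 0.0,
                lod: float = 0.0) -> Peak | None:
    """Pick the qualifying peak nearest the expected retention time.

    Qualifying means: apex inside the window and height at least
    max(cutoff_height, in-sample LOD). Ties in apex distance go to the higher
    peak.
    """
    floor = max(cutoff_height, lod)
    cands = [p for p in peaks
             if window[0] <= p.apex_rt <= window[1] and p.height >= floor]
    if not cands:
        return None
    return min(cands, key=lambda p: (abs(p.apex_rt - expected_rt), -p.height))
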