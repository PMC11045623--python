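"""Three-level retention-time shift correction.

Internal standards (IS) measured across the batch give a global shift (their
mean displacement from the target list) and a search half-width (the largest
observed displacement, floored per instrument mode). Calibration series can
reveal intensity-dependent shifts — column overload makes high concentrations
elute earlier — validated by regression and an unspecific-peak veto against an
IS-only control. Finally, each sample's own IS displacement predicts the
matrix-driven shift of the analytes assigned to that IS. The three levels
combine into one resolved search window per analyte and sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .params import WorkflowParams
from .peaks import ConsensusPeak, Peak

log = logging.getLogger(__name__)


@dataclass
class IntensityTrend:
    """Validated intensity-dependent RT trend: apex_rt ~ slope*log10(height)."""

    slope: float         # minutes per decade of height (negative = overload)
    intercept: float
    p_value: float

    def predict(self, height: float) -> float:
        return self.intercept + self.slope * np.log10(max(height, 1.0))


@dataclass
class ShiftModel:
    """Resolved shift state for one batch."""

    global_mean_shift: float
    search_halfwidth: float
    mode: str = "LC"
    per_sample_is_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    intensity_trends: dict[str, IntensityTrend] = field(default_factory=dict)


def global_shift(is_shifts, mode: str = "LC",
                 params: WorkflowParams | None = None) -> tuple[float, float]:
    """Mean IS displacement and search half-width for the batch.

    ``is_shifts`` are apex-minus-expected displacements (minutes) pooled over
    all internal standards and IS-containing samples. The half-width is the
    largest absolute displacement, but never below the instrument-mode floor
    (0.5 min LC, 0.1 min GC). With no IS found anywhere the shift is zero and
    the floor alone defines the window.
    """
    params = params or WorkflowParams()
    floor = params.rt_window_floor(mode)
    shifts = np.asarray(list(is_shifts), dtype=float)
    if len(shifts) == 0:
        log.warning("no internal standard detected in any sample; "
                    "global shift 0, window floor %.2f min", floor)
        return 0.0, floor
    return float(shifts.mean()), float(max(np.abs(shifts).max(), floor))


def intensity_shift(consensus: ConsensusPeak,
                    control_has_peak: bool | None = None,
                    params: WorkflowParams | None = None) -> IntensityTrend | None:
    """Detect a column-overload RT trend from the calibration series.

    Regresses reference apex RT on log10(apex height) over the calibration
    levels. The trend is accepted only when the slope is negative (higher
    concentrations eluting earlier), the regression is significant, and the
    IS-only control shows no unspecific peak above LOD in the analyte window
    (``control_has_peak`` False). Without a control the veto is unavailable
    and a stricter significance level applies.
    """
    params = params or WorkflowParams()
    levels = sorted(consensus.apex_by_level)
    if len(levels) < 3:
        return None
    heights = np.array([consensus.height_by_level[c] for c in levels])
    apexes = np.array([consensus.apex_by_level[c] for c in levels])
    if np.any(heights <= 0) or np.ptp(apexes) == 0:
        return None
    res = _st.linregress(np.log10(heights), apexes)
    alpha = 0.05 if control_has_peak is not None else 0.01
    if control_has_peak:
        return None                     # unspecific interference: veto
    if res.slope >= 0 or res.pvalue >= alpha:
        return None
    return IntensityTrend(float(res.slope), float(res.intercept),
                          float(res.pvalue))


def sample_is_shift(is_peak: Peak | None, expected_is_rt: float
                    ) -> tuple[float, bool]:
    """Per-sample IS displacement; (0, fallback=True) when the IS is missing."""
    if is_peak is None:
        return 0.0, True
    return float(is_peak.apex_rt - expected_is_rt), False


def resolve_window(consensus: ConsensusPeak, model: ShiftModel,
                   sample_id: str, is_id: str | None,
                   measured_height: float | None = None
                   ) -> tuple[tuple[float, float], float]:
    """Resolve the search window and shifted expected RT for one analyte/sample.

    ``per_sample_is_shift`` holds each sample's IS displacement relative to
    the reference frame in which the consensus was measured, so the expected
    RT moves by that residual when the assigned IS was found in the sample
    and stays at the consensus RT otherwise (global fallback: the consensus
    already carries the batch-level shift). An intensity-trend prediction is
    added when one was validated and a height estimate is at hand. The window
    is the shifted RT plus/minus the batch half-width, trimmed to the
    reference-derived RT range extended by the same half-width.
    """
    shift = 0.0
    if is_id is not None and (sample_id, is_id) in model.per_sample_is_shift:
        shift = model.per_sample_is_shift[(sample_id, is_id)]
    expected = consensus.expected_rt + shift
    trend = model.intensity_trends.get(consensus.analyte_id)
    if trend is not None and measured_height is not None and measured_height > 0:
        expected += trend.predict(measured_height) - consensus.expected_rt
    hw = model.search_halfwidth
    lo = max(expected - hw, consensus.rt_range[0] - hw)
    hi = min(expected + hw, consensus.rt_range[1] + hw)
    if lo > hi:
        lo, hi = expected - hw, expected + hw
    return (lo, hi), expected
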