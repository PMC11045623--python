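"""Baseline, noise, and in-sample LOD/LOQ from the background EIC.

The baseline is normally the 25% intensity quantile of the extended
(background) trace. Three triggers guard against noisy chromatograms where a
low quantile would sit inside structured interference: (A) the zigzag
fraction must stay below its threshold, (B) the relative RMSE of the
baseline-defining intensities about the baseline must stay below its
threshold, and (C) the maximum intensity divided by the 25% quantile must
exceed the minimum background ratio. If any trigger fails, the 80% quantile
defines an elevated baseline instead. Noise is the standard deviation of the
baseline-defining intensities; baseline + 3*noise and baseline + 10*noise act
as in-sample LOD and LOQ — intensity acceptance thresholds, not final
concentration limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eic import EIC
from .params import WorkflowParams
from .sax import zigzag_fraction


@dataclass
class BaselineStats:
    baseline: float
    noise: float
    quantile_used: float
    lod: float
    loq: float
    zigzag_exceeded: bool
    rmse_exceeded: bool
    ratio_too_low: bool
    degenerate: bool = False

    @property
    def triggers(self) -> dict[str, bool]:
        return {"zigzag_exceeded": self.zigzag_exceeded,
                "rmse_exceeded": self.rmse_exceeded,
                "ratio_too_low": self.ratio_too_low}


def lod_loq(baseline: float, noise: float) -> tuple[float, float]:
    """In-sample LOD and LOQ: baseline + 3*noise and baseline + 10*noise."""
    return baseline + 3.0 * noise, baseline + 10.0 * noise


def estimate_baseline(bg: EIC, params: WorkflowParams | None = None) -> BaselineStats:
    """Run the quantile cascade on a background EIC.

    Quantiles use linear interpolation between order statistics; noise is the
    population standard deviation of the baseline-defining set. A provisional
    baseline/noise from the normal quantile feeds the zigzag trigger. A
    zero 25% quantile (blank region) fails the ratio trigger rather than
    dividing by zero.
    """
    params = params or WorkflowParams()
    y = np.asarray(bg.intensity, dtype=float)
    if len(y) == 0 or np.all(y == 0):
        return BaselineStats(0.0, 0.0, params.higher_background_quantile,
                             0.0, 0.0, False, False, True, degenerate=True)

    q_norm = float(np.quantile(y, params.normal_background_quantile))
    base_set = y[y <= q_norm]
    noise0 = float(base_set.std()) if len(base_set) else 0.0

    zz = zigzag_fraction(bg, q_norm, noise0, min_run=params.zigzag_min_run)
    zigzag_exceeded = zz >= params.zigzag_trigger_threshold

    if q_norm > 0 and len(base_set):
        rel_rmse = float(np.sqrt(np.mean((base_set - q_norm) ** 2))) / q_norm
        rmse_exceeded = rel_rmse >= params.background_rmse_threshold
        ratio_too_low = (y.max() / q_norm) <= params.minimum_background_ratio
    else:
        rmse_exceeded = False
        ratio_too_low = True   # undefined ratio: treat as failed

    if zigzag_exceeded or rmse_exceeded or ratio_too_low:
        q_used = params.higher_background_quantile
    else:
        q_used = params.normal_background_quantile

    baseline = float(np.quantile(y, q_used))
    defining = y[y <= baseline]
    noise = float(defining.std()) if len(defining) else 0.0
    lod, loq = lod_loq(baseline, noise)
    return BaselineStats(baseline, noise, q_used, lod, loq,
                         zigzag_exceeded, rmse_exceeded, ratio_too_low)
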