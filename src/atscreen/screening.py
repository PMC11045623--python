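"""Per analyte-and-sample screening decisions.

A candidate peak inside the resolved search window is accepted as DETECTED
when it clears four gates: residual shift within tolerance, shape similar to
the consensus (optional, via MINDIST on SAX sequences), enough data points,
and a confirming ion present whenever one can be expected above its own
in-sample LOD. A peak failing any gate keeps its integrated area but is
tagged CHECK — counted negative in fully unsupervised mode, available for
manual re-evaluation. No qualifying peak at all means NOT_DETECTED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .baseline import BaselineStats
from .eic import EIC
from .params import WorkflowParams
from .peaks import ConsensusPeak, Peak, select_peak
from .sax import encode_sax, mindist
from .shifts import ShiftModel


class Status(str, Enum):
    DETECTED = "DETECTED"
    CHECK = "CHECK"
    NOT_DETECTED = "NOT_DETECTED"
    MASKED_BY_BACKGROUND = "MASKED_BY_BACKGROUND"


@dataclass
class ConfirmingIon:
    """A secondary ion expected to co-elute at a stable intensity ratio."""

    mz: float
    expected_ratio: float       # confirming / quantifier intensity
    tolerance: float = 0.20

    def __post_init__(self) -> None:
        if self.expected_ratio <= 0:
            raise ValueError("confirming-ion ratio must be positive")


@dataclass
class ScreeningHit:
    analyte_id: str
    sample_id: str
    status: Status
    peak: Peak | None = None
    area: float = 0.0
    height: float = 0.0
    apex_rt: float = float("nan")
    applied_shift: float = 0.0
    check_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status is Status.CHECK and not self.check_reasons:
            raise ValueError("CHECK status requires at least one reason")

    @property
    def is_positive(self) -> bool:
        """Positive in fully unsupervised mode (CHECK counts negative)."""
        return self.status is Status.DETECTED


def confirmers_check(quant_peak: Peak, conf_eics: list[EIC],
                     ions: list[ConfirmingIon],
                     conf_stats: list[BaselineStats],
                     conf_peaks: list[list[Peak]]) -> str:
    """Screen confirming ions for one quantifier peak.

    Per ion, the expected confirming intensity is quantifier height times the
    expected ratio. Below that ion's in-sample LOD no detection can be
    expected and the ion imposes no penalty. Otherwise a confirming peak must
    co-elute (apex within the quantifier bounds) with a measured
    confirming/quantifier ratio within tolerance. Returns 'confirmed',
    'not_expected' (no ion was testable) or 'missing'.
    """
    if not ions:
        return "confirmed"
    any_expected = False
    for ion, eic, stats, peaks in zip(ions, conf_eics, conf_stats, conf_peaks):
        expected = quant_peak.height * ion.expected_ratio
        if expected <= stats.lod:
            continue
        any_expected = True
        lo_rt = eic.rt[quant_peak.start_idx] if quant_peak.start_idx < len(eic) \
            else -np.inf
        hi_rt = eic.rt[min(quant_peak.end_idx, len(eic) - 1)]
        ok = False
        for cp in peaks:
            if not lo_rt <= cp.apex_rt <= hi_rt:
                continue
            ratio = cp.height / quant_peak.height
            if abs(ratio - ion.expected_ratio) <= ion.tolerance * ion.expected_ratio:
                ok = True
                break
        if not ok:
            return "missing"
    return "confirmed" if any_expected else "not_expected"


def screen_sample(analyte_id: str, sample_id: str,
                  peaks: list[Peak], eic: EIC, stats: BaselineStats,
                  window: tuple[float, float], expected_rt: float,
                  consensus: ConsensusPeak,
                  params: WorkflowParams,
                  mode: str = "LC",
                  cutoff_height: float = 0.0,
                  confirm_outcome: str | None = None,
                  confirm_fn=None) -> ScreeningHit:
    """Decide DETECTED / CHECK / NOT_DETECTED for one analyte in one sample.

    ``confirm_outcome`` short-circuits the confirming-ion result when it was
    evaluated upstream; alternatively ``confirm_fn(peak)`` is called lazily
    with the selected peak. A valid peak sitting exactly at the unshifted
    consensus RT overrides the shift-corrected window (high-resolution data
    makes such a match distinctive), so IS-shift mistakes cannot displace an
    obvious hit.
    """
    # unshifted-exact-match override
    spacing = consensus.scan_spacing or eic.scan_spacing
    exact_tol = params.exact_rt_scan_tolerance * spacing
    override = None
    for p in peaks:
        if p.height >= max(stats.lod, cutoff_height) \
                and abs(p.apex_rt - consensus.expected_rt) <= exact_tol:
            override = p
            break
    if override is not None:
        peak = override
        expected_rt = consensus.expected_rt
    else:
        peak = select_peak(peaks, expected_rt, window,
                           cutoff_height=cutoff_height, lod=stats.lod)
    if peak is None:
        return ScreeningHit(analyte_id, sample_id, Status.NOT_DETECTED)

    reasons: list[str] = []
    shift_tol = max(consensus.width, params.rt_window_floor(mode))
    residual = abs(peak.apex_rt - expected_rt)
    if residual > shift_tol:
        reasons.append("shift_out_of_range")

    near_expected = residual <= consensus.width
    significant = peak.height >= stats.lod
    if params.use_MINDIST and consensus.shape is not None \
            and not (near_expected and significant):
        seg = eic.intensity[peak.start_idx:peak.end_idx + 1]
        if len(seg) >= 2:
            d = mindist(encode_sax(seg, params.sax_alphabet_size), consensus.shape)
            if d > params.mindist_ceiling:
                reasons.append("shape_mismatch")

    if peak.n_points <= params.min_peak_points:
        reasons.append("too_few_points")

    outcome = confirm_outcome
    if outcome is None and confirm_fn is not None:
        outcome = confirm_fn(peak)
    if outcome == "missing":
        reasons.append("confirming_missing")

    status = Status.CHECK if reasons else Status.DETECTED
    return ScreeningHit(analyte_id, sample_id, status, peak=peak,
                        area=peak.area, height=peak.height,
                        apex_rt=peak.apex_rt,
                        applied_shift=expected_rt - consensus.expected_rt,
                        check_reasons=tuple(reasons))
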