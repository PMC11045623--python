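"""Quantification: blank masking, matrix correction, reference validation,
auto-trimmed six-variant linear calibration, concentrations and recoveries.

Calibration fits simple linear regressions of response ratio against nominal
concentration in six variants — through the origin or free intercept, each
unweighted or weighted by x or 1/x — and trims high-leverage levels by Cook's
distance as long as doing so lowers the median quantification error and
raises the coefficient of determination, keeping at least a minimum number of
points. Among variants meeting the R-squared and error thresholds the winner
has the lowest error, then the widest retained concentration range, then the
highest R-squared. The retained extremes define the quantifiable range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import statsmodels.api as sm

from .params import WorkflowParams

log = logging.getLogger(__name__)

_VARIANTS = {
    1: (True, None), 2: (True, "x"), 3: (True, "1/x"),
    4: (False, None), 5: (False, "x"), 6: (False, "1/x"),
}


class Exclusion(str, Enum):
    NONE = "none"
    MASKED_BY_BACKGROUND = "masked_by_background"
    BELOW_CALIBRATION = "below_calibration"
    ABOVE_CALIBRATION = "above_calibration"
    INVALID_REFERENCE = "invalid_reference"
    CHECK_STATUS = "check_status"
    NOT_DETECTED = "not_detected"
    NO_CALIBRATION = "no_calibration"


@dataclass
class CalibrationFit:
    variant: int
    slope: float
    intercept: float
    r2: float
    error_quant: float                      # percent (median absolute deviation)
    included_levels: tuple[float, ...]      # concentrations retained
    removed_levels: tuple[tuple[float, str], ...]
    x_cutoff: float                         # lowest retained response ratio
    x_max: float                            # highest retained response ratio
    y_cutoff: float                         # lowest retained concentration

    @property
    def through_origin(self) -> bool:
        return _VARIANTS[self.variant][0]

    def predict_conc(self, response_ratio: float) -> float:
        return (response_ratio - self.intercept) / self.slope


@dataclass
class QuantResult:
    analyte_id: str
    sample_id: str
    concentration: float | None
    recovery: float | None = None
    exclusion: Exclusion = Exclusion.NONE


def error_quantification(slope: float, intercept: float,
                         conc, response_ratio) -> float:
    """Median absolute percent deviation of back-predicted concentrations.

    Each level's response ratio is inverted through the line; the error is
    median(|(C_actual - C_predicted) / C_actual| * 100).
    """
    if slope == 0:
        raise ValueError("zero slope: calibration not invertible")
    conc = np.asarray(conc, dtype=float)
    rr = np.asarray(response_ratio, dtype=float)
    pred = (rr - intercept) / slope
    return float(np.median(np.abs((conc - pred) / conc) * 100.0))


def _fit_variant(conc: np.ndarray, rr: np.ndarray, through_origin: bool,
                 weighting: str | None):
    X = conc[:, None] if through_origin else sm.add_constant(conc)
    if weighting == "x":
        w = conc
    elif weighting == "1/x":
        w = 1.0 / conc
    else:
        w = np.ones_like(conc)
    # whitened OLS is numerically identical to WLS and exposes the influence
    # machinery (hat matrix, Cook's distance) for both variants
    sw = np.sqrt(w)
    res = sm.OLS(rr * sw, X * sw[:, None]).fit()
    if through_origin:
        slope, intercept = float(res.params[0]), 0.0
    else:
        intercept, slope = float(res.params[0]), float(res.params[1])
    cooks = res.get_influence().cooks_distance[0]
    return slope, intercept, float(res.rsquared), np.asarray(cooks)


def fit_calibration(conc, response_ratio,
                    params: WorkflowParams | None = None) -> CalibrationFit | None:
    """Auto-trimmed best linear calibration over the six variants.

    Per variant the highest-Cook's-distance level is removed while the
    removal lowers the quantification error, raises R-squared, and leaves at
    least ``min_cal_points`` levels. Only variants with R-squared at least
    ``min_r2`` and error below ``max_error_quant`` qualify; the winner
    minimises error, then maximises retained concentration span, then
    R-squared. Returns None when nothing qualifies.
    """
    params = params or WorkflowParams()
    conc = np.asarray(conc, dtype=float)
    rr = np.asarray(response_ratio, dtype=float)
    ok = np.isfinite(rr) & (conc > 0)
    conc, rr = conc[ok], rr[ok]
    if len(conc) < params.min_cal_points:
        return None

    candidates: list[CalibrationFit] = []
    for variant, (origin, weighting) in _VARIANTS.items():
        keep = np.ones(len(conc), dtype=bool)
        removed: list[tuple[float, str]] = []
        try:
            slope, icpt, r2, cooks = _fit_variant(conc, rr, origin, weighting)
            if slope == 0:
                continue
            err = error_quantification(slope, icpt, conc, rr)
        except Exception:
            continue
        while keep.sum() > params.min_cal_points:
            idx = np.nonzero(keep)[0]
            worst = idx[int(np.argmax(cooks))]
            trial = keep.copy()
            trial[worst] = False
            try:
                s2, i2, r22, c2 = _fit_variant(conc[trial], rr[trial],
                                               origin, weighting)
                if s2 == 0:
                    break
                e2 = error_quantification(s2, i2, conc[trial], rr[trial])
            except Exception:
                break
            if e2 < err and r22 > r2:
                keep = trial
                removed.append((float(conc[worst]), "cooks_distance_trim"))
                slope, icpt, r2, cooks, err = s2, i2, r22, c2, e2
            else:
                break
        kept_conc = conc[keep]
        kept_rr = rr[keep]
        candidates.append(CalibrationFit(
            variant=variant, slope=slope, intercept=icpt, r2=r2,
            error_quant=err,
            included_levels=tuple(sorted(kept_conc)),
            removed_levels=tuple(removed),
            x_cutoff=float(kept_rr.min()), x_max=float(kept_rr.max()),
            y_cutoff=float(kept_conc.min())))

    qualifying = [c for c in candidates
                  if c.r2 >= params.min_r2
                  and c.error_quant < params.max_error_quant * 100.0]
    if not qualifying:
        return None
    return min(qualifying,
               key=lambda c: (c.error_quant,
                              -(max(c.included_levels) - min(c.included_levels)),
                              -c.r2))


def blank_mask(sample_responses, blank_responses,
               params: WorkflowParams | None = None):
    """Subtract a systematic blank background and mask weak responses.

    When responses appear in more than ``blank_fraction_threshold`` of the
    solvent blanks, their mean (over all blanks, absences counting as zero)
    is subtracted from every sample; samples whose raw response does not
    exceed ``blank_multiplier`` times that mean are tagged masked-by-
    background. Without detected blank responses everything passes through.
    Returns (adjusted responses, masked boolean array, blank mean).
    """
    params = params or WorkflowParams()
    resp = np.asarray(sample_responses, dtype=float)
    blanks = np.asarray(blank_responses, dtype=float)
    if len(blanks) == 0:
        log.warning("no solvent blanks in batch: blank masking skipped")
        return resp.copy(), np.zeros(len(resp), dtype=bool), 0.0
    frac = float(np.mean(blanks > 0))
    if frac <= params.blank_fraction_threshold:
        return resp.copy(), np.zeros(len(resp), dtype=bool), 0.0
    mean_blank = float(blanks.mean())
    adjusted = resp - mean_blank
    masked = resp <= params.blank_multiplier * mean_blank
    return adjusted, masked, mean_blank


def matrix_correction(matrix_rrs, solvent_rrs) -> float:
    """Multiplicative factor recovering solvent-equivalent response ratios.

    factor = median(solvent) / median(matrix); missing or degenerate groups
    give 1 (no correction).
    """
    m = np.asarray(matrix_rrs, dtype=float)
    s = np.asarray(solvent_rrs, dtype=float)
    if len(m) == 0 or len(s) == 0 or np.median(m) <= 0:
        log.warning("matrix correction unavailable: factor 1")
        return 1.0
    return float(np.median(s) / np.median(m))


def validate_references(ref_rrs, fence: float = 1.5) -> np.ndarray:
    """Boolean mask of references inside the Tukey fences.

    The accepted interval is [Q1 - fence*IQR, Q3 + fence*IQR]; with fewer
    than 3 references everything is kept.
    """
    rr = np.asarray(ref_rrs, dtype=float)
    if len(rr) < 3:
        log.warning("fewer than 3 reference controls: outlier check skipped")
        return np.ones(len(rr), dtype=bool)
    q1, q3 = np.quantile(rr, [0.25, 0.75])
    iqr = q3 - q1
    return (rr >= q1 - fence * iqr) & (rr <= q3 + fence * iqr)


def recovery(sample_rr: float, valid_ref_rrs) -> float | None:
    """Recovery in percent against the median valid reference response ratio."""
    ref = np.asarray(valid_ref_rrs, dtype=float)
    if len(ref) == 0:
        return None
    med = float(np.median(ref))
    if med == 0:
        log.warning("reference median response ratio is zero: recovery undefined")
        return None
    return 100.0 * sample_rr / med


def quantify_sample(analyte_id: str, sample_id: str, response_ratio: float,
                    fit: CalibrationFit | None,
                    status_positive: bool = True,
                    masked: bool = False,
                    check: bool = False,
                    allow_check: bool = False) -> QuantResult:
    """Concentration for one sample from its (adjusted, corrected) response ratio.

    Ratios outside the retained calibration range are excluded as below/above
    calibration; CHECK hits are excluded unless ``allow_check`` (supervised
    re-evaluation); masked-by-background and undetected samples carry their
    exclusion instead of a number.
    """
    if masked:
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.MASKED_BY_BACKGROUND)
    if check and not allow_check:
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.CHECK_STATUS)
    if not status_positive and not (check and allow_check):
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.NOT_DETECTED)
    if fit is None:
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.NO_CALIBRATION)
    if response_ratio < fit.x_cutoff:
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.BELOW_CALIBRATION)
    if response_ratio > fit.x_max:
        return QuantResult(analyte_id, sample_id, None,
                           exclusion=Exclusion.ABOVE_CALIBRATION)
    return QuantResult(analyte_id, sample_id,
                       float(fit.predict_conc(response_ratio)))
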