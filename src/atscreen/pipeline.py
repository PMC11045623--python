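"""Batch orchestration: the six-step screening pipeline.

Given a sample manifest (solvent blanks, reference standards, calibration
levels, matrix QC, IS-only control, samples), a target list and an
internal-standard list, the pipeline runs:

A. EIC generation per m/z with background-based baseline/noise estimation
   and peak detection;
B. global retention-time shift from all internal standards;
C. peak-list annotation on references/calibrations, consensus peaks, and
   intensity-dependent shift checks;
D. per-sample internal-standard shifts;
E. screening of every sample for every analyte with CHECK tagging;
F. quantification: blank masking, matrix correction, reference validation,
   auto-trimmed calibration, concentrations and recoveries.

Everything is deterministic: no stage draws random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import BaselineStats, estimate_baseline
from .eic import EIC, ScanMap, background_window, extract_eic, read_scan_map
from .params import WorkflowParams
from .peaks import ConsensusPeak, Peak, build_consensus, find_peaks, select_peak, \
    split_merged
from .quantify import CalibrationFit, Exclusion, QuantResult, blank_mask, \
    fit_calibration, matrix_correction, quantify_sample, recovery, \
    validate_references
from .sax import encode_sax
from .screening import ConfirmingIon, ScreeningHit, Status, confirmers_check, \
    screen_sample
from .shifts import ShiftModel, global_shift, intensity_shift, sample_is_shift
from .metrics import bland_altman, classification_metrics, confusion_from_hits, mape

log = logging.getLogger(__name__)

GROUPS = ("blank", "reference", "calibration", "matrix_qc", "is_only", "sample")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample manifest (path, sample_id, group, concentration)."""
    df = pd.read_csv(path)
    required = {"path", "sample_id", "group"}
    if missing := required - set(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "concentration" not in df.columns:
        df["concentration"] = np.nan
    for i, row in df.iterrows():
        if row["group"] not in GROUPS:
            raise ValueError(f"manifest row {i}: unknown group {row['group']!r}")
        if row["group"] == "calibration" and not np.isfinite(row["concentration"]):
            raise ValueError(f"manifest row {i}: calibration row without a "
                             "concentration")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest contains duplicate sample ids")
    return df


def read_targets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"analyte_id", "mz", "rt"}
    if missing := required - set(df.columns):
        raise ValueError(f"target list missing columns: {sorted(missing)}")
    if df["analyte_id"].duplicated().any():
        raise ValueError("target list contains duplicate analyte ids")
    for col, default in (("confirm_mz", np.nan), ("confirm_ratio", np.nan),
                         ("is_id", ""), ("mode", "LC"), ("name", "")):
        if col not in df.columns:
            df[col] = default
    df["is_id"] = df["is_id"].fillna("")
    return df


def read_is_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if missing := {"is_id", "mz", "rt"} - set(df.columns):
        raise ValueError(f"IS list missing columns: {sorted(missing)}")
    return df


@dataclass
class AnalyteContext:
    """Per-analyte annotation state shared across samples."""

    consensus: ConsensusPeak | None = None
    cutoff_height: float = 0.0
    matrix_factor: float = 1.0
    fit: CalibrationFit | None = None


@dataclass
class PipelineResult:
    hits: pd.DataFrame              # analyte x sample long table of statuses
    responses: pd.DataFrame         # responses, IS responses, ratios, masks
    concentrations: pd.DataFrame    # quantified values + exclusions + recovery
    consensus: pd.DataFrame         # per-analyte consensus characteristics
    qualitative: pd.DataFrame       # analyte x sample TRUE/FALSE/masked matrix
    shift_model: ShiftModel | None = None
    calibrations: dict[str, CalibrationFit] = field(default_factory=dict)
    screening_hits: list[ScreeningHit] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.hits.to_csv(out / "screening_hits.csv", index=False)
        self.responses.to_csv(out / "responses.csv", index=False)
        self.concentrations.to_csv(out / "concentrations.csv", index=False)
        self.consensus.to_csv(out / "consensus_peaks.csv", index=False)
        self.qualitative.to_csv(out / "qualitative_matrix.csv")


class _EICCache:
    """Background-EIC extraction with baseline stats, one pass per window."""

    def __init__(self, params: WorkflowParams):
        self.params = params

    def get(self, sm: ScanMap, mz: float, window: tuple[float, float],
            analyte_id: str) -> tuple[EIC, EIC, BaselineStats]:
        bg_win = background_window(window, self.params.background_extension_factor,
                                   scan_range=sm.rt_range)
        bg = extract_eic(sm, mz, bg_win, tol=self.params.mz_tol_default,
                         tol_is_da=self.params.mz_tol_is_da,
                         analyte_id=analyte_id, is_background=True)
        stats = estimate_baseline(bg, self.params)
        lo = int(np.searchsorted(bg.rt, window[0], side="left"))
        hi = int(np.searchsorted(bg.rt, window[1], side="right"))
        eic = EIC(analyte_id, bg.sample_id, mz, bg.tol, bg.tol_is_da,
                  bg.rt[lo:hi], bg.intensity[lo:hi], window)
        return eic, bg, stats


def _detect(eic: EIC, stats: BaselineStats, params: WorkflowParams,
            cutoff: float = 0.0) -> list[Peak]:
    peaks = find_peaks(eic, stats, params)
    return split_merged(peaks, eic, cutoff_height=cutoff)


def run_pipeline(manifest: pd.DataFrame, targets: pd.DataFrame,
                 is_table: pd.DataFrame, params: WorkflowParams | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full screening workflow on one batch.

    Requires at least one reference or calibration sample for annotation;
    without calibration rows the run is screening-only (no concentrations,
    with a warning).
    """
    params = params or WorkflowParams()
    cache = _EICCache(params)
    mode = str(targets["mode"].iloc[0]) if len(targets) else "LC"

    # ---- load scans --------------------------------------------------- (A)
    scan_maps: dict[str, ScanMap] = {}
    for _, row in manifest.iterrows():
        scan_maps[row["sample_id"]] = read_scan_map(row["path"])
    groups = dict(zip(manifest["sample_id"], manifest["group"]))
    conc_by_sample = dict(zip(manifest["sample_id"], manifest["concentration"]))
    annot_ids = [s for s, g in groups.items() if g in ("reference", "calibration")]
    if not annot_ids:
        raise ValueError("no reference or calibration samples: cannot annotate")

    # ---- Function B: global shift from internal standards --------------
    is_peaks: dict[tuple[str, str], Peak] = {}
    all_shifts = []
    for _, srow in is_table.iterrows():
        is_id, is_mz, is_rt = srow["is_id"], srow["mz"], srow["rt"]
        win = (is_rt - params.initial_search_halfwidth,
               is_rt + params.initial_search_halfwidth)
        for sid, g in groups.items():
            if g == "blank":
                continue
            eic, _, stats = cache.get(scan_maps[sid], is_mz, win, is_id)
            peaks = _detect(eic, stats, params)
            cands = [p for p in peaks if p.height >= stats.lod]
            if not cands:
                continue
            pk = max(cands, key=lambda p: p.height)   # IS: dominant peak
            is_peaks[(sid, is_id)] = pk
            all_shifts.append(pk.apex_rt - is_rt)
    mean_shift, halfwidth = global_shift(all_shifts, mode=mode, params=params)
    model = ShiftModel(global_mean_shift=mean_shift, search_halfwidth=halfwidth,
                       mode=mode)

    # ---- Function D: per-sample IS shifts (relative to reference frame) -
    for _, srow in is_table.iterrows():
        is_id = srow["is_id"]
        ref_apexes = [is_peaks[(sid, is_id)].apex_rt for sid in annot_ids
                      if (sid, is_id) in is_peaks]
        if not ref_apexes:
            continue
        frame = float(np.median(ref_apexes))
        for sid in groups:
            pk = is_peaks.get((sid, is_id))
            shift, fallback = sample_is_shift(pk, frame)
            if not fallback:
                model.per_sample_is_shift[(sid, is_id)] = shift

    # ---- Function C: annotation on references / calibrations ------------
    contexts: dict[str, AnalyteContext] = {}
    for _, trow in targets.iterrows():
        aid = trow["analyte_id"]
        ctx = AnalyteContext()
        contexts[aid] = ctx
        center = trow["rt"] + mean_shift
        win = (center - halfwidth, center + halfwidth)
        ref_pk: dict[str, Peak] = {}
        ref_eic: dict[str, EIC] = {}
        levels: dict[str, float] = {}
        for sid in annot_ids:
            eic, _, stats = cache.get(scan_maps[sid], trow["mz"], win, aid)
            peaks = _detect(eic, stats, params)
            c = center
            is_id = trow["is_id"] or None
            if is_id is not None and (sid, is_id) in is_peaks:
                # reference's own IS displacement refines the center
                c = trow["rt"] + (is_peaks[(sid, is_id)].apex_rt
                                  - float(is_table.set_index("is_id")
                                          .loc[is_id, "rt"]))
            pk = select_peak(peaks, c, win, lod=stats.lod)
            if pk is None:
                continue
            ref_pk[sid] = pk
            ref_eic[sid] = eic
            lvl = conc_by_sample.get(sid)
            if lvl is not None and np.isfinite(lvl):
                levels[sid] = float(lvl)
        encoder = lambda seg: encode_sax(seg, params.sax_alphabet_size)
        ctx.consensus = build_consensus(aid, ref_pk, ref_eic, levels,
                                        shape_encoder=encoder)
        if ctx.consensus is None:
            log.warning("analyte %s: no reference detection, unscreenable", aid)
            continue
        ctx.cutoff_height = params.minimum_cutoff_intensity_factor \
            * ctx.consensus.max_height
        # intensity-dependent shift, vetoed by the IS-only control
        control_has_peak = None
        ctrl = [s for s, g in groups.items() if g == "is_only"]
        if ctrl:
            eic, _, stats = cache.get(scan_maps[ctrl[0]], trow["mz"], win, aid)
            ctrl_peaks = _detect(eic, stats, params)
            control_has_peak = any(p.height >= stats.lod for p in ctrl_peaks)
        trend = intensity_shift(ctx.consensus, control_has_peak, params)
        if trend is not None:
            model.intensity_trends[aid] = trend

    # ---- Function E: screening ------------------------------------------
    hits: list[ScreeningHit] = []
    is_rt_by_id = dict(zip(is_table["is_id"], is_table["rt"]))
    for _, trow in targets.iterrows():
        aid = trow["analyte_id"]
        ctx = contexts[aid]
        is_id = trow["is_id"] or None
        has_confirm = np.isfinite(trow.get("confirm_mz", np.nan))
        for sid in groups:
            if ctx.consensus is None:
                hits.append(ScreeningHit(aid, sid, Status.NOT_DETECTED))
                continue
            from .shifts import resolve_window
            win, exp_rt = resolve_window(ctx.consensus, model, sid, is_id)
            eic, _, stats = cache.get(scan_maps[sid], trow["mz"], win, aid)
            peaks = _detect(eic, stats, params, cutoff=ctx.cutoff_height)

            confirm_fn = None
            if has_confirm:
                ion = ConfirmingIon(float(trow["confirm_mz"]),
                                    float(trow["confirm_ratio"]),
                                    params.confirming_ratio_tolerance)
                ceic, _, cstats = cache.get(scan_maps[sid], ion.mz, win,
                                            f"{aid}~confirm")
                cpeaks = _detect(ceic, cstats, params)

                def confirm_fn(pk, _e=ceic, _s=cstats, _p=cpeaks, _i=ion):
                    return confirmers_check(pk, [_e], [_i], [_s], [_p])

            hits.append(screen_sample(
                aid, sid, peaks, eic, stats, win, exp_rt, ctx.consensus,
                params, mode=mode, cutoff_height=ctx.cutoff_height,
                confirm_fn=confirm_fn))

    hit_by = {(h.analyte_id, h.sample_id): h for h in hits}

    # ---- Function F: quantification --------------------------------------
    blank_ids = [s for s, g in groups.items() if g == "blank"]
    sample_ids = list(groups)
    cal_ids = [s for s, g in groups.items() if g == "calibration"]
    ref_ids = [s for s, g in groups.items() if g == "reference"]
    mqc_ids = [s for s, g in groups.items() if g == "matrix_qc"]
    if not cal_ids:
        log.warning("no calibration samples: screening-only mode, "
                    "no concentrations will be reported")

    resp_rows, quant_rows = [], []
    qual = {}
    for _, trow in targets.iterrows():
        aid = trow["analyte_id"]
        ctx = contexts[aid]
        is_id = trow["is_id"] or None

        def response_of(sid: str) -> float:
            h = hit_by[(aid, sid)]
            if h.peak is None:
                return 0.0
            return h.area if params.response_type == "area" else h.height

        def is_response_of(sid: str) -> float | None:
            if is_id is None:
                return None
            pk = is_peaks.get((sid, is_id))
            if pk is None:
                return None
            return pk.area if params.response_type == "area" else pk.height

        raw = {sid: response_of(sid) for sid in sample_ids}
        blanks = [raw[s] for s in blank_ids]
        adjusted_arr, masked_arr, blank_mean = blank_mask(
            [raw[s] for s in sample_ids], blanks, params)
        adjusted = dict(zip(sample_ids, adjusted_arr))
        masked = dict(zip(sample_ids, masked_arr))

        def ratio_of(sid: str) -> float:
            r = max(adjusted[sid], 0.0)
            ir = is_response_of(sid)
            return r / ir if ir else r

        rr = {sid: ratio_of(sid) for sid in sample_ids}
        if mqc_ids and ref_ids:
            ctx.matrix_factor = matrix_correction(
                [rr[s] for s in mqc_ids], [rr[s] for s in ref_ids])
        corrected = {sid: rr[sid] * ctx.matrix_factor
                     if groups[sid] in ("sample",) else rr[sid]
                     for sid in sample_ids}

        ref_rrs = np.array([corrected[s] for s in ref_ids])
        valid_mask = validate_references(ref_rrs, params.iqr_fence_multiplier) \
            if len(ref_rrs) else np.empty(0, dtype=bool)
        valid_refs = ref_rrs[valid_mask] if len(ref_rrs) else ref_rrs

        fit = None
        if cal_ids:
            concs = [conc_by_sample[s] for s in cal_ids]
            pos = [hit_by[(aid, s)].status in (Status.DETECTED, Status.CHECK)
                   for s in cal_ids]
            pts = [(c, corrected[s]) for c, s, p in zip(concs, cal_ids, pos) if p]
            if len(pts) >= params.min_cal_points:
                fit = fit_calibration([c for c, _ in pts], [r for _, r in pts],
                                      params)
        ctx.fit = fit

        for sid in sample_ids:
            h = hit_by[(aid, sid)]
            resp_rows.append({
                "analyte_id": aid, "sample_id": sid, "group": groups[sid],
                "status": h.status.value, "response": raw[sid],
                "adjusted_response": adjusted[sid],
                "is_response": is_response_of(sid),
                "response_ratio": corrected[sid],
                "masked_by_background": bool(masked[sid]),
                "apex_rt": h.apex_rt})
            if groups[sid] == "sample":
                qr = quantify_sample(
                    aid, sid, corrected[sid], fit,
                    status_positive=h.status is Status.DETECTED,
                    masked=bool(masked[sid]),
                    check=h.status is Status.CHECK)
                rec = recovery(corrected[sid], valid_refs) \
                    if qr.concentration is not None else None
                quant_rows.append({
                    "analyte_id": aid, "sample_id": sid,
                    "concentration": qr.concentration,
                    "recovery": rec, "exclusion": qr.exclusion.value})
                if masked[sid]:
                    qual[(aid, sid)] = "masked"
                else:
                    qual[(aid, sid)] = "TRUE" if h.status is Status.DETECTED \
                        else "FALSE"

    hits_df = pd.DataFrame([{
        "analyte_id": h.analyte_id, "sample_id": h.sample_id,
        "status": h.status.value, "area": h.area, "height": h.height,
        "apex_rt": h.apex_rt, "applied_shift": h.applied_shift,
        "check_reasons": ";".join(h.check_reasons)} for h in hits])
    cons_rows = []
    for aid, ctx in contexts.items():
        c = ctx.consensus
        if c is None:
            continue
        cons_rows.append({"analyte_id": aid, "expected_rt": c.expected_rt,
                          "left_width": c.left_width, "right_width": c.right_width,
                          "rt_lo": c.rt_range[0], "rt_hi": c.rt_range[1],
                          "max_height": c.max_height,
                          "shape": c.shape.letters if c.shape else ""})
    analyte_ids = list(targets["analyte_id"])
    s_only = [s for s, g in groups.items() if g == "sample"]
    qual_df = pd.DataFrame(
        [[qual.get((a, s), "FALSE") for s in s_only] for a in analyte_ids],
        index=analyte_ids, columns=s_only)

    result = PipelineResult(
        hits=hits_df, responses=pd.DataFrame(resp_rows),
        concentrations=pd.DataFrame(quant_rows),
        consensus=pd.DataFrame(cons_rows), qualitative=qual_df,
        shift_model=model,
        calibrations={a: c.fit for a, c in contexts.items() if c.fit is not None},
        screening_hits=hits)
    if out_dir is not None:
        result.write(out_dir)
    return result
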