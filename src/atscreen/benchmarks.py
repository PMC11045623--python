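"""Seeded validation experiments over the screening engine.

Each routine builds synthetic inputs with known ground truth, runs the
relevant part of the workflow, and returns summary numbers. They back both
the acceptance test suite and the reproduction script, so the measured
quantities are computed in exactly one place.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from .baseline import estimate_baseline
from .eic import EIC
from .metrics import confusion_from_hits, classification_metrics, mape
from .params import WorkflowParams
from .peaks import find_peaks, select_peak, split_merged
from .pipeline import run_pipeline
from .quantify import fit_calibration
from .screening import Status
from .shifts import global_shift
from .synth import AnalyteSpec, BatchSpec, ISSpec, make_batch


def _eic(t, y, background=False):
    return EIC("bench", "s", 100.0, 5.0, False, t, y,
               (float(t[0]), float(t[-1])), is_background=background)


def peak_walker_suite(n_traces: int = 200, seed: int = 0,
                      spacing: float = 0.01) -> dict:
    """Apex and area recovery on isolated noisy Gaussian peaks.

    Each trace holds one Gaussian (height 500-5000 counts, sigma 0.03-0.08
    min) with additive Gaussian noise at a chromatographic signal-to-noise
    ratio of 10-40 (S/N = 2h / peak-to-peak noise with the usual 5-sigma
    peak-to-peak span, so S/N = 10 corresponds to a noise sd of h/25) and
    zero baseline. Reports the fraction of apexes recovered within one scan
    of truth and the median relative deviation of the detected area from
    the closed-form value h*sigma*sqrt(2*pi).
    """
    rng = np.random.default_rng(seed)
    params = WorkflowParams()
    apex_hits = 0
    area_errors = []
    for _ in range(n_traces):
        h = rng.uniform(500.0, 5000.0)
        sigma = rng.uniform(0.03, 0.08)
        snr = rng.uniform(10.0, 40.0)
        noise_sd = 2.0 * h / (5.0 * snr)      # S/N = 2h / (5 * sd)
        apex_rt = rng.uniform(1.2, 2.8)
        t = np.arange(0.0, 4.0, spacing)
        clean = h * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)
        y = np.maximum(clean + rng.normal(0.0, noise_sd, len(t)), 0.0)
        eic = _eic(t, y)
        stats = estimate_baseline(_eic(t, y, background=True))
        peaks = find_peaks(eic, stats, params)
        if not peaks:
            area_errors.append(1.0)
            continue
        pk = max(peaks, key=lambda p: p.height)
        if abs(pk.apex_rt - apex_rt) <= spacing + 1e-12:
            apex_hits += 1
        truth = h * sigma * math.sqrt(2.0 * math.pi)
        area_errors.append(abs(pk.area - truth) / truth)
    return {"apex_within_1_scan_fraction": apex_hits / n_traces,
            "median_area_rel_error_pct": float(np.median(area_errors)) * 100.0,
            "n": n_traces}


def split_suite(n_pairs: int = 50, seed: int = 0) -> dict:
    """Valley placement for merged Gaussian pairs.

    Pairs sit 3 sigma apart (the closest spacing at which a superposition of
    two Gaussians still has a valley; at exactly 2 sigma the sum is unimodal
    for every height ratio) with the second height 85-100% of the first, so
    the rise from the valley to the second apex exceeds the 40% new-peak
    trigger. Reports the largest offset (in scans) between the enforced
    split boundary and the brute-force minimum between the apexes.
    """
    rng = np.random.default_rng(seed)
    params = WorkflowParams()
    max_offset = 0
    n_split = 0
    for _ in range(n_pairs):
        sigma = rng.uniform(0.03, 0.06)
        h1 = rng.uniform(800.0, 2000.0)
        h2 = h1 * rng.uniform(0.85, 1.0)
        apex1 = rng.uniform(1.3, 2.3)
        t = np.arange(0.0, 4.0, 0.01)
        y = h1 * np.exp(-0.5 * ((t - apex1) / sigma) ** 2) \
            + h2 * np.exp(-0.5 * ((t - apex1 - 3 * sigma) / sigma) ** 2) + 10.0
        eic = _eic(t, y)
        stats = estimate_baseline(_eic(t, y, background=True))
        peaks = split_merged(find_peaks(eic, stats, params), eic)
        if len(peaks) != 2:
            continue
        a, b = peaks
        valley = a.apex_idx + int(np.argmin(y[a.apex_idx:b.apex_idx + 1]))
        offset = max(abs(a.end_idx - valley), abs(b.start_idx - valley))
        max_offset = max(max_offset, offset)
        n_split += 1
    return {"pairs_split": n_split, "n": n_pairs,
            "max_valley_offset_scans": max_offset}


def shift_recovery_suite(seed: int = 0, n_is: int = 10,
                         n_samples: int = 8) -> dict:
    """Global-shift recovery from detected internal standards.

    Plants a -1.0 min batch shift with 0.05 min jitter per IS-sample
    observation, detects every IS peak from its trace, and reports the
    absolute error of the recovered mean shift (minutes).
    """
    rng = np.random.default_rng(seed)
    params = WorkflowParams()
    shifts = []
    for i in range(n_is):
        rt0 = rng.uniform(2.5, 9.5)
        for _ in range(n_samples):
            true_shift = -1.0 + rng.normal(0.0, 0.05)
            t = np.arange(rt0 - 2.0, rt0 + 2.0, 0.01)
            y = 5000.0 * np.exp(-0.5 * ((t - rt0 - true_shift) / 0.04) ** 2) \
                + 20.0 + rng.normal(0.0, 5.0, len(t))
            y = np.maximum(y, 0.0)
            eic = _eic(t, y)
            stats = estimate_baseline(_eic(t, y, background=True))
            peaks = find_peaks(eic, stats, params)
            pk = select_peak(peaks, rt0 + (-1.0), (rt0 - 2.0, rt0 + 2.0),
                             lod=stats.lod)
            if pk is not None:
                shifts.append(pk.apex_rt - rt0)
    mean, hw = global_shift(shifts, mode="GC", params=params)
    return {"recovered_mean_shift": float(mean),
            "abs_error": abs(mean + 1.0),
            "halfwidth": float(hw),
            "n": len(shifts)}


def _batch_spec(n_analytes: int, n_samples: int, seed: int, **kw) -> BatchSpec:
    rts = np.linspace(1.8, 13.2, n_analytes)
    analytes = []
    rng = np.random.default_rng(seed + 7)
    for i in range(n_analytes):
        analytes.append(AnalyteSpec(
            f"A{i:02d}", mz=150.05 + 3.17 * i, rt=float(rts[i]),
            response_factor=float(rng.uniform(300.0, 2000.0)),
            sigma=float(rng.uniform(0.03, 0.06)),
            confirm_mz=150.05 + 3.17 * i + 1.0 if i % 2 == 0 else None,
            confirm_ratio=0.5,
            is_id="IS1" if i % 2 == 0 else "IS2"))
    defaults = dict(
        analytes=analytes,
        internal_standards=[ISSpec("IS1", 310.0711, 5.0),
                            ISSpec("IS2", 330.0815, 9.0)],
        n_samples=n_samples, seed=seed)
    defaults.update(kw)
    return BatchSpec(**defaults)


def shifted_list_agreement(seed: int = 0, n_analytes: int = 8,
                           n_samples: int = 3,
                           work_dir: str | Path | None = None) -> dict:
    """Hit-set agreement between exact and randomly shifted target lists.

    The same noiseless batch is screened twice: once with correct target
    retention times, once with every listed RT (analytes and IS) displaced
    by a per-compound draw from -1.1 to -0.9 min. Reports the fraction of
    analyte-sample screening statuses that agree.
    """
    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    common = dict(noise_sd=0.0, response_noise=0.0, per_sample_shift_sd=0.0,
                  sample_presence_prob=0.5, n_blanks=2, n_references=3)
    plain = make_batch(_batch_spec(n_analytes, n_samples, seed, **common),
                       base / "plain")
    shifted = make_batch(_batch_spec(n_analytes, n_samples, seed,
                                     compound_rt_shift_range=(-1.1, -0.9),
                                     **common),
                         base / "shifted")
    r1 = run_pipeline(plain.manifest, plain.targets, plain.is_table)
    r2 = run_pipeline(shifted.manifest, shifted.targets, shifted.is_table)
    s1 = {(h.analyte_id, h.sample_id): h.status for h in r1.screening_hits}
    s2 = {(h.analyte_id, h.sample_id): h.status for h in r2.screening_hits}
    keys = sorted(s1)
    agree = sum(s1[k] == s2[k] for k in keys)
    hits1 = {k for k, v in s1.items() if v is Status.DETECTED}
    hits2 = {k for k, v in s2.items() if v is Status.DETECTED}
    return {"status_agreement": agree / len(keys),
            "hit_sets_equal": hits1 == hits2,
            "n": len(keys)}


def calibration_suite(seed: int = 0, n_lines: int = 20) -> dict:
    """Slope recovery and outlier trimming on seeded calibration lines.

    Lines span 0.1-1000 ng/mL over 8 levels with 5% multiplicative response
    noise and true slope 2. Also plants one gross (10x) outlier at the top
    level of a clean line and checks that Cook's-distance trimming removes
    it while keeping at least 4 points.
    """
    levels = np.array([0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 1000.0])
    rng = np.random.default_rng(seed)
    slope_errors, errors, r2s = [], [], []
    accepted = 0
    for _ in range(n_lines):
        rr = 2.0 * levels * np.exp(rng.normal(0.0, 0.05, len(levels)))
        fit = fit_calibration(levels, rr)
        if fit is None:
            continue
        accepted += 1
        slope_errors.append(abs(fit.slope / 2.0 - 1.0))
        errors.append(fit.error_quant)
        r2s.append(fit.r2)
    rr_out = 2.0 * levels.copy()
    rr_out[-1] *= 10.0
    fit_out = fit_calibration(levels, rr_out)
    outlier_removed = fit_out is not None and \
        any(lvl == 1000.0 for lvl, _ in fit_out.removed_levels)
    return {"accepted_fraction": accepted / n_lines,
            "median_slope_error_pct": float(np.median(slope_errors)) * 100.0,
            "median_error_quant_pct": float(np.median(errors)),
            "min_r2": float(np.min(r2s)),
            "outlier_removed": bool(outlier_removed),
            "outlier_points_kept": len(fit_out.included_levels)
            if fit_out else 0,
            "n": n_lines}


def screening_e2e_suite(seed: int = 0, n_analytes: int = 40,
                        n_samples: int = 8,
                        work_dir: str | Path | None = None) -> dict:
    """Full-pipeline screening and quantification against planted truth.

    A seeded batch (40 analytes x 8 samples by default, plus blanks,
    references, an 8-level calibration and an IS-only control) with 5%
    multiplicative response noise is generated as mzML, screened, and
    quantified. CHECK counts negative. Reports sensitivity, specificity and
    the mean absolute percentage error of quantified against planted
    concentrations.
    """
    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    spec = _batch_spec(n_analytes, n_samples, seed,
                       response_noise=0.05, noise_sd=5.0,
                       sample_conc_range=(1.0, 200.0),
                       sample_presence_prob=0.5)
    batch = make_batch(spec, base)
    result = run_pipeline(batch.manifest, batch.targets, batch.is_table)
    sample_ids = [s for s, g in zip(batch.manifest["sample_id"],
                                    batch.manifest["group"]) if g == "sample"]
    truth = {(a, s): bool(batch.truth_presence.loc[a, s])
             for a in batch.truth_presence.index for s in sample_ids}
    hits = [h for h in result.screening_hits if h.sample_id in sample_ids]
    counts = confusion_from_hits(hits, truth)
    sens, spec_, acc = classification_metrics(counts)
    quant = result.concentrations.dropna(subset=["concentration"])
    planted = [batch.truth_conc.loc[r["analyte_id"], r["sample_id"]]
               for _, r in quant.iterrows()]
    mape_pct = mape(planted, quant["concentration"].to_numpy()) \
        if len(quant) else float("nan")
    return {"sensitivity": sens, "specificity": spec_, "accuracy": acc,
            "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
            "mape_pct": mape_pct, "n_quantified": len(quant),
            "n": len(hits)}
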