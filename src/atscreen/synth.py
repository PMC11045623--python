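"""Seeded synthetic chromatogram and batch generator.

Produces centroided mzML files with machine-readable ground truth so every
stage of the workflow can be exercised against known answers: Gaussian-ish
peaks with optional exponential tailing, additive baseline plus heteroscedastic
noise, zigzag (alternating-spike) interference, co-eluting isomers on a shared
m/z, per-compound and global retention-time shifts, and linear
response-concentration relations with optional saturation and blank
contamination.

The writer emits minimal but standard-conforming mzML (64-bit float arrays,
no compression) so the reader path of the workflow is exercised end to end.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erfc

# ---------------------------------------------------------------------------
# mzML writing


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{n}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(path: str | Path, scan_times, centroids, ms_level: int = 1) -> Path:
    """Write per-scan centroid lists as a centroided mzML file.

    ``centroids`` is one (mz_array, intensity_array) pair per scan. Zero-
    intensity centroids are dropped, as a real peak picker would.
    """
    path = Path(path)
    parts = [_MZML_HEADER.format(run_id=path.stem, n=len(scan_times))]
    for i, (rt, (mz, inten)) in enumerate(zip(scan_times, centroids)):
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        keep = inten > 0
        mz, inten = mz[keep], inten[keep]
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        mz_b64, int_b64 = _b64(mz), _b64(inten)
        parts.append(_SPECTRUM.format(index=i, scan=i + 1, npts=len(mz),
                                      ms_level=ms_level, rt=float(rt),
                                      mz_len=len(mz_b64), mz_b64=mz_b64,
                                      int_len=len(int_b64), int_b64=int_b64))
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
    return path


# ---------------------------------------------------------------------------
# chromatographic signal model


@dataclass
class PeakSpec:
    """One planted chromatographic peak on one m/z channel."""

    mz: float
    apex_rt: float            # minutes
    height: float             # counts at apex
    sigma: float = 0.04       # minutes
    tailing: float = 0.0      # exponential tail time constant (min); 0 = Gaussian

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.height <= 0:
            raise ValueError("peak sigma and height must be positive")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Peak shape evaluated at times ``t``, scaled so the maximum equals height."""
        if self.tailing <= 0:
            return self.height * np.exp(-0.5 * ((t - self.apex_rt) / self.sigma) ** 2)
        # exponentially modified Gaussian, renormalised to the requested height
        s, tau = self.sigma, self.tailing
        z = (t - self.apex_rt) / s - s / tau
        shape = np.exp(-(t - self.apex_rt) / tau + s ** 2 / (2 * tau ** 2)) \
            * erfc(-z / np.sqrt(2)) / 2
        m = shape.max()
        return self.height * shape / m if m > 0 else shape

    def area(self) -> float:
        """Closed-form area of the planted profile (exact for the Gaussian case)."""
        if self.tailing <= 0:
            return self.height * self.sigma * np.sqrt(2 * np.pi)
        t = np.arange(self.apex_rt - 8 * self.sigma,
                      self.apex_rt + 8 * self.sigma + 10 * self.tailing, self.sigma / 50)
        return float(np.trapezoid(self.profile(t), t))


def make_chromatogram(peaks: list[PeakSpec], rt_range=(0.0, 14.0),
                      spacing: float = 0.01, baseline: float = 20.0,
                      noise_sd: float = 0.0, noise_het: float = 0.0,
                      zigzag: list[tuple[float, float, float]] | None = None,
                      mz_jitter_ppm: float = 0.0, seed: int | None = None):
    """Simulate one sample's scans for the m/z channels named in ``peaks``.

    The signal per channel is the sum of the channel's peak profiles plus
    ``baseline`` plus Gaussian noise with sd ``noise_sd + noise_het * signal``
    (heteroscedastic term proportional to the clean signal). ``zigzag``
    entries (mz, rt_center, height) inject alternating high/near-baseline
    spikes over ~0.3 min around rt_center. Returns (scan_times, centroids)
    ready for :func:`write_mzml`.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(rt_range[0], rt_range[1] + spacing / 2, spacing)
    channels: dict[float, np.ndarray] = {}
    for p in peaks:
        channels.setdefault(p.mz, np.zeros_like(t))
        channels[p.mz] += p.profile(t)
    for mz, rt_c, h in (zigzag or []):
        channels.setdefault(mz, np.zeros_like(t))
        i0 = np.searchsorted(t, rt_c - 0.15)
        i1 = np.searchsorted(t, rt_c + 0.15)
        spike = np.zeros(i1 - i0)
        spike[::2] = h
        channels[mz][i0:i1] += spike
    for mz in channels:
        clean = channels[mz]
        sd = noise_sd + noise_het * clean
        channels[mz] = np.maximum(clean + baseline + rng.normal(0.0, 1.0, len(t)) * sd,
                                  0.0)
    mzs = np.array(sorted(channels))
    centroids = []
    for i in range(len(t)):
        obs_mz = mzs
        if mz_jitter_ppm > 0:
            obs_mz = mzs * (1 + rng.normal(0, mz_jitter_ppm * 1e-6, len(mzs)))
        centroids.append((obs_mz, np.array([channels[m][i] for m in mzs])))
    return t, centroids


# ---------------------------------------------------------------------------
# batch generation


@dataclass
class AnalyteSpec:
    """Target definition used for batch simulation."""

    analyte_id: str
    mz: float
    rt: float                      # true retention time, minutes
    response_factor: float = 1000.0  # apex counts per ng/mL
    sigma: float = 0.04
    tailing: float = 0.0
    confirm_mz: float | None = None
    confirm_ratio: float = 0.5     # confirming / quantifier intensity ratio
    is_id: str | None = None       # assigned internal standard
    saturation_height: float | None = None   # response cap (detector overload)


@dataclass
class ISSpec:
    """Internal standard spiked at constant level into every non-blank sample."""

    is_id: str
    mz: float
    rt: float
    height: float = 50000.0
    sigma: float = 0.04


@dataclass
class BatchSpec:
    """Everything needed to simulate a screening batch deterministically.

    Calibration spans 0.1-1000 ng/mL by default, the working range of an
    LC-HRMS micropollutant method; GC methods typically use 0.5-500 ng/mL.
    ``compound_rt_shift_range`` displaces the *reported* target-list RT per
    compound (the planted peak stays put), emulating a target list whose
    retention times are stale; ``global_shift`` moves every planted peak.
    """

    analytes: list[AnalyteSpec]
    internal_standards: list[ISSpec]
    cal_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 1000.0)
    n_blanks: int = 3
    n_references: int = 3
    reference_conc: float = 10.0
    n_samples: int = 4
    include_is_only: bool = True
    n_matrix_qc: int = 0
    matrix_suppression: float = 1.0     # multiplies responses in matrix QC
    sample_conc_range: tuple[float, float] = (0.5, 200.0)
    sample_presence_prob: float = 0.5
    global_shift: float = 0.0           # minutes, applied to every planted peak
    per_sample_shift_sd: float = 0.0
    compound_rt_shift_range: tuple[float, float] | None = None
    blank_contam_ids: tuple[str, ...] = ()
    blank_contam_height: float = 500.0
    baseline: float = 20.0
    noise_sd: float = 5.0
    response_noise: float = 0.0         # multiplicative sd on planted heights
    rt_range: tuple[float, float] = (0.0, 14.0)
    spacing: float = 0.01
    mode: str = "LC"
    seed: int = 0


@dataclass
class SyntheticBatch:
    """Output bundle of :func:`make_batch`: file paths plus ground truth."""

    manifest: pd.DataFrame         # path, sample_id, group, concentration
    targets: pd.DataFrame          # analyte_id, mz, rt (as listed), ...
    is_table: pd.DataFrame
    truth_presence: pd.DataFrame   # analyte_id x sample_id -> planted bool
    truth_conc: pd.DataFrame       # analyte_id x sample_id -> planted ng/mL
    truth_shifts: pd.DataFrame     # per-sample planted shift, per-compound list shift


def _sample_plan(spec: BatchSpec) -> list[tuple[str, str, float]]:
    plan = [(f"blank_{i+1}", "blank", 0.0) for i in range(spec.n_blanks)]
    plan += [(f"cal_{lvl:g}", "calibration", lvl) for lvl in spec.cal_levels]
    plan += [(f"ref_{i+1}", "reference", spec.reference_conc)
             for i in range(spec.n_references)]
    if spec.include_is_only:
        plan.append(("is_only", "is_only", 0.0))
    plan += [(f"mqc_{i+1}", "matrix_qc", spec.reference_conc)
             for i in range(spec.n_matrix_qc)]
    plan += [(f"sample_{i+1}", "sample", np.nan) for i in range(spec.n_samples)]
    return plan


def make_batch(spec: BatchSpec, out_dir: str | Path) -> SyntheticBatch:
    """Simulate a full batch: one mzML per sample plus ground-truth tables.

    Deterministic for a fixed ``spec.seed``. Analyte responses follow
    height = response_factor x concentration (optionally noisy / saturated);
    internal standards are spiked at constant height into every non-blank
    sample. Truth tables record planted presence, concentration and shifts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    plan = _sample_plan(spec)

    # per-compound target-list RT displacement (listed RT = true RT + delta),
    # applied to analytes and internal standards alike so the displacement is
    # discoverable through the IS; drawn from a dedicated stream so batches
    # with and without displacement are otherwise identical
    shift_rng = np.random.default_rng([spec.seed, 2654435761])
    list_shift = {}
    for key in [a.analyte_id for a in spec.analytes] \
            + [s.is_id for s in spec.internal_standards]:
        if spec.compound_rt_shift_range is not None:
            lo, hi = spec.compound_rt_shift_range
            list_shift[key] = float(shift_rng.uniform(lo, hi))
        else:
            list_shift[key] = 0.0

    presence = {}
    conc = {}
    rows_manifest = []
    sample_shifts = {}
    for sample_id, group, level in plan:
        shift = spec.global_shift
        if spec.per_sample_shift_sd > 0:
            shift += float(rng.normal(0.0, spec.per_sample_shift_sd))
        sample_shifts[sample_id] = shift
        peaks: list[PeakSpec] = []
        if group != "blank":
            for s in spec.internal_standards:
                peaks.append(PeakSpec(s.mz, s.rt + shift, s.height, s.sigma))
        for a in spec.analytes:
            if group in ("calibration", "reference", "matrix_qc"):
                c = level
            elif group == "sample":
                c = float(rng.uniform(*spec.sample_conc_range)) \
                    if rng.random() < spec.sample_presence_prob else 0.0
            else:
                c = 0.0
            presence[(a.analyte_id, sample_id)] = c > 0
            conc[(a.analyte_id, sample_id)] = c
            h = a.response_factor * c
            if spec.response_noise > 0 and h > 0:
                h *= float(np.exp(rng.normal(0.0, spec.response_noise)))
            if group == "matrix_qc":
                h *= spec.matrix_suppression
            if a.saturation_height is not None:
                h = min(h, a.saturation_height)
            if h > 0:
                peaks.append(PeakSpec(a.mz, a.rt + shift, h, a.sigma, a.tailing))
                if a.confirm_mz is not None:
                    peaks.append(PeakSpec(a.confirm_mz, a.rt + shift,
                                          h * a.confirm_ratio, a.sigma, a.tailing))
            if group == "blank" and a.analyte_id in spec.blank_contam_ids:
                peaks.append(PeakSpec(a.mz, a.rt + shift,
                                      spec.blank_contam_height, a.sigma))
                presence[(a.analyte_id, sample_id)] = False
        # every targeted channel must exist in every file so that empty EICs
        # still carry baseline + noise
        all_mz = {a.mz for a in spec.analytes} | {s.mz for s in spec.internal_standards}
        all_mz |= {a.confirm_mz for a in spec.analytes if a.confirm_mz is not None}
        present_mz = {p.mz for p in peaks}
        for mz in sorted(all_mz - present_mz):
            peaks.append(PeakSpec(mz, spec.rt_range[0] + 0.01, 1e-9, 0.001))
        t, cents = make_chromatogram(
            peaks, rt_range=spec.rt_range, spacing=spec.spacing,
            baseline=spec.baseline, noise_sd=spec.noise_sd,
            seed=int(rng.integers(0, 2 ** 31)))
        path = write_mzml(out_dir / f"{sample_id}.mzML", t, cents)
        rows_manifest.append({"path": str(path), "sample_id": sample_id,
                              "group": group, "concentration": level})

    manifest = pd.DataFrame(rows_manifest)
    targets = pd.DataFrame([{
        "analyte_id": a.analyte_id, "name": a.analyte_id, "mz": a.mz,
        "rt": a.rt + list_shift[a.analyte_id],
        "confirm_mz": a.confirm_mz if a.confirm_mz is not None else np.nan,
        "confirm_ratio": a.confirm_ratio,
        "is_id": a.is_id if a.is_id is not None else "",
        "mode": spec.mode} for a in spec.analytes])
    is_table = pd.DataFrame([{"is_id": s.is_id, "mz": s.mz,
                              "rt": s.rt + list_shift[s.is_id],
                              "mode": spec.mode} for s in spec.internal_standards])
    sample_ids = [sid for sid, _, _ in plan]
    analyte_ids = [a.analyte_id for a in spec.analytes]
    truth_presence = pd.DataFrame(
        [[presence[(a, s)] for s in sample_ids] for a in analyte_ids],
        index=analyte_ids, columns=sample_ids)
    truth_conc = pd.DataFrame(
        [[conc[(a, s)] for s in sample_ids] for a in analyte_ids],
        index=analyte_ids, columns=sample_ids)
    truth_shifts = pd.DataFrame({
        "sample_id": sample_ids,
        "planted_shift": [sample_shifts[s] for s in sample_ids]})
    truth_shifts.attrs["list_shift"] = list_shift

    manifest.to_csv(out_dir / "manifest.csv", index=False)
    targets.to_csv(out_dir / "targets.csv", index=False)
    is_table.to_csv(out_dir / "internal_standards.csv", index=False)
    truth_presence.to_csv(out_dir / "truth_presence.csv")
    truth_conc.to_csv(out_dir / "truth_conc.csv")
    truth_shifts.to_csv(out_dir / "truth_shifts.csv", index=False)
    return SyntheticBatch(manifest, targets, is_table, truth_presence,
                          truth_conc, truth_shifts)
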