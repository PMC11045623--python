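"""Minimal mzML parsing.

Reads the subset of mzML the workflow needs from centroided MS1 data: spectrum
ms level, centroid/profile flag, scan start time, and the m/z and intensity
binary arrays (32/64-bit float, zlib or uncompressed). Parsing is streaming
(lxml iterparse) and namespace-agnostic, so files from common converters load
without the full PSI controlled-vocabulary machinery.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F32 = "MS:1000521"
_ACC_F64 = "MS:1000523"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


@dataclass
class SpectrumRecord:
    """One parsed spectrum: time in minutes plus centroid arrays."""

    scan_time: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    is_profile: bool


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = dict(child.attrib)
    return out


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    dtype = "<f8"
    compressed = False
    kind = None
    text = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> SpectrumRecord:
    params = _cv_params(elem)
    ms_level = int(params.get(_ACC_MS_LEVEL, {}).get("value", 1))
    is_profile = _ACC_PROFILE in params
    scan_time = np.nan
    mz = inten = np.empty(0)
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam" and child.get("accession") == _ACC_SCAN_START:
            t = float(child.get("value"))
            unit = child.get("unitName", "minute")
            scan_time = t / 60.0 if unit.lower().startswith("sec") else t
        elif tag == "binaryDataArray":
            kind, arr = _decode_binary_array(child)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
    if np.isnan(scan_time):
        raise ValueError("spectrum without a scan start time")
    if len(mz) != len(inten):
        raise ValueError("m/z and intensity array length mismatch")
    return SpectrumRecord(scan_time, ms_level, mz, inten, is_profile)


def iter_spectra(path: str | Path):
    """Yield :class:`SpectrumRecord` for every spectrum in an mzML file."""
    path = Path(path)
    try:
        for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
            yield _parse_spectrum(elem)
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot read mzML file {path.name}: {exc}") from exc
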