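"""Workflow parameters.

All tunables of the screening engine live in one frozen-ish dataclass so that
every stage (EIC extraction, baseline cascade, peak walker, shift model,
screening gates, calibration) reads from a single, validated source. Keys in a
configuration file use the same names as the dataclass fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class WorkflowParams:
    """User-tunable analysis parameters with their default values.

    The defaults correspond to a routine LC/GC-HRMS target screening setup;
    each parameter is documented next to the stage that consumes it.
    """

    # --- EIC extraction ---
    mz_tol_default: float = 5.0          # extraction tolerance (ppm unless mz_tol_is_da)
    mz_tol_is_da: bool = False           # interpret mz_tol_default as absolute Da
    background_extension_factor: float = 1.5   # background window = 1.5x search window
    initial_search_halfwidth: float = 1.5      # min; pre-annotation search half window

    # --- baseline / noise cascade ---
    zigzag_trigger_threshold: float = 0.25     # max tolerated zigzag fraction (trigger A)
    background_rmse_threshold: float = 0.10    # relative RMSE of baseline set (trigger B)
    minimum_background_ratio: float = 3.0      # max intensity / Q25 must exceed (trigger C)
    normal_background_quantile: float = 0.25
    higher_background_quantile: float = 0.80

    # --- peak walker ---
    intensity_factor_decrease: float = 0.40    # drop > 40% of last assigned continues peak
    intensity_factor_increase: float = 0.40    # rise > 40% starts the new-peak counter
    density_factor: float = 5.0                # plateau tolerance = 5 x data density
    increase_density_fraction: float = 0.25    # rise tolerance = 1/4 x data density
    min_peak_points: int = 7                   # peaks with <= this many points get CHECK
    minimum_cutoff_intensity_factor: float = 0.001  # x highest reference height

    # --- retention-time windows ---
    rt_window_floor_lc: float = 0.5            # min half width, LC (minutes)
    rt_window_floor_gc: float = 0.1            # min half width, GC (minutes)

    # --- screening gates ---
    confirming_ratio_tolerance: float = 0.20   # allowed deviation of confirming-ion ratio
    use_MINDIST: bool = False                  # enable SAX shape gate
    mindist_ceiling: float = 3.0               # max accepted MINDIST vs consensus shape
    sax_alphabet_size: int = 7
    exact_rt_scan_tolerance: float = 1.0       # scans; "exactly at expected RT" override

    # --- zigzag operational definition ---
    zigzag_min_run: int = 4                    # min points in an alternating run

    # --- quantification ---
    min_r2: float = 0.95
    max_error_quant: float = 0.30              # fractional (30%)
    min_cal_points: int = 4
    blank_fraction_threshold: float = 1.0 / 3.0
    blank_multiplier: float = 3.0
    iqr_fence_multiplier: float = 1.5
    response_type: str = "area"                # "area" or "height"

    # --- reporting ---
    ba_limit_multiplier: float = 1.96

    def __post_init__(self) -> None:
        for key in ("normal_background_quantile", "higher_background_quantile",
                    "blank_fraction_threshold", "increase_density_fraction"):
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{key} must lie in (0, 1), got {v}")
        if self.normal_background_quantile >= self.higher_background_quantile:
            raise ValueError("normal_background_quantile must be below "
                             "higher_background_quantile")
        if self.min_cal_points < 2:
            raise ValueError("min_cal_points must be >= 2")
        if self.background_extension_factor < 1.0:
            raise ValueError("background_extension_factor must be >= 1")
        if not 2 <= self.sax_alphabet_size <= 20:
            raise ValueError("sax_alphabet_size must be in [2, 20]")
        if self.response_type not in ("area", "height"):
            raise ValueError("response_type must be 'area' or 'height'")

    def rt_window_floor(self, mode: str) -> float:
        """Minimum search half-width for an instrument mode ('LC' or 'GC')."""
        mode = mode.upper()
        if mode == "LC":
            return self.rt_window_floor_lc
        if mode == "GC":
            return self.rt_window_floor_gc
        raise ValueError(f"unknown instrument mode: {mode!r}")


_FIELD_NAMES = {f.name for f in dataclasses.fields(WorkflowParams)}


def load_config(path: str | Path | None) -> WorkflowParams:
    """Load parameters from a YAML key/value file over the defaults.

    Unknown keys raise, guarding against silently ignored typos; out-of-range
    values raise with the offending key named.
    """
    if path is None:
        return WorkflowParams()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key: value mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return WorkflowParams(**data)
    except ValueError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc
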