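"""End-to-end orchestration: raw frames -> anisotropy maps -> rates CSV.

``run_pipeline`` composes the stages in the order of the original workflow:
G-factor calibration from fluorescein, split/register/background-correct each
sensor frame, per-pixel anisotropy, per-ROI statistics, kinetic series
assembly and rate fitting.  Outputs are tidy CSVs (series and rates) plus a
QC report (G estimate, shift, masked-pixel fraction per frame, per-ROI valid
pixel counts).  Every CSV embeds the configuration hash and package version
in comment header lines, and a rerun with identical inputs and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anisotropy import (
    DEFAULT_INTENSITY_THRESHOLD,
    anisotropy_map,
    estimate_g_factor,
)
from .errors import ConfigurationError, DataQualityError, InsufficientSignalError
from .image_model import GFactor, OptosplitFrame, Rect, read_frame, read_image
from .preprocess import (
    DEFAULT_MAX_SHIFT,
    DEFAULT_RADIUS,
    ShiftEstimate,
    estimate_shift,
    preprocess_frame,
    split_channels,
)
from .roi_kinetics import (
    DEFAULT_MIN_VALID,
    ROI,
    assemble_series,
    estimate_rate,
    measurements_to_frame,
    rates_to_frame,
    read_rois_csv,
    roi_mean_anisotropy,
    rois_from_label_mask,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("anisopipe")


@dataclass
class RunConfig:
    """Configuration of one analysis run (mirrors the YAML file).

    Defaults follow the published workflow where it states them: rolling-ball
    radius 100 px, 5-minute sampling interval, treatment at the second
    timepoint (baseline at or before ``treatment_time_min``).
    """

    frames: list[str] = field(default_factory=list)  # sensor TIFFs, time order
    fluorescein: Optional[str] = None
    rois: Optional[str] = None  # polygon CSV or uint16 label-mask TIFF
    output_dir: str = "."
    rect_para: Union[Rect, tuple, str] = (0, 0, 0, 0)
    rect_perp: Union[Rect, tuple, str] = (0, 0, 0, 0)
    radius: float = DEFAULT_RADIUS
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    min_valid: int = DEFAULT_MIN_VALID
    interval_min: float = 5.0
    treatment_time_min: float = 0.0
    baseline_time_min: float = 0.0
    model: str = "exponential"
    max_shift: float = DEFAULT_MAX_SHIFT
    condition: str = "condition"
    g_override: Optional[float] = None
    camera_offset: float = 0.0  # dark level subtracted in G estimation
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if isinstance(v, Rect):
                v = [v.x, v.y, v.w, v.h]
            elif isinstance(v, tuple):
                v = list(v)
            d[name] = v
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Identifies the analysis (inputs and parameters), not where its
        results are written: ``output_dir`` is excluded so reruns into
        different directories produce identical output files.
        """
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    series: pd.DataFrame
    rates: pd.DataFrame
    qc: dict
    series_path: Path
    rates_path: Path
    qc_path: Path


def _load_rois(path: str) -> tuple[list[ROI], Optional[np.ndarray]]:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        mask = read_image(p)
        return rois_from_label_mask(mask), mask
    return read_rois_csv(p), None


def _write_csv_with_header(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# anisopipe {__version__}\n# config_hash {config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run calibration, preprocessing, anisotropy and kinetics for one condition.

    The alignment shift is estimated once, from the first sensor frame, and
    applied to every frame of the run — the dual-channel misalignment is an
    instrument property, constant within an acquisition session.
    """
    if not config.frames:
        raise ConfigurationError("no sensor frames configured")
    rect_para = Rect.coerce(config.rect_para)
    rect_perp = Rect.coerce(config.rect_perp)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- G-factor -------------------------------------------------------
    if config.g_override is not None:
        g = GFactor(value=float(config.g_override), mode="scalar", estimation_region="full")
        if config.fluorescein:
            logger.warning(
                "both --g and a fluorescein calibration supplied; using explicit G=%.4f",
                g.value,
            )
        logger.info("using explicit G = %.4f", g.value)
    else:
        if not config.fluorescein:
            raise ConfigurationError(
                "missing fluorescein calibration: supply 'fluorescein' or 'g_override'"
            )
        fl_frames = read_frame(config.fluorescein, rect_para, rect_perp)
        pairs = [split_channels(f) for f in fl_frames]
        g = estimate_g_factor(pairs, offset=config.camera_offset)
        logger.info("estimated G = %.4f from %d fluorescein frame(s)", g.value, len(pairs))

    # ---- frames ---------------------------------------------------------
    frames: list[OptosplitFrame] = []
    for path in config.frames:
        frames.extend(
            read_frame(
                path,
                rect_para,
                rect_perp,
                timepoint_min=config.baseline_time_min if not frames
                else frames[-1].timepoint_min + config.interval_min,
                interval_min=config.interval_min,
            )
        )
    shift = estimate_shift(split_channels(frames[0]), max_shift=config.max_shift)
    logger.info("alignment shift (dy, dx) = (%.3f, %.3f)", shift.dy, shift.dx)

    if not config.rois:
        raise ConfigurationError("no ROI file configured")
    rois, label_mask = _load_rois(config.rois)
    if not rois:
        raise DataQualityError(f"no ROIs found in {config.rois}")

    qc_frames = []
    measurements: dict[str, list] = {roi.label: [] for roi in rois}
    roi_valid_counts: dict[str, list[int]] = {roi.label: [] for roi in rois}
    for frame in frames:
        pair, _ = preprocess_frame(
            frame, radius=config.radius, max_shift=config.max_shift, shift=shift
        )
        amap = anisotropy_map(pair, g, intensity_threshold=config.intensity_threshold)
        qc_frames.append(
            {
                "timepoint_min": frame.timepoint_min,
                "masked_pixel_fraction": float(1.0 - amap.valid.mean()),
            }
        )
        for roi in rois:
            try:
                m = roi_mean_anisotropy(
                    amap,
                    roi,
                    min_valid=config.min_valid,
                    timepoint_min=frame.timepoint_min,
                    label_mask=label_mask,
                )
            except InsufficientSignalError as exc:
                logger.warning("dropping measurement: %s", exc)
                continue
            measurements[roi.label].append(m)
            roi_valid_counts[roi.label].append(m.n_valid_pixels)

    # ---- series and rates ----------------------------------------------
    series_list = []
    rates = []
    for roi in rois:
        ms = measurements[roi.label]
        if len(ms) < 2:
            logger.warning("ROI %s has <2 usable timepoints; skipped", roi.label)
            continue
        series = assemble_series(
            ms,
            condition=config.condition,
            treatment_time_min=config.treatment_time_min,
            interval_min=config.interval_min,
        )
        series_list.append(series)
        try:
            rates.append(estimate_rate(series, model=config.model))
        except DataQualityError as exc:
            logger.warning("rate fit skipped for ROI %s: %s", roi.label, exc)
    if not series_list:
        raise DataQualityError("all ROIs fell below the minimum valid-pixel count")

    series_df = measurements_to_frame(series_list)
    rates_df = rates_to_frame(rates)
    chash = config.config_hash()
    series_path = out_dir / "series.csv"
    rates_path = out_dir / "rates.csv"
    qc_path = out_dir / "qc.json"
    _write_csv_with_header(series_df, series_path, chash)
    _write_csv_with_header(rates_df, rates_path, chash)
    qc = {
        "version": __version__,
        "config_hash": chash,
        "g_factor": g.value,
        "g_source_frames": g.source_frames,
        "shift_dy": shift.dy,
        "shift_dx": shift.dx,
        "shift_peak_quality": shift.peak_quality,
        "frames": qc_frames,
        "roi_valid_pixels": roi_valid_counts,
    }
    with open(qc_path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        series=series_df,
        rates=rates_df,
        qc=qc,
        series_path=series_path,
        rates_path=rates_path,
        qc_path=qc_path,
    )
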