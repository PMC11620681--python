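"""Per-ROI anisotropy statistics, kinetic series assembly and rate estimation.

The replicate unit is the ROI (one cell), mirroring assays that image 5–30
cells per dish.  ROIs are drawn on the parallel-intensity image (to avoid
selection bias toward bright/dim anisotropy) as polygons, or supplied as a
label-mask image; a nucleus exclusion polygon can be attached because the
sensor is excluded from the nucleus.

Anisotropy declines after a treatment that forces NADPH consumption
(diamide + 2-DG): NADP⁺ rises, the sensor dimerizes, homoFRET depolarizes the
emission.  The decline is summarized either as a linear slope of mean r vs
time or as the decay constant k of a single-exponential relaxation

    r(t) = r_inf + (r0 − r_inf) · exp(−k·(t − t_treat)),

with r0 fixed at the baseline measurement.  Conditions are compared
descriptively by the bootstrap difference of mean rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import optimize, stats

from .errors import DataQualityError, InsufficientSignalError
from .image_model import AnisotropyMap

__all__ = [
    "ROI",
    "ROIMeasurement",
    "KineticSeries",
    "RateEstimate",
    "ConditionComparison",
    "rasterize_roi",
    "roi_mean_anisotropy",
    "assemble_series",
    "estimate_rate",
    "compare_conditions",
    "final_concentration",
    "read_rois_csv",
    "write_rois_csv",
    "rois_from_label_mask",
    "measurements_to_frame",
    "rates_to_frame",
]

DEFAULT_MIN_VALID = 20  # pixels


@dataclass
class ROI:
    """A cell region of interest.

    ``geometry`` is either an (N, 2) polygon vertex array in (x, y) pixel
    coordinates (N ≥ 3) or an integer label value referring to a label-mask
    image.  ``exclude_geometry`` is an optional polygon removed from the
    region (typically the nucleus, which excludes the sensor).
    """

    label: str
    geometry: Union[np.ndarray, int]
    exclude_geometry: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not isinstance(self.geometry, (int, np.integer)):
            self.geometry = np.asarray(self.geometry, dtype=np.float64)
            if self.geometry.ndim != 2 or self.geometry.shape[1] != 2 or len(self.geometry) < 3:
                raise ValueError("polygon geometry must be an (N>=3, 2) array of (x, y)")
        if self.exclude_geometry is not None:
            self.exclude_geometry = np.asarray(self.exclude_geometry, dtype=np.float64)
            if self.exclude_geometry.ndim != 2 or len(self.exclude_geometry) < 3:
                raise ValueError("exclude polygon must be an (N>=3, 2) array")


@dataclass(frozen=True)
class ROIMeasurement:
    """Anisotropy summary of one ROI at one timepoint."""

    roi_label: str
    timepoint_min: float
    mean_r: float
    sd_r: float
    n_valid_pixels: int
    mean_total_intensity: float


@dataclass
class KineticSeries:
    """Time-ordered measurements of one ROI under one condition."""

    condition: str
    measurements: list[ROIMeasurement]
    treatment_time_min: float
    interval_min: float = 5.0

    @property
    def times(self) -> np.ndarray:
        return np.array([m.timepoint_min for m in self.measurements])

    @property
    def mean_r(self) -> np.ndarray:
        return np.array([m.mean_r for m in self.measurements])

    @property
    def roi_label(self) -> str:
        return self.measurements[0].roi_label if self.measurements else ""


@dataclass(frozen=True)
class RateEstimate:
    """Fitted anisotropy-decline rate for one kinetic series.

    ``rate`` is the slope of mean r vs time (per minute) for the linear
    model, or the decay constant k (per minute) for the exponential model.
    """

    model: str
    rate: float
    intercept_or_r0: float
    se_rate: float
    n_points: int
    r_inf: Optional[float] = None
    roi_label: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ConditionComparison:
    """Bootstrap comparison of mean rates between two conditions (a − b)."""

    difference: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center-in-polygon mask; a pixel belongs if its center is inside."""
    rows, cols = shape
    xmin = max(0, int(np.floor(vertices[:, 0].min())))
    xmax = min(cols - 1, int(np.ceil(vertices[:, 0].max())))
    ymin = max(0, int(np.floor(vertices[:, 1].min())))
    ymax = min(rows - 1, int(np.ceil(vertices[:, 1].max())))
    mask = np.zeros(shape, dtype=bool)
    if xmin > xmax or ymin > ymax:
        return mask
    yy, xx = np.mgrid[ymin : ymax + 1, xmin : xmax + 1]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(vertices).contains_points(pts)
    mask[ymin : ymax + 1, xmin : xmax + 1] = inside.reshape(yy.shape)
    return mask


def rasterize_roi(
    roi: ROI, shape: tuple[int, int], label_mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Boolean membership mask for an ROI (geometry minus exclusion)."""
    if isinstance(roi.geometry, (int, np.integer)):
        if label_mask is None:
            raise ValueError(f"ROI {roi.label!r} refers to a label mask but none was given")
        mask = np.asarray(label_mask) == int(roi.geometry)
    else:
        mask = _polygon_mask(roi.geometry, shape)
    if roi.exclude_geometry is not None:
        mask &= ~_polygon_mask(roi.exclude_geometry, shape)
    return mask


def roi_mean_anisotropy(
    amap: AnisotropyMap,
    roi: ROI,
    min_valid: int = DEFAULT_MIN_VALID,
    timepoint_min: float = 0.0,
    label_mask: Optional[np.ndarray] = None,
    estimator: str = "pixelwise",
) -> ROIMeasurement:
    """Anisotropy summary over the ROI's valid pixels.

    ``estimator="pixelwise"`` (default) is the unweighted arithmetic mean of
    per-pixel r — per-pixel anisotropy followed by ROI statistics.
    ``estimator="ensemble"`` recomputes r from the summed intensities, which
    equals the intensity-weighted mean of pixel r; it down-weights dim pixels
    and is far less sensitive to the r -> 1 artifact of perpendicular pixels
    clipped to zero, so prefer it at low photon budgets.

    Raises :class:`InsufficientSignalError` with fewer than ``min_valid``
    valid pixels — edges, masked nuclei and dim cells are unreliable.
    """
    if estimator not in ("pixelwise", "ensemble"):
        raise ValueError(f"unknown estimator {estimator!r}")
    member = rasterize_roi(roi, amap.r.shape, label_mask)
    sel = member & amap.valid
    n = int(sel.sum())
    if n < min_valid:
        raise InsufficientSignalError(
            f"ROI {roi.label!r} at t={timepoint_min:g} min has {n} valid pixels "
            f"(minimum {min_valid})"
        )
    r = amap.r[sel]
    if estimator == "ensemble":
        weights = amap.total_intensity[sel]
        mean_r = float(np.average(r, weights=weights))
    else:
        mean_r = float(r.mean())
    return ROIMeasurement(
        roi_label=roi.label,
        timepoint_min=float(timepoint_min),
        mean_r=mean_r,
        sd_r=float(r.std(ddof=1)) if n > 1 else 0.0,
        n_valid_pixels=n,
        mean_total_intensity=float(amap.total_intensity[sel].mean()),
    )


def assemble_series(
    measurements: Sequence[ROIMeasurement],
    condition: str,
    treatment_time_min: float,
    interval_min: float = 5.0,
    interval_tol_min: float = 0.5,
) -> KineticSeries:
    """Order measurements by time and validate the kinetic design.

    Requires ≥ 2 timepoints, no duplicate times, exactly one baseline
    (time ≤ treatment time), and post-treatment spacing consistent with
    ``interval_min`` within ``interval_tol_min``.
    """
    if len(measurements) < 2:
        raise DataQualityError("a kinetic series needs at least two timepoints")
    ordered = sorted(measurements, key=lambda m: m.timepoint_min)
    times = np.array([m.timepoint_min for m in ordered])
    if np.any(np.diff(times) <= 0):
        raise DataQualityError(f"duplicate timepoints in series: {times.tolist()}")
    n_baseline = int(np.sum(times <= treatment_time_min))
    if n_baseline != 1:
        raise DataQualityError(
            f"expected exactly one baseline (t <= {treatment_time_min}), found {n_baseline}"
        )
    post = times[times > treatment_time_min]
    if len(post) >= 2:
        gaps = np.diff(post)
        if np.any(np.abs(gaps - interval_min) > interval_tol_min):
            raise DataQualityError(
                f"post-treatment spacing {gaps.tolist()} inconsistent with "
                f"interval {interval_min} ± {interval_tol_min} min"
            )
    return KineticSeries(
        condition=condition,
        measurements=list(ordered),
        treatment_time_min=float(treatment_time_min),
        interval_min=float(interval_min),
    )


def estimate_rate(series: KineticSeries, model: str = "linear") -> RateEstimate:
    """Fit the anisotropy decline of one series.

    linear
        Least-squares slope of mean r vs time over post-treatment points
        (baseline excluded; the treatment changes the regime).
    exponential
        Least-squares fit of r(t) = r_inf + (r0 − r_inf)·exp(−k·(t−t_treat))
        over baseline + post points, with r0 fixed at the baseline mean r.

    Requires ≥ 3 post-treatment points and a nondegenerate time spread.
    """
    t_treat = series.treatment_time_min
    times = series.times
    r = series.mean_r
    post = times > t_treat
    if int(post.sum()) < 3:
        raise DataQualityError("rate estimation needs >= 3 post-treatment points")
    if np.ptp(times[post]) <= 0:
        raise DataQualityError("degenerate time spread")

    if model == "linear":
        res = stats.linregress(times[post], r[post])
        se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        return RateEstimate(
            model="linear",
            rate=float(res.slope),
            intercept_or_r0=float(res.intercept),
            se_rate=se,
            n_points=int(post.sum()),
            roi_label=series.roi_label,
            condition=series.condition,
        )
    if model != "exponential":
        raise ValueError(f"unknown model {model!r}")

    baseline = times <= t_treat
    r0 = float(r[baseline][-1])
    t_fit = times[post] - t_treat
    r_fit = r[post]
    if np.allclose(r_fit, r0, atol=1e-12):
        return RateEstimate(
            model="exponential",
            rate=0.0,
            intercept_or_r0=r0,
            se_rate=0.0,
            n_points=int(post.sum()),
            r_inf=r0,
            roi_label=series.roi_label,
            condition=series.condition,
        )

    def _model(t: np.ndarray, k: float, r_inf: float) -> np.ndarray:
        return r_inf + (r0 - r_inf) * np.exp(-k * t)

    try:
        popt, pcov = optimize.curve_fit(
            _model,
            t_fit,
            r_fit,
            p0=(0.05, float(r_fit[-1])),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise DataQualityError(f"exponential fit failed to converge: {exc}") from exc
    k, r_inf = (float(v) for v in popt)
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else 0.0
    return RateEstimate(
        model="exponential",
        rate=k,
        intercept_or_r0=r0,
        se_rate=se,
        n_points=int(post.sum()),
        r_inf=r_inf,
        roi_label=series.roi_label,
        condition=series.condition,
    )


def compare_conditions(
    a: Sequence[RateEstimate],
    b: Sequence[RateEstimate],
    n_boot: int = 2000,
    seed: int = 0,
) -> ConditionComparison:
    """Difference of mean rates (a − b) with a percentile bootstrap CI.

    A descriptive comparison across ROIs; export the tidy CSV for any
    inferential analysis.
    """
    if len(a) < 3 or len(b) < 3:
        raise DataQualityError("condition comparison needs >= 3 ROIs per condition")
    ra = np.array([e.rate for e in a])
    rb = np.array([e.rate for e in b])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = rng.choice(ra, ra.size).mean() - rng.choice(rb, rb.size).mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ConditionComparison(
        difference=float(ra.mean() - rb.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def final_concentration(
    stock_mM: float, volume_added: float, volume_initial: float
) -> float:
    """Concentration after adding ``volume_added`` of stock to ``volume_initial``.

    Volumes may be in any one consistent unit.  E.g. mixing 1 mL of a 500 mM
    stock into 1 mL gives 250 mM; adding 100 μL of a 250 mM mixture to
    900 μL gives a 25 mM final concentration.
    """
    if stock_mM <= 0 or volume_added <= 0 or volume_initial <= 0:
        raise ValueError("stock concentration and volumes must be positive")
    return stock_mM * volume_added / (volume_added + volume_initial)


# ---------------------------------------------------------------------------
# ROI and tidy-table I/O


def read_rois_csv(path: Union[str, Path]) -> list[ROI]:
    """Read polygon ROIs from a CSV of (label, vertex_x, vertex_y[, role]) rows.

    ``role`` is ``include`` (default) or ``exclude``; exclude rows define the
    nucleus-exclusion polygon for the same label.
    """
    include: dict[str, list[tuple[float, float]]] = {}
    exclude: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(row for row in fh if not row.startswith("#"))
        header = next(reader)
        if header[0].strip().lower() != "label":
            raise ValueError(f"ROI CSV {path} must start with a 'label' header column")
        for row in reader:
            if not row or not row[0].strip():
                continue
            label = row[0].strip()
            x, y = float(row[1]), float(row[2])
            role = row[3].strip().lower() if len(row) > 3 and row[3].strip() else "include"
            target = include if role == "include" else exclude
            if label not in include and label not in order:
                order.append(label)
            target.setdefault(label, []).append((x, y))
    rois = []
    for label in order:
        if label not in include:
            raise ValueError(f"ROI {label!r} has only exclusion vertices")
        rois.append(
            ROI(
                label=label,
                geometry=np.array(include[label]),
                exclude_geometry=np.array(exclude[label]) if label in exclude else None,
            )
        )
    return rois


def write_rois_csv(rois: Sequence[ROI], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "vertex_x", "vertex_y", "role"])
        for roi in rois:
            if isinstance(roi.geometry, (int, np.integer)):
                raise ValueError("label-mask ROIs cannot be written as polygon CSV")
            for x, y in roi.geometry:
                writer.writerow([roi.label, f"{x:.3f}", f"{y:.3f}", "include"])
            if roi.exclude_geometry is not None:
                for x, y in roi.exclude_geometry:
                    writer.writerow([roi.label, f"{x:.3f}", f"{y:.3f}", "exclude"])


def rois_from_label_mask(mask: np.ndarray) -> list[ROI]:
    """One ROI per nonzero label value of a label-mask image."""
    labels = np.unique(np.asarray(mask))
    return [ROI(label=f"roi{int(v)}", geometry=int(v)) for v in labels if v != 0]


def measurements_to_frame(
    series_list: Sequence[KineticSeries],
) -> pd.DataFrame:
    """Tidy per-ROI, per-timepoint table."""
    rows = []
    for s in series_list:
        for m in s.measurements:
            rows.append(
                {
                    "condition": s.condition,
                    "roi_label": m.roi_label,
                    "timepoint_min": m.timepoint_min,
                    "mean_r": m.mean_r,
                    "sd_r": m.sd_r,
                    "n_valid_pixels": m.n_valid_pixels,
                    "mean_total_intensity": m.mean_total_intensity,
                }
            )
    return pd.DataFrame(rows)


def rates_to_frame(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Tidy per-ROI rate table."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition,
                "roi_label": e.roi_label,
                "model": e.model,
                "rate_per_min": e.rate,
                "se_rate": e.se_rate,
                "intercept_or_r0": e.intercept_or_r0,
                "r_inf": e.r_inf if e.r_inf is not None else np.nan,
                "n_points": e.n_points,
            }
            for e in rates
        ]
    )
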