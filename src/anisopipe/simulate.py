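"""Synthetic Optosplit frames, fluorescein calibrations and kinetic assays.

The generative model follows the physics of a homoFRET NADP⁺ sensor read out
by polarization imaging:

* A cell expresses a sensor whose anisotropy interpolates between a monomer
  value (no homoFRET) and a dimer value (homoFRET-depolarized) as free NADP⁺
  drives dimerization: r = (1 − d)·r_mono + d·r_dimer with dimer fraction d.
* For total expected signal S and true anisotropy r, the polarization
  components are E[I∥] = S·(1 + 2r)/3 and, before detection, S·(1 − r)/3;
  the perpendicular detection path is attenuated by 1/G — exactly the
  asymmetry the fluorescein G-factor corrects.
* Shot noise is Poisson per channel; a constant camera offset is added
  without noise; the perpendicular field is translated by a configurable
  channel misalignment and both fields are composed side by side into one
  camera frame.
* After a treatment that forces NADPH consumption (diamide + 2-DG), cell
  anisotropy relaxes as r(t) = r_inf + (r0 − r_inf)·exp(−k·(t − t_treat)),
  sampled at a baseline and fixed 5-minute intervals.

All randomness flows from a single seed: identical configurations reproduce
frames bit-exactly.  Anisotropy inputs are capped at 0.4, the one-photon
fundamental limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_model import OptosplitFrame, Rect
from .roi_kinetics import KineticSeries, ROI, ROIMeasurement

__all__ = [
    "SensorModel",
    "SceneConfig",
    "AssayConfig",
    "SceneTruth",
    "render_scene",
    "simulate_fluorescein",
    "simulate_assay",
    "simulate_series",
]

R_MAX_1P = 0.4  # one-photon fundamental anisotropy limit


@dataclass(frozen=True)
class SensorModel:
    """Two-state homoFRET sensor: monomer bright-anisotropy, dimer depolarized.

    ``dimer_fraction_fn`` maps the free-NADP⁺ fraction x ∈ [0, 1] to the
    dimer fraction d ∈ [0, 1]; the default is the identity (no binding curve
    is assumed).  Must be monotone nondecreasing with d(0)=0 and d(1)=1.
    """

    r_monomer: float = 0.32
    r_dimer: float = 0.20
    dimer_fraction_fn: Callable[[float], float] = lambda x: x

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_dimer < self.r_monomer <= R_MAX_1P):
            raise ValueError(
                f"need 0 <= r_dimer < r_monomer <= {R_MAX_1P}, "
                f"got {self.r_dimer}, {self.r_monomer}"
            )
        if abs(self.dimer_fraction_fn(0.0)) > 1e-9 or abs(self.dimer_fraction_fn(1.0) - 1.0) > 1e-9:
            raise ValueError("dimer_fraction_fn must satisfy d(0)=0 and d(1)=1")

    def anisotropy(self, nadp_fraction: float) -> float:
        """Cell anisotropy at a given free-NADP⁺ fraction (intensity-weighted mix)."""
        d = float(self.dimer_fraction_fn(float(nadp_fraction)))
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"dimer fraction {d} outside [0, 1]")
        return (1.0 - d) * self.r_monomer + d * self.r_dimer


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of one simulated field of view.

    ``shape`` is the per-channel field size; the composed camera frame is
    twice as wide.  ``expression_photons`` is the expected total signal per
    sensor pixel (both polarization components combined), chosen to match a
    bright live-cell acquisition.  ``channel_shift`` is the (dy, dx)
    displacement of the perpendicular field on the camera — the
    misregistration the pipeline must estimate and undo.
    """

    shape: tuple[int, int] = (128, 128)
    n_cells: int = 8
    cell_axes: tuple[float, float] = (10.0, 16.0)  # min/max ellipse semi-axis, px
    nucleus_fraction: float = 0.4  # nucleus semi-axes relative to cell
    expression_photons: float = 10_000.0
    background: float = 20.0
    offset: float = 100.0
    g: float = 1.15
    channel_shift: tuple[float, float] = (1.0, -1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression_photons < 0 or self.background < 0 or self.offset < 0:
            raise ValueError("photon, background and offset levels must be >= 0")
        if self.g <= 0:
            raise ValueError("true G must be positive")
        if not 0 <= self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must be in [0, 1)")
        lo, hi = self.cell_axes
        if not (0 < lo <= hi) or 2 * hi >= min(self.shape):
            raise ValueError("cells must fit in the field")


@dataclass(frozen=True)
class AssayConfig:
    """Kinetic design of the consumption assay.

    ``k`` maps condition name -> decay constant (per minute); larger k means
    faster NADPH consumption (e.g. an oxLDL-loaded condition with more GSR).
    ``timepoints_min`` defaults to a baseline at 0 followed by five 5-minute
    intervals (a 25-minute kinetic).
    """

    r_baseline: float = 0.32
    r_inf: float = 0.22
    k: dict[str, float] = field(default_factory=lambda: {"control": 0.05})
    treatment_time_min: float = 0.0
    interval_min: float = 5.0
    n_timepoints: int = 6
    cell_sd: float = 0.005  # per-cell baseline anisotropy jitter

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inf <= self.r_baseline <= R_MAX_1P):
            raise ValueError("need 0 <= r_inf <= r_baseline <= 0.4")
        if any(k < 0 for k in self.k.values()):
            raise ValueError("decay constants must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("need a baseline plus at least one post point")

    @property
    def timepoints_min(self) -> np.ndarray:
        return self.treatment_time_min + self.interval_min * np.arange(self.n_timepoints)

    def r_of_t(self, t_min: float, condition: str, r0: Optional[float] = None) -> float:
        """Expected anisotropy of a cell at time ``t_min`` under ``condition``."""
        r0 = self.r_baseline if r0 is None else r0
        if t_min <= self.treatment_time_min:
            return r0
        k = self.k[condition]
        return self.r_inf + (r0 - self.r_inf) * float(
            np.exp(-k * (t_min - self.treatment_time_min))
        )


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a rendered frame."""

    cell_labels: np.ndarray  # per-channel-pixel cell label (0 = background)
    r_true: np.ndarray  # per-cell anisotropy, index = label - 1
    g: float
    channel_shift: tuple[float, float]
    rect_para: Rect
    rect_perp: Rect
    rois: list[ROI]


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _ellipse_polygon(cy: float, cx: float, ay: float, ax: float, n: int = 24) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta)])


def _place_cells(
    scene: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[ROI]]:
    """Lay out non-overlapping elliptical cells; returns label image and ROIs.

    ROIs trace the cell ellipse slightly inside its rim (dim edges are
    unreliable) and carry the nucleus as an exclusion polygon.
    """
    rows, cols = scene.shape
    lo, hi = scene.cell_axes
    labels = np.zeros(scene.shape, dtype=np.uint16)
    rois: list[ROI] = []
    placed: list[tuple[float, float, float]] = []
    label = 0
    attempts = 0
    while label < scene.n_cells and attempts < 200 * scene.n_cells:
        attempts += 1
        ay = rng.uniform(lo, hi)
        ax = rng.uniform(lo, hi)
        margin = max(ay, ax) + 2
        cy = rng.uniform(margin, rows - margin)
        cx = rng.uniform(margin, cols - margin)
        radius = max(ay, ax)
        if any(np.hypot(cy - py, cx - px) < radius + pr + 2 for py, px, pr in placed):
            continue
        label += 1
        placed.append((cy, cx, radius))
        labels[_ellipse_mask(scene.shape, cy, cx, ay, ax)] = label
        nf = scene.nucleus_fraction
        roi = ROI(
            label=f"cell{label:02d}",
            geometry=_ellipse_polygon(cy, cx, 0.9 * ay, 0.9 * ax),
            exclude_geometry=(
                _ellipse_polygon(cy, cx, nf * ay + 0.5, nf * ax + 0.5) if nf > 0 else None
            ),
        )
        rois.append(roi)
    if label < scene.n_cells:
        raise ValueError(
            f"could not place {scene.n_cells} non-overlapping cells in field {scene.shape}"
        )
    # carve out sensor-free nuclei
    if scene.nucleus_fraction > 0:
        nucleus = np.zeros(scene.shape, dtype=bool)
        for (cy, cx, _), roi in zip(placed, rois):
            verts = roi.exclude_geometry
            ay = (verts[:, 1].max() - verts[:, 1].min()) / 2
            ax = (verts[:, 0].max() - verts[:, 0].min()) / 2
            nucleus |= _ellipse_mask(scene.shape, cy, cx, ay, ax)
        labels[nucleus] = 0
    return labels, rois


def _compose_frame(
    exp_para: np.ndarray,
    exp_perp: np.ndarray,
    scene: SceneConfig,
    rng: Optional[np.random.Generator],
    timepoint_min: float,
    quantize: bool,
    channel_label: str,
) -> OptosplitFrame:
    """Shift perp, apply noise/offset, and compose the side-by-side frame."""
    dy, dx = scene.channel_shift
    if (dy, dx) != (0.0, 0.0):
        exp_perp = ndi.shift(exp_perp, (dy, dx), order=1, mode="constant", cval=scene.background)
        exp_perp = np.clip(exp_perp, 0.0, None)
    if rng is not None:
        para = rng.poisson(exp_para).astype(np.float64)
        perp = rng.poisson(exp_perp).astype(np.float64)
    else:
        para, perp = exp_para, exp_perp
    para = para + scene.offset
    perp = perp + scene.offset
    rows, cols = scene.shape
    pixels = np.concatenate([para, perp], axis=1)
    if quantize:
        pixels = np.clip(np.rint(pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return OptosplitFrame(
        pixels=pixels,
        rect_para=Rect(0, 0, cols, rows),
        rect_perp=Rect(cols, 0, cols, rows),
        timepoint_min=timepoint_min,
        channel_label=channel_label,
        metadata={"simulated": "true", "g": f"{scene.g}", "shift": f"{dy},{dx}"},
    )


def render_scene(
    scene: SceneConfig,
    r_true: float | Sequence[float],
    noise: bool = True,
    quantize: bool = True,
    timepoint_min: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    geometry_rng: Optional[np.random.Generator] = None,
    channel_label: str = "sensor",
) -> tuple[OptosplitFrame, SceneTruth]:
    """Render one Optosplit frame of sensor-expressing cells.

    ``r_true`` is a scalar anisotropy shared by all cells or one value per
    cell.  ``rng`` drives the shot noise; ``geometry_rng`` (defaulting to the
    same generator) drives cell placement, so a time series can reuse one
    layout while every frame gets fresh noise.  With ``noise=False`` the
    expected (Poisson-mean) image is returned; with ``quantize=False``
    pixels stay float, so noise-free renders are algebraically exact.
    """
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    labels, rois = _place_cells(scene, geometry_rng if geometry_rng is not None else rng)
    r_cells = np.broadcast_to(np.atleast_1d(np.asarray(r_true, dtype=np.float64)),
                              (scene.n_cells,)).copy()
    if np.any(r_cells < -0.5) or np.any(r_cells > R_MAX_1P):
        raise ValueError(f"r_true must lie in [-0.5, {R_MAX_1P}]")
    r_map = np.zeros(scene.shape)
    inside = labels > 0
    r_map[inside] = r_cells[labels[inside] - 1]
    signal = np.where(inside, scene.expression_photons, 0.0)
    exp_para = signal * (1.0 + 2.0 * r_map) / 3.0 + scene.background
    exp_perp = (signal * (1.0 - r_map) / 3.0) / scene.g + scene.background
    frame = _compose_frame(
        exp_para, exp_perp, scene, rng if noise else None, timepoint_min, quantize, channel_label
    )
    truth = SceneTruth(
        cell_labels=labels,
        r_true=r_cells,
        g=scene.g,
        channel_shift=scene.channel_shift,
        rect_para=frame.rect_para,
        rect_perp=frame.rect_perp,
        rois=rois,
    )
    return frame, truth


def simulate_fluorescein(
    scene: SceneConfig,
    noise: bool = True,
    quantize: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> OptosplitFrame:
    """Render a spatially uniform fluorescein calibration frame (r = 0).

    Carries the scene's true G and channel shift, so estimating G from it
    and correcting the same field should return anisotropy ≈ 0.
    """
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    s = scene.expression_photons
    exp_para = np.full(scene.shape, s / 3.0 + scene.background)
    exp_perp = np.full(scene.shape, (s / 3.0) / scene.g + scene.background)
    return _compose_frame(
        exp_para, exp_perp, scene, rng if noise else None, 0.0, quantize, "fluorescein"
    )


@dataclass
class AssayResult:
    """Frames and ground truth for one simulated assay."""

    frames: dict[str, list[OptosplitFrame]]  # condition -> frames in time order
    fluorescein: OptosplitFrame
    rois: dict[str, list[ROI]]
    truth: pd.DataFrame  # condition, cell, timepoint_min, r_true, k_true


def simulate_assay(
    assay: AssayConfig,
    scene: SceneConfig,
    sensor: Optional[SensorModel] = None,
) -> AssayResult:
    """Simulate the full treatment kinetic: frames per condition and timepoint.

    Each condition gets its own field of cells (its own dish).  Per-cell
    baseline anisotropy is jittered by ``assay.cell_sd`` (persistent across
    the series — expression and microenvironment differ between cells, not
    between consecutive frames), then relaxes exponentially after treatment
    with the condition's decay constant.  ``sensor`` bounds are used to clip
    jittered values to the physical range.
    """
    sensor = SensorModel() if sensor is None else sensor
    noise_rng = np.random.default_rng(scene.seed)
    frames: dict[str, list[OptosplitFrame]] = {}
    rois: dict[str, list[ROI]] = {}
    records = []
    for cond_idx, condition in enumerate(assay.k):
        # each condition is its own dish: distinct layout, persistent per cell
        geometry_seed = (scene.seed + 1000003 * (cond_idx + 1)) % (2**31)
        r0_cells = assay.r_baseline + assay.cell_sd * noise_rng.standard_normal(scene.n_cells)
        r0_cells = np.clip(r0_cells, assay.r_inf, R_MAX_1P)
        cond_frames = []
        for t in assay.timepoints_min:
            r_t = np.array(
                [assay.r_of_t(float(t), condition, r0=float(r0)) for r0 in r0_cells]
            )
            frame, truth = render_scene(
                scene,
                r_t,
                noise=True,
                quantize=True,
                timepoint_min=float(t),
                rng=noise_rng,
                geometry_rng=np.random.default_rng(geometry_seed),
                channel_label=condition,
            )
            cond_frames.append(frame)
            rois[condition] = truth.rois
            for cell_idx, r_val in enumerate(r_t):
                records.append(
                    {
                        "condition": condition,
                        "roi_label": f"cell{cell_idx + 1:02d}",
                        "timepoint_min": float(t),
                        "r_true": float(r_val),
                        "k_true": assay.k[condition],
                    }
                )
        frames[condition] = cond_frames
    fluorescein = simulate_fluorescein(scene, rng=noise_rng)
    return AssayResult(
        frames=frames,
        fluorescein=fluorescein,
        rois=rois,
        truth=pd.DataFrame(records),
    )


def simulate_series(
    assay: AssayConfig,
    n_rois: int = 20,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> dict[str, list[KineticSeries]]:
    """Measurement-level tier: per-ROI mean-r series without image rendering.

    Draws each ROI's baseline from the per-cell jitter model, relaxes it with
    the condition's k, and adds independent Gaussian measurement noise of
    ``noise_sd`` to every timepoint — the between-frame scatter a well-exposed
    ROI mean shows.  Useful for replicate studies where rendering every frame
    would add nothing.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[KineticSeries]] = {}
    for condition in assay.k:
        series_list = []
        for i in range(n_rois):
            r0 = float(
                np.clip(
                    assay.r_baseline + assay.cell_sd * rng.standard_normal(),
                    assay.r_inf,
                    R_MAX_1P,
                )
            )
            meas = []
            for t in assay.timepoints_min:
                r = assay.r_of_t(float(t), condition, r0=r0) + noise_sd * rng.standard_normal()
                meas.append(
                    ROIMeasurement(
                        roi_label=f"roi{i + 1:02d}",
                        timepoint_min=float(t),
                        mean_r=float(r),
                        sd_r=noise_sd,
                        n_valid_pixels=200,
                        mean_total_intensity=1e4,
                    )
                )
            series_list.append(
                KineticSeries(
                    condition=condition,
                    measurements=meas,
                    treatment_time_min=assay.treatment_time_min,
                    interval_min=assay.interval_min,
                )
            )
        out[condition] = series_list
    return out
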