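# Methods

## Anisotropy model

For one-photon excitation, a fluorophore population with anisotropy *r* and
total intensity *S* emits polarization components

    E[I∥] = S·(1 + 2r)/3        E[I⊥] = S·(1 − r)/3.

A real instrument detects the perpendicular channel with different
efficiency; we model this as a detection-side attenuation of 1/G, which is
exactly what the G-factor corrects. The corrected per-pixel anisotropy is

    r = (I∥ − G·I⊥) / (I∥ + 2·G·I⊥),

with total intensity T = I∥ + 2·G·I⊥. For nonnegative channel values and
G > 0 this ratio is algebraically confined to [−0.5, 1], is invariant to a
common rescaling of both channels, and is additive over co-located species
weighted by intensity fraction — three properties the test suite asserts
directly. G is estimated from fluorescein solution, whose anisotropy is
close to zero, so the formula degenerates to G = I∥/I⊥; the scalar
estimator is the ratio of channel means over the central 50 % of the field
(avoiding edge roll-off), optionally after subtracting a camera dark offset
(an uncorrected offset pulls G toward 1 at low calibration brightness). A
per-pixel G mode (smoothed ratio map) exists for vignetting studies; scalar
G is the default.

The homoFRET sensor itself is modeled as a two-state mixture: monomers with
anisotropy `r_monomer` (default 0.32) and dimers depolarized to `r_dimer`
(default 0.20), mixed by a dimer fraction that maps monotonically from the
free-NADP⁺ fraction (identity by default — no binding curve is assumed).
All anisotropy inputs are capped at 0.4, the one-photon fundamental limit.
These sensor numbers are order-of-magnitude choices for a bright
fluorescent-protein sensor, fully configurable, and are not calibrated
against any measured sensor.

## Pipeline stages and numerical choices

**Coordinates.** 0-based, origin top-left; rectangles are (x, y, w, h)
half-open. Multi-page TIFFs are a time series in page order, defaulting to
baseline + 5·page minutes.

**Splitting.** The two fields are cropped by `rect_para`/`rect_perp`, which
must be equal-sized, in-bounds and disjoint. Loading never rescales pixels;
the camera offset is left for background subtraction.

**Registration.** Optosplit misalignment is modeled as pure translation
(rotation/scale are out of scope). The correction applied to the
perpendicular channel is estimated by phase correlation with Fourier
upsampling (default 1/100 px grid); noise-free integer shifts are recovered
exactly and sub-pixel shifts to better than 0.25 px. Resampling is bilinear.
Border rows/columns without source data replicate the nearest edge value
rather than being zero-filled: a constant fill would propagate through the
morphological background estimate over a full ball radius from the border.
Cells are placed away from the border, so replicated pixels never enter an
ROI. The shift is estimated once per run (it is an instrument property) and
applied to every frame.

**Background.** Rolling-ball subtraction with a radius larger than the
largest cell (default 100 px; simulations use 40 px for cells of ≤ 32 px
diameter — same ratio, smaller field). The background is the grayscale
opening with a flat disk footprint of the ball radius — the wide-ball
limit. A curved (hemispherical) profile couples the intensity axis to the
pixel axis one count per pixel, letting the ball apex ride up into dim
structures; on dual-channel data this preferentially steals signal from the
weaker perpendicular channel and biases r upward, so the flat element is
used deliberately. The opening is computed exactly at full resolution
(legacy implementations shrink the image for speed; results can differ at
the ±1-count level).

Two refinements address noise: the opening of a noisy image tracks the
*lower envelope* of the noise, leaving an uncorrected pedestal of a few
counts that dilutes the intensity ratio (an absolute-counts error, so its
effect on r grows as 1/S at low photon budgets). The ball background is
therefore computed on a Gaussian-presmoothed copy (σ = 1 px) and re-anchored
by the mean residual over background pixels. Background pixels are
identified by sigma-clipping the *parallel*-channel residual only: the
parallel channel has the better signal-to-noise, so dim cells that are
statistically invisible in the perpendicular channel are still excluded from
its pedestal estimate. Both refinements are exact no-ops on noise-free
images, and corrected channels are clipped at zero.

**Anisotropy map.** Pixels are invalid where T ≤ the intensity threshold
(default 50 counts post-subtraction; the spec of the original workflow gives
none) or the denominator is below ε = 10⁻⁶ counts. Invalid pixels carry
r = 0, never NaN — the mask carries the information, and downstream
statistics stay NaN-free. `mask_low_signal` tightens the mask for dim cell
rims without touching r.

**ROI statistics.** ROIs are polygons (CSV) or label masks (uint16 TIFF),
drawn on the parallel-intensity image to avoid selection bias, with an
optional nucleus-exclusion polygon (the sensor is excluded from the
nucleus). A pixel belongs to a polygon if its center is inside. The default
per-ROI statistic is the unweighted mean of per-pixel r over valid pixels —
pixel-by-pixel anisotropy followed by ROI statistics. An "ensemble"
estimator (r recomputed from summed intensities, equal to the
intensity-weighted mean of pixel r) is available behind a flag: it
down-weights dim pixels and is far less sensitive to the r → 1 artifact of
perpendicular pixels clipped to zero, so it is the better choice at low
photon budgets; the two differ only in dim pixels. A measurement needs at
least `min_valid` (default 20) valid pixels. The replicate unit is the
ROI/cell, matching assays of 5–30 cells per dish.

**Kinetics.** A series must contain exactly one baseline (t ≤ treatment
time) and post-treatment points at a consistent interval (default 5 min).
Rates: the linear model is the least-squares slope of mean r vs time over
post-treatment points; the exponential model fits
r(t) = r_inf + (r0 − r_inf)·exp(−k·(t − t_treat)) with r0 fixed at the
baseline value (Levenberg–Marquardt, initial k = 0.05/min; a constant
series short-circuits to k = 0). At least 3 post-treatment points are
required. The assay itself shows time courses without fitting a named
model; these rate estimators are this package's extension, and inferential
statistics are deliberately replaced by a descriptive bootstrap comparison
of mean rates (2000 percentile resamples, seeded) — the tidy CSV can be
exported to any stats package.

## Synthetic data generator

`render_scene` emulates the imaging: elliptical cells (semi-axes 10–16 px by
default) with sensor-free nuclear holes (nucleus at 40 % of the cell axes),
expected signal `expression_photons` per sensor pixel (default 10⁴,
matching a bright live-cell acquisition), polarization components as above,
perpendicular detection attenuated by 1/G (default G 1.15), the
perpendicular field translated by the configured channel misalignment
(default (1, −1) px), Poisson shot noise per channel, a constant noiseless
camera offset (default 100 counts) and uniform background light (default 20
counts), composed side by side into one uint16 frame. Noise-free,
unquantized renders satisfy the expected-value identities exactly and are
used as algebraic oracles. `simulate_fluorescein` renders the uniform
calibration field (r = 0) with the same instrument parameters.

`simulate_assay` renders a full treatment kinetic: each condition is its own
dish (own cell layout), per-cell baseline anisotropy is jittered by
`cell_sd` (default 0.005, persistent across the series), and after treatment
each cell relaxes exponentially from r₀ = 0.32 toward r_inf = 0.22 with the
condition's k (defaults in the 0.02–0.06/min range produce a visible
decline over the 25-minute window of a baseline + five 5-minute-interval
design). Ground truth (per-cell r(t), k, masks, ROIs with nucleus
exclusions) is emitted alongside. A measurement-level tier
(`simulate_series`) generates per-ROI mean-r series directly from the same
kinetic model plus Gaussian measurement noise (default SD 0.005, the
between-frame scatter of a well-exposed ROI mean); it serves replicate
studies — e.g. the 100-replicate rate-ordering comparison — where rendering
every frame would add nothing. All randomness flows from a single seed;
identical configurations reproduce frames bit-exactly.

What the generator does *not* emulate: photobleaching, cell movement, focus
drift, read noise (a configurable Gaussian could be added; the default
camera model is shot noise + offset), spectral bleed-through between sensor
colors, high-NA depolarization, or any real binding curve. Passing tests
therefore demonstrate the correctness of the analysis chain under an
idealized but physically structured instrument model — not robustness to
every artifact of real microscopy.

## Problem sizes

Simulated studies use a 192×192 px per-channel field with 20 cells (the
upper end of the 5–30 cells-per-dish replicate rule) and a 40 px ball
radius; these sizes make the exact full-resolution opening and the
100-replicate studies quick on a laptop while preserving the
radius-to-cell-size ratio of the real protocol (radius 100 for real
frames). The photon-budget scaling study spans S ∈ {10², 10³, 10⁴}
expected photons/pixel and summarizes the error-vs-budget relation by the
log-log slope, which is −0.5 for shot-noise-limited recovery.

## Known limitations

- Translation-only registration; rotation, scale and chromatic effects are
  out of scope.
- The background model assumes the true background varies on scales larger
  than the ball; the pedestal re-anchoring assumes most pixels are
  background (cell-dense fields would need `recenter=False` or masked
  calibration frames).
- At 10² photons/pixel the default pixelwise ROI mean carries a small
  positive bias from zero-clipped perpendicular pixels; use the ensemble
  estimator there.
- Anisotropy is reported as raw r; no normalization or conversion to
  absolute NADPH concentration is attempted (no calibration curve exists).
- G-factor estimation from fluorescein assumes the calibration frames are
  dark-corrected or bright enough that the camera offset is negligible; the
  `offset` argument and `camera_offset` config key handle the former.
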