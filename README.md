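# anisopipe

Dual-channel fluorescence-anisotropy image analysis for homoFRET NADP⁺
biosensors — from raw Optosplit camera frames to per-cell anisotropy kinetic
series and NADPH-consumption rate estimates, with a fully seeded synthetic
microscope so the whole pipeline is testable without cells or hardware.

## The problem

Genetically encoded Apollo-NADP⁺ sensors report the cellular NADP⁺/NADPH
balance through homoFRET: free NADP⁺ drives sensor homodimerization, energy
transfer between the identical fluorophores depolarizes the emission, and the
fluorescence anisotropy *r* drops. Imaging this requires polarization optics:
an Optosplit emission splitter projects the parallel (I∥) and perpendicular
(I⊥) fields side by side onto one camera sensor. Turning those raw frames
into per-cell anisotropy time courses takes a chain of corrections —
channel cropping, sub-pixel registration, rolling-ball background
subtraction, instrument G-factor calibration — before the central quantity
can be computed per pixel:

```
r = (I∥ − G·I⊥) / (I∥ + 2·G·I⊥)
```

where G = I∥/I⊥ measured on fluorescein solution (anisotropy ≈ 0) corrects
the unequal detection sensitivity of the two channels, and the denominator
is the total intensity used for validity masking. After adding diamide
(forces glutathione-disulfide reductase to consume NADPH) together with 2-DG
(blocks NADPH regeneration), anisotropy declines over a baseline + 5-minute
sampling design; the decline is summarized per cell as a linear slope or as
the decay constant *k* of

```
r(t) = r_inf + (r0 − r_inf)·exp(−k·(t − t_treat))
```

`anisopipe` is for microscopists and cell biologists running this assay (or
any dual-channel anisotropy imaging) who want a scriptable, reproducible
replacement for ImageJ macro chains, plus a generative model of the whole
experiment for validation.

## Worked example

Simulate a 25-minute consumption assay (baseline + five 5-minute points,
true k = 0.05/min, 10⁴ expected photons per pixel), then run the analysis
chain on the rendered frames:

```python
import numpy as np
from anisopipe import (AssayConfig, SceneConfig, simulate_assay,
                       estimate_g_factor, estimate_shift, split_channels,
                       anisotropy_map, roi_mean_anisotropy,
                       assemble_series, estimate_rate)
from anisopipe.preprocess import preprocess_frame

scene = SceneConfig(seed=7, n_cells=8, shape=(128, 128), expression_photons=10_000)
assay = AssayConfig(k={"control": 0.05})          # NADPH consumption at 0.05 / min
result = simulate_assay(assay, scene)

g = estimate_g_factor([split_channels(result.fluorescein)])
shift = estimate_shift(split_channels(result.frames["control"][0]))
print(f"G-factor: {g.value:.4f}   alignment shift (dy, dx): ({shift.dy:.2f}, {shift.dx:.2f})")

measurements = {roi.label: [] for roi in result.rois["control"]}
for frame in result.frames["control"]:
    pair, _ = preprocess_frame(frame, radius=40, shift=shift)
    amap = anisotropy_map(pair, g, intensity_threshold=2000)
    for roi in result.rois["control"]:
        measurements[roi.label].append(
            roi_mean_anisotropy(amap, roi, timepoint_min=frame.timepoint_min))

rates = []
for label, ms in measurements.items():
    series = assemble_series(ms, "control", treatment_time_min=0.0)
    rates.append(estimate_rate(series, model="exponential").rate)
print(f"median k over {len(rates)} cells: {np.median(rates):.4f} / min (truth 0.05)")
```

Output:

```
G-factor: 1.1445   alignment shift (dy, dx): (-1.00, 1.00)
median k over 8 cells: 0.0510 / min (truth 0.05)
```

The estimated G recovers the simulated instrument asymmetry (true G 1.15)
from a single fluorescein frame; the shift is the correction that undoes the
simulated Optosplit misalignment of (+1, −1) px; and the per-cell exponential
fits recover the programmed consumption rate within a few percent. One
cell's mean anisotropy by timepoint shows the expected relaxation from the
monomer-rich baseline toward the dimerized plateau:

```
cell01 mean r by timepoint: [0.3223, 0.3, 0.2824, 0.2687, 0.2589, 0.2508]
```

## Command line

The same stages are exposed as subcommands of a single `anisopipe`
executable, driven by a YAML run configuration:

```sh
anisopipe simulate --config sim.yaml --seed 7 -o data/          # synthetic assay
anisopipe calibrate-g data/fluorescein.tif --rect-para 0,0,128,128 \
          --rect-perp 128,0,128,128 -o gfactor.yaml
anisopipe preprocess in.tif out_para.tif out_perp.tif \
          --rect-para 0,0,128,128 --rect-perp 128,0,128,128 --radius 100
anisopipe anisotropy out_para.tif out_perp.tif --g gfactor.yaml \
          --threshold 50 -o rmap.tif,itotal.tif,mask.tif
anisopipe run run_config.yaml                                    # full pipeline
```

`run` writes a tidy `series.csv` (per ROI and timepoint), `rates.csv` (per
ROI) and a `qc.json` recording the G estimate, the registration shift, the
masked-pixel fraction per frame and per-ROI valid-pixel counts. Exit codes:
0 success, 2 configuration error, 3 data-quality failure.

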