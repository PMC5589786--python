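# gradientchip

Desk-scale reimplementation of the analysis behind a shear-stress-free
microfluidic gradient generator for single-cell image cytometry: a
source–sink diffusion model of a five-chamber culture device, a synthetic
two-channel microscope emulator with known ground truth, and the image
analysis chain that maps each tracked cell to a time-averaged drug exposure
and quantifies concentration-dependent changes in cell area and
eccentricity.

**Who it is for.** Anyone who wants to prototype or validate gradient-chip
image-cytometry pipelines without a cleanroom or a microscope: the device
physics (gradient shape and equilibration time, laminar side channels,
shear-free chamber) is simulated from the printed device dimensions, and
the cell-biology readout is emulated by a generator whose dose–response law
is known exactly, so every stage of the analysis can be tested against
ground truth.

## The model

**Device.** The culture chamber is an elongated hexagon (3.78 mm along the
side channels, gradient-axis width tapering 1.65 → 1.32 mm, height
37.5 μm) flanked by two perfusion channels (200 × 150 μm, 8 μl/h) and
connected to them by arrays of high-resistance channels (112.5 × 25 ×
37.5 μm). With balanced side pressures the connector flow is exactly zero
and mass transport in the chamber is purely diffusive:

    ∂c/∂t = D ∇²c,  c = c₀ on the source face,  c = 0 on the sink face,
    zero flux elsewhere,

solved depth-averaged on the rasterized footprint with a 5-point Laplacian
and unconditionally stable implicit stepping. At steady state the profile
is quasi-linear from 100% (source) to 0% (sink) and the settling time
scales as L²/D (~29 min for L = 1.65 mm, D = 4×10⁻¹⁰ m²/s, 5% tolerance).
Side channels obey laminar duct hydrodynamics: v = Q/wh,
Re = ρvD_h/μ ≈ 0.013, wall shear τ = 6μQ/wh² ≈ 3 mPa.

**Cells.** The synthetic microscope renders non-overlapping ellipses
(green channel) over the dye field (red channel, intensity linear in
concentration) with Gaussian PSF, Poisson shot noise, Gaussian read noise,
and Brownian motion. Cell morphology responds to the local concentration
through a Hill occupancy with first-order kinetics:

    A(t) = A₀ · (1 − E_max · H(c) · (1 − e^(−kt))),  H(c) = cⁿ/(cⁿ + EC50ⁿ),

with eccentricity relaxing toward a rounded target with the same kinetics.

**Analysis.** Frames are registered (integer-pixel phase correlation),
segmented (Gaussian smooth → Otsu → hole fill → size filter → watershed
split), measured (area = pixel count; eccentricity from the second central
moments of the pixel set: 0 for a circle, <1 for an ellipse), and linked by
Hungarian assignment on centroid distance. The dye channel is collapsed to
a normalized percent profile per time point; each cell's mean exposure is
the trapezoidal time average of the interpolated concentration at its
tracked positions. Morphology deltas use the convention that positive
values mean shrinking (area) and rounding (eccentricity). Pooled deltas are
binned into box statistics and the threshold-like response is summarized by
a Hill fit (`HillThresholdModel.fit()` → results with bootstrap CIs and a
`summary()` table).

## Worked example

```python
import gradientchip as gc
from gradientchip.config import default_config

cfg = default_config()                     # printed device values, 2 um/px imaging

hyd = gc.channel_hydrodynamics(cfg.perfusion, cfg.geometry, cfg.fluid)
print(f"Re = {hyd.reynolds_number:.4f}, wall shear = {hyd.wall_shear_stress_pa*1e3:.2f} mPa")

t = gc.time_to_steady_state(cfg.geometry, cfg.fluid, cfg.perfusion, 0.05)
print(f"time to steady state (5% of c0): {t/60:.1f} min")

manifest = gc.run_pipeline(cfg, outdir="demo_run")   # full synthetic experiment
```

prints

```
Re = 0.0127, wall shear = 2.96 mPa
time to steady state (5% of c0): 25.2 min
```

— the side channels are deep in the laminar regime (Re ≪ 1) and the
hexagonal chamber equilibrates in ~25 min (the pure 1.65 mm 1D span takes
29.0 min; the tapered ends are faster). The pipeline run writes, under
`demo_run/`, the simulated field (`field.tif/.csv`), the synthetic stacks
(`green.tif`, `red.tif`) with ground truth, per-frame measurements, tracks,
the measured gradient profile, per-cell exposures and deltas, binned box
statistics with figures, and `fit.json` with the recovered dose–response:

```json
{"ec50_ug_ml": 0.972, "emax_eff": 0.369, "hill_n": 2.74,
 "ci_ec50": [0.931, 1.002], "n_cells": 200, "flags": []}
```

The generator's true EC50 is 1.0 μg/ml and true E_max 0.4: the full
image-based pipeline (segmentation noise, tracking, dye-channel exposure
estimation) recovers them within a few percent. The same stages are
available from the shell:

```bash
gradientchip run --seed 1 --outdir demo_run
gradientchip synth --mode well --c-uniform 2.0 --n-cells 100 --outdir well_run
gradientchip simulate-gradient --tolerance 0.05 --outdir gradient_out
```

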