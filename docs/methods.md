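# Methods

## Chamber footprint and the diffusion model

The culture chamber's printed base, "3.78 × 1.65–1.32 mm²", is interpreted
as an elongated hexagon: a 3.78 × 1.32 mm rectangle spanning the full
length along the side-channel axis, with a shallow triangular bulge on each
channel-facing side so the gradient-axis width grows from 1.32 mm at the
two ends to 1.65 mm at the centerline. The exact vertex coordinates are not
published; this is the simplest hexagon consistent with a chamber that
contacts both side channels along its long sides, and its shoelace area
(5.613 mm²) is the reference the rasterized mask is validated against
(within 2% at the default 10 μm grid). The footprint is rasterized
cell-centered; a configuration with fewer than 50 cells across the gradient
axis is rejected as too coarse.

Inside the chamber only diffusion acts (the connector arrays decouple the
chamber from the side-channel flow), so the model is the depth-averaged
heat equation ∂c/∂t = D∇²c with Dirichlet faces — the per-row first and
last footprint cells are held at c₀ (source) and 0 (sink) — and zero-flux
walls elsewhere. The side channels are treated as perfect reservoirs
(at 8 μl/h their residence time is seconds against a ~30 min diffusion
time) and the connectors' internal diffusion delay is neglected (their
112.5 μm length is <7% of the gradient span). Convection inside the
chamber is not modeled; under pressure imbalance only the net connector
flow magnitude is reported, from the rectangular-duct resistance
R = 12μL/(wh³(1 − 0.63·h/w)) with the per-side array in parallel.

**Numerics.** 5-point Laplacian; θ-scheme in time. The default is backward
Euler (θ = 1): it is unconditionally stable *and* L-stable, which matters
because the zero initial condition meets the source face as a sharp
boundary layer, and Crank–Nicolson (θ = 0.5, also available) rings against
it at practical step sizes (grid Fourier number D·dt/h² ≈ 28 at the
default dt = τ/100, τ = L²/π²D). An explicit option exists for
cross-checks and is gated by the CFL bound dt ≤ h²/(4D), violation raising
an error that names the bound. The steady state is obtained by a direct
sparse Laplace solve. Snapshots are clipped to [0, c₀] (discretization can
under/overshoot at machine precision); the solver is verified against the
independent Fourier-series solution of the 1D problem to <2% of c₀, with
the series evaluated on the discrete span (the Dirichlet values sit at the
first/last cell centers, so the effective 10 μm-grid span is 1.64 mm).

The equilibration time is the first time max|c − c_steady| < tol·c₀,
integrated at dt = τ/100 with log-linear interpolation of the crossing
(the deviation decays exponentially at late times). For the 1.65 mm span
and D = 4×10⁻¹⁰ m²/s it is 29.0 min (analytic: (L²/π²D)·ln((2/π)/0.05) =
29.2 min); on the full hexagon it is 25.2 min, because the tapered ends
have a shorter source–sink path. The dye's diffusion coefficient is not a
published number; the default 4×10⁻¹⁰ m²/s is typical for a ~1 kDa organic
dye in water and reproduces the device's ~30 min equilibration. It is a
configuration parameter, and the product (equilibration time × D) is
verified constant across a 4× range of D.

## Synthetic microscope

The generator emulates what the real acquisition produces — two-channel
grayscale time-lapse stacks at 0, 5, 30, 45 and 60 min — with exactly
known per-cell ground truth. Cells are rigid ellipses (area and
eccentricity fully parameterize shape, which is all the analysis measures)
placed without overlap by rejection sampling; defaults are semi-major axes
14–22 μm and axis ratios 0.5–0.9, typical of adherent osteosarcoma-like
cells, at 200 cells per chamber (hundreds per chamber, as the device
supports). Motion is Brownian with σ = 2 μm per 15 min, concentration
independent. Rendering: anti-aliased ellipse coverage at constant emission
density (green); dye field scaled linearly to counts (red); Gaussian PSF
(σ = 1 px); Poisson shot noise × gain + 100-count background + Gaussian
read noise (σ = 2). An optional global stage drift per frame exercises
registration. Tile stitching, photobleaching, division and detachment are
not emulated, so passing tests say nothing about stitching artifacts or
long-horizon imaging; they do exercise realistic shot noise, PSF blur,
motion, and segmentation/tracking error propagation.

The dose–response law is a modeling choice (the underlying biology is only
known to be threshold-like and fast): Hill occupancy H(c) = cⁿ/(cⁿ+EC50ⁿ)
with first-order approach to the asymptote, A(t) = A₀(1 − E_max·H·(1 −
e^(−kt))), eccentricity relaxing toward a rounded target with the same
kinetics. Defaults E_max = 0.4, EC50 = 1 μg/ml (mid-range of the 0–5 μg/ml
gradient), n = 2, k = 0.5/min — the rate puts >60% of the asymptotic
response within 2 min, matching the microplate observation that the effect
is already visible at the earliest imaged time.

In gradient mode the default dye field is the *pre-equilibrated* steady
profile (baseline imaged after the ~30 min equilibration); setting
`gradient_time_offset_s = 0` instead starts imaging while the gradient
forms, as in the original acquisition. The pre-equilibrated default is the
regime the per-cell mean-exposure correction is designed for, and makes
the end-to-end parameter-recovery check well-posed (each cell's exposure
is stationary up to its Brownian motion). Imaging defaults to 0.65 μm/px
(a 20× objective); the shipped pipeline profile renders whole chambers at
2 μm/px (825 × 1890 px), which keeps multi-replicate runs fast while
leaving ~8 px across a typical cell diameter — ample for pixel-count area
and moment eccentricity.

## Image analysis

Registration is integer-pixel phase correlation (plain cross-correlation
normalization, which is more robust to noise on smooth cell images than
whitened phase weighting); sub-pixel alignment would not change pixel-count
metrics. Segmentation is Gaussian smooth (σ = 1 px) → global Otsu → hole
fill → removal of objects < 30 px → optional watershed split on the
distance transform (peak separation 7 px); all parameters config-exposed,
since the original workflow delegates this to external software without
published settings. A blank frame yields zero objects, not an error.
Measurements: area = pixel count; eccentricity from the equivalent-ellipse
second-moment definition (0 circle → <1 elongated), which is
scale-invariant to <0.03 between a shape and its 2× rasterization.
Tracking is frame-to-frame Hungarian assignment on centroid distance with
links beyond 25 px forbidden; no gap closing or division handling — broken
tracks are flagged truncated and excluded from delta statistics by default.

The dye profile is the per-column masked mean, median filtered (5 bins),
normalized to percent between reference strips (the 5% of columns nearest
each face), clipped to [−10, 110]%. The outermost 2 pixel columns at each
face are discarded first: PSF bleed across the chamber wall depresses
them, and with the trim the measured profile reproduces the simulated one
to <5 percentage points per bin. Per-cell exposure interpolates the
profile at the cell's tracked gradient-axis position at each imaged time
and averages by trapezoid — with the default 5-point schedule this is
within 10% of dense quadrature for smooth exposure histories.

## Dose–response summaries

Deltas follow the sign convention positive = shrinking (fractional area)
and positive = rounding (eccentricity; absolute difference by default,
fractional switchable — the published normalization is ambiguous for
eccentricity). Chambers are analyzed independently and pooled on per-cell
mean exposure, which absorbs inter-chamber profile differences; pooling a
single chamber reproduces that chamber's summary exactly. Binned summaries
are box statistics (median, quartiles, 1.5·IQR whiskers, n) over 5 equal
bins spanning [0, c₀]; a Kendall-tau monotonic-trend statistic per time
point is reported descriptively, never asserted. The Hill threshold fit
(delta = E_max_eff·H(c)) runs a coarse grid over EC50 (log-spaced across
the observed range) and n ∈ [0.5, 4] with E_max_eff solved in closed form,
then local least-squares refinement; uncertainty is a cell-resampling
bootstrap (200 reps, seeded, percentile CIs). Fits at the concentration
range boundary are flagged extrapolated; an all-zero response is flagged
degenerate rather than raising. The requirement of ≥20 cells spanning ≥3
exposure levels guards against unidentifiable designs.

## Problem sizes and determinism

Default verification runs use: 10 μm solver grids (62k unknowns on the
hexagon), 200-cell chambers at 2 μm/px for segmentation/tracking checks,
and 20 independent 500-cell full-pipeline replicates for the EC50-recovery
property (recovery within ±25% required in ≥90% of replicates; typical
errors are a few percent). All randomness flows from one integer seed
through named per-stage substreams (cells / motion / noise), so identical
configurations reproduce stacks and tables bit-for-bit; no stage reads OS
entropy. Every CSV carries a header with units in the column names; the
run manifest records the config hash, seed, package version and per-stage
outputs, and is written atomically.

## Known limitations

- The hexagon vertex coordinates and the connector count per side (default
  20) are decisions, not published values; both are configurable.
- The diffusion solver is 2D depth-averaged; vertical gradients across the
  37.5 μm height and transport inside the side channels are out of scope.
- The response law is quasi-static in concentration (the instantaneous
  local concentration drives the kinetics), with no memory of the exposure
  path beyond what the first-order kinetics impose.
- Segmentation assumes well-separated, convex, uniformly stained cells;
  confluent cultures or protrusive morphologies would need a different
  operator chain.
- Configuration sections are optional (defaults fill in); only unknown
  keys are rejected. A deployment that requires every section spelled out
  should validate separately.
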