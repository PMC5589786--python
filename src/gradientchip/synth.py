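"""Synthetic two-channel time-lapse generator with known ground truth.

Stands in for the microscope: ellipsoidal fluorescent cells (green channel)
over a diffusing dye gradient (red channel), with Gaussian PSF blur,
Poisson shot noise and Gaussian read noise, Brownian cell motion, and a
concentration- and time-dependent morphology response.  The response is a
Hill occupancy in concentration combined with first-order kinetics in time:

    A(t) = A0 · (1 − emax · H(c) · (1 − e^(−k t))),   H(c) = cⁿ/(cⁿ + EC50ⁿ)

and eccentricity relaxes from its baseline toward ``ecc_target`` with the
same kinetics.  Two acquisition modes are provided: ``gradient`` (cells over
the chamber gradient) and ``well`` (uniform concentration, emulating a
microplate dose series).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .device import ChamberMask, DeviceGeometry, FluidProperties, PerfusionConfig, build_chamber_mask
from .errors import ConfigurationError, DensityError
from .gradient import ConcentrationField, simulate_gradient, steady_state


@dataclass(frozen=True)
class DoseResponseParams:
    """Ground-truth dose-response law of the simulated cells."""

    emax: float = 0.4
    ec50_ug_ml: float = 1.0
    hill_n: float = 2.0
    rate_k_per_min: float = 0.5
    ecc_target: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ConfigurationError("emax must be in [0, 1]")
        if self.ec50_ug_ml <= 0 or self.hill_n <= 0:
            raise ConfigurationError("ec50 and hill_n must be > 0")
        if self.rate_k_per_min < 0:
            raise ConfigurationError("rate_k_per_min must be >= 0")
        if not 0.0 <= self.ecc_target <= 1.0:
            raise ConfigurationError("ecc_target must be in [0, 1]")

    def occupancy(self, c_ug_ml: float) -> float:
        c = max(float(c_ug_ml), 0.0)
        if c == 0.0:
            return 0.0
        cn = c**self.hill_n
        return cn / (cn + self.ec50_ug_ml**self.hill_n)


@dataclass
class CellState:
    """A rigid-ellipse cell: position, semi-axes, orientation."""

    track_id: int
    x_um: float
    y_um: float
    a_um: float
    b_um: float
    orientation_rad: float
    baseline_area_um2: float

    def __post_init__(self) -> None:
        if not self.a_um >= self.b_um > 0:
            raise ConfigurationError("semi-axes must satisfy a >= b > 0")

    @property
    def area_um2(self) -> float:
        return math.pi * self.a_um * self.b_um

    @property
    def eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.b_um / self.a_um) ** 2)


@dataclass(frozen=True)
class ImagingConfig:
    """Virtual-microscope settings.

    ``pixel_size_um`` defaults to 0.65 μm/px (a 20× objective); coarser
    sampling is routinely used for whole-chamber synthetic runs.  Photon
    counts are Poisson-distributed, multiplied by ``poisson_gain`` and
    offset by ``background_level`` plus Gaussian read noise.
    """

    pixel_size_um: float = 0.65
    pad_px: int = 10
    time_points_min: tuple = (0.0, 5.0, 30.0, 45.0, 60.0)
    background_level: float = 100.0
    psf_sigma_px: float = 1.0
    poisson_gain: float = 1.0
    read_noise_sigma: float = 2.0
    cell_photon_density: float = 150.0
    dye_photon_scale: float = 400.0
    shot_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        tp = tuple(float(t) for t in self.time_points_min)
        if len(tp) == 0 or tp[0] != 0.0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("time_points_min must start at 0 and be strictly increasing")

    def frame_shape(self, chamber: ChamberMask) -> tuple[int, int]:
        """(height, width) in px covering the chamber bounding box plus padding."""
        w_um = chamber.x_um[-1] + chamber.spacing_um / 2
        l_um = chamber.y_um[-1] + chamber.spacing_um / 2
        return (
            int(math.ceil(l_um / self.pixel_size_um)) + 2 * self.pad_px,
            int(math.ceil(w_um / self.pixel_size_um)) + 2 * self.pad_px,
        )

    def um_to_px(self, coord_um):
        """Chamber μm coordinate -> continuous pixel coordinate (center = int)."""
        return np.asarray(coord_um, float) / self.pixel_size_um + self.pad_px - 0.5

    def px_to_um(self, coord_px):
        return (np.asarray(coord_px, float) - self.pad_px + 0.5) * self.pixel_size_um


@dataclass
class SimulatedDataset:
    """Two-channel stack plus per-cell ground truth and the config echo."""

    green: np.ndarray  # (n_t, H, W) uint16
    red: np.ndarray
    ground_truth: pd.DataFrame
    chamber: ChamberMask
    imaging: ImagingConfig
    config: dict = field(default_factory=dict)

    def save(self, outdir) -> dict:
        """Write green/red TIFF stacks, ground-truth CSV and config JSON."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "green": outdir / "green.tif",
            "red": outdir / "red.tif",
            "ground_truth": outdir / "ground_truth.csv",
            "config": outdir / "config.json",
        }
        tifffile.imwrite(paths["green"], self.green, photometric="minisblack")
        tifffile.imwrite(paths["red"], self.red, photometric="minisblack")
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        paths["config"].write_text(json.dumps(self.config, indent=2, default=float))
        return {k: str(v) for k, v in paths.items()}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream so every stage draws from an independent generator."""
    import zlib

    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]))


def sample_cells(
    n: int,
    chamber: ChamberMask,
    rng: np.random.Generator,
    *,
    a_range_um: tuple[float, float] = (14.0, 22.0),
    axis_ratio_range: tuple[float, float] = (0.5, 0.9),
    margin_um: float = 5.0,
    max_attempts_per_cell: int = 200,
) -> list[CellState]:
    """Place ``n`` non-overlapping ellipses inside the footprint.

    Rejection sampling on bounding circles (radius = semi-major axis); fails
    with :class:`DensityError` once the retry budget is exhausted.
    Deterministic for a given generator state.
    """
    if n == 0:
        return []
    ny, nx = chamber.shape
    h = chamber.spacing_um

    def inside(x: float, y: float, r: float) -> bool:
        for ang in np.linspace(0.0, 2 * math.pi, 8, endpoint=False):
            px, py = x + r * math.cos(ang), y + r * math.sin(ang)
            ix, iy = int(px / h - 0.5 + 0.5), int(py / h - 0.5 + 0.5)
            if not (0 <= ix < nx and 0 <= iy < ny) or not chamber.mask[iy, ix]:
                return False
        return True

    xmax = chamber.x_um[-1] + h / 2
    ymax = chamber.y_um[-1] + h / 2
    cells: list[CellState] = []
    xs = np.empty(n)
    ys = np.empty(n)
    radii = np.empty(n)
    attempts = 0
    budget = max_attempts_per_cell * n
    while len(cells) < n:
        if attempts >= budget:
            raise DensityError(
                f"placed {len(cells)}/{n} cells in {budget} attempts; lower n or the margin"
            )
        attempts += 1
        a = rng.uniform(*a_range_um)
        b = a * rng.uniform(*axis_ratio_range)
        x = rng.uniform(0.0, xmax)
        y = rng.uniform(0.0, ymax)
        if not inside(x, y, a + margin_um):
            continue
        k = len(cells)
        if k and np.any(np.hypot(xs[:k] - x, ys[:k] - y) <= radii[:k] + a):
            continue
        xs[k], ys[k], radii[k] = x, y, a
        cells.append(
            CellState(
                track_id=k,
                x_um=x,
                y_um=y,
                a_um=a,
                b_um=b,
                orientation_rad=rng.uniform(0.0, math.pi),
                baseline_area_um2=math.pi * a * b,
            )
        )
    return cells


def cell_response(
    c_local_ug_ml: float,
    t_min: float,
    params: DoseResponseParams,
    state0: CellState,
) -> CellState:
    """State of a cell after ``t_min`` minutes at local concentration ``c``.

    Area shrinks by emax·H(c)·(1 − e^(−kt)) of baseline; eccentricity moves
    toward ``ecc_target`` with the same factor.  Semi-axes are rescaled so
    area and eccentricity stay jointly consistent.
    """
    if t_min < 0 or c_local_ug_ml < 0:
        raise ConfigurationError("t and c must be >= 0")
    h = params.occupancy(c_local_ug_ml)
    g = 1.0 - math.exp(-params.rate_k_per_min * t_min) if params.rate_k_per_min > 0 else 0.0
    f = h * g
    area = state0.baseline_area_um2 * (1.0 - params.emax * f)
    e0 = state0.eccentricity
    ecc = e0 + (params.ecc_target - e0) * f
    ratio = math.sqrt(max(1.0 - ecc**2, 1e-12))  # b/a
    a = math.sqrt(area / (math.pi * ratio))
    return CellState(
        track_id=state0.track_id,
        x_um=state0.x_um,
        y_um=state0.y_um,
        a_um=a,
        b_um=a * ratio,
        orientation_rad=state0.orientation_rad,
        baseline_area_um2=state0.baseline_area_um2,
    )


def _add_ellipse(img: np.ndarray, xc: float, yc: float, a: float, b: float, theta: float, density: float, supersample: int = 3) -> None:
    """Accumulate an anti-aliased filled ellipse (all units in px)."""
    hgt, wid = img.shape
    r = a + 1.0
    x0, x1 = max(int(math.floor(xc - r)), 0), min(int(math.ceil(xc + r)) + 1, wid)
    y0, y1 = max(int(math.floor(yc - r)), 0), min(int(math.ceil(yc + r)) + 1, hgt)
    if x0 >= x1 or y0 >= y1:
        return
    ss = supersample
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    px = (np.arange(x0, x1)[:, None] + sub[None, :]).ravel()
    py = (np.arange(y0, y1)[:, None] + sub[None, :]).ravel()
    dx = px[None, :] - xc
    dy = py[:, None] - yc
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cov = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    img[y0:y1, x0:x1] += density * cov


def _apply_noise(photons: np.ndarray, config: ImagingConfig, rng: np.random.Generator) -> np.ndarray:
    if config.shot_noise:
        signal = rng.poisson(np.maximum(photons, 0.0)).astype(float) * config.poisson_gain
    else:
        signal = photons * config.poisson_gain
    out = signal + config.background_level
    if config.read_noise_sigma > 0:
        out = out + rng.normal(0.0, config.read_noise_sigma, photons.shape)
    return out


def render_frame(
    states: list[CellState],
    dye_snapshot,
    config: ImagingConfig,
    chamber: ChamberMask,
    rng: np.random.Generator | None = None,
    *,
    drift_px: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Render one (green, red) frame pair as float count images.

    ``dye_snapshot`` is a concentration grid over the chamber footprint
    (μg/ml, NaN outside) or a scalar for a uniform bath.  Red intensity is
    linear in concentration (``dye_photon_scale`` counts per μg/ml).
    ``drift_px`` shifts the whole scene (both channels), emulating stage
    drift between acquisitions.
    """
    if rng is None:
        rng = _rng(config.rng_seed, "render")
    shape = config.frame_shape(chamber)
    green = np.zeros(shape)
    s = config.pixel_size_um
    ddx, ddy = drift_px
    for cell in states:
        _add_ellipse(
            green,
            float(config.um_to_px(cell.x_um)) + ddx,
            float(config.um_to_px(cell.y_um)) + ddy,
            cell.a_um / s,
            cell.b_um / s,
            cell.orientation_rad,
            config.cell_photon_density,
        )

    cols = np.arange(shape[1], dtype=float)
    rows = np.arange(shape[0], dtype=float)
    x_um = config.px_to_um(cols - ddx)
    y_um = config.px_to_um(rows - ddy)
    if np.isscalar(dye_snapshot):
        h = chamber.spacing_um
        ny, nx = chamber.shape
        ix = np.clip(np.round(x_um / h - 0.5).astype(int), 0, nx - 1)
        iy = np.clip(np.round(y_um / h - 0.5).astype(int), 0, ny - 1)
        in_chamber = chamber.mask[iy[:, None], ix[None, :]]
        conc = np.where(in_chamber, float(dye_snapshot), 0.0)
    else:
        grid = np.nan_to_num(np.asarray(dye_snapshot, float), nan=0.0)
        h = chamber.spacing_um
        ny, nx = chamber.shape
        ix = np.clip(np.round(x_um / h - 0.5).astype(int), 0, nx - 1)
        iy = np.clip(np.round(y_um / h - 0.5).astype(int), 0, ny - 1)
        inb = (x_um >= 0) & (x_um <= nx * h)
        conc = grid[iy[:, None], ix[None, :]] * inb[None, :]
        inby = (y_um >= 0) & (y_um <= ny * h)
        conc = conc * inby[:, None]
    red = config.dye_photon_scale * conc

    if config.psf_sigma_px > 0:
        green = ndimage.gaussian_filter(green, config.psf_sigma_px)
        red = ndimage.gaussian_filter(red, config.psf_sigma_px)
    return _apply_noise(green, config, rng), _apply_noise(red, config, rng)


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_dataset(
    geometry: DeviceGeometry,
    fluid: FluidProperties,
    perfusion: PerfusionConfig,
    dose_params: DoseResponseParams,
    imaging: ImagingConfig,
    mode: str = "gradient",
    *,
    n_cells: int = 200,
    c_uniform_ug_ml: float | None = None,
    sigma_step_um_per_15min: float = 2.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    gradient_time_offset_s: float | None = None,
    seed: int | None = None,
    field: ConcentrationField | None = None,
    chamber: ChamberMask | None = None,
) -> SimulatedDataset:
    """Generate a full two-channel time-lapse with ground truth.

    In ``gradient`` mode the dye field comes from the diffusion model; by
    default it is the pre-equilibrated steady profile (baseline imaging
    after the ~30 min equilibration), while ``gradient_time_offset_s``
    starts the clock at an arbitrary point of the transient (0 emulates
    imaging while the gradient forms).  In ``well`` mode the bath is
    uniform at ``c_uniform_ug_ml``.  Everything is reproducible from
    ``seed``.
    """
    if seed is None:
        seed = imaging.rng_seed
    if chamber is None:
        chamber = build_chamber_mask(geometry)
    times = np.asarray(imaging.time_points_min, float)

    if mode == "gradient":
        if field is None:
            if gradient_time_offset_s is None:
                field = steady_state(geometry, fluid, perfusion, chamber=chamber)
                time_index = {t: 0 for t in times}
            else:
                sim_times = gradient_time_offset_s + times * 60.0
                field = simulate_gradient(
                    geometry, fluid, perfusion, sim_times, chamber=chamber
                )
                time_index = {t: i for i, t in enumerate(times)}
        else:
            if field.times_s.size == 1:
                time_index = {t: 0 for t in times}
            elif field.times_s.size == times.size:
                time_index = {t: i for i, t in enumerate(times)}
            else:
                raise ConfigurationError(
                    "precomputed field must have 1 snapshot or one per time point"
                )
    elif mode == "well":
        if c_uniform_ug_ml is None:
            raise ConfigurationError("well mode requires c_uniform_ug_ml")
        field = None
        time_index = {}
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    rng_cells = _rng(seed, "cells")
    rng_motion = _rng(seed, "motion")
    rng_noise = _rng(seed, "noise")
    cells = sample_cells(n_cells, chamber, rng_cells)

    x = np.array([c.x_um for c in cells])
    y = np.array([c.y_um for c in cells])
    h = chamber.spacing_um
    ny, nx = chamber.shape

    def in_mask(xv, yv):
        ix = np.clip(np.round(xv / h - 0.5).astype(int), 0, nx - 1)
        iy = np.clip(np.round(yv / h - 0.5).astype(int), 0, ny - 1)
        return chamber.mask[iy, ix] & (xv >= 0) & (yv >= 0)

    green_pages, red_pages, rows = [], [], []
    for i, t in enumerate(times):
        if i > 0 and n_cells > 0:
            dt = times[i] - times[i - 1]
            sigma = sigma_step_um_per_15min * math.sqrt(dt / 15.0)
            step = rng_motion.normal(0.0, sigma, size=(2, n_cells))
            x_new, y_new = x + step[0], y + step[1]
            ok = in_mask(x_new, y_new)
            x = np.where(ok, x_new, x)
            y = np.where(ok, y_new, y)

        if mode == "gradient":
            local_c = field.sample(x, y, time_index[t]) if n_cells else np.empty(0)
            dye = field.conc[time_index[t]]
        else:
            local_c = np.full(n_cells, float(c_uniform_ug_ml))
            dye = float(c_uniform_ug_ml)

        frame_states = []
        for j, cell in enumerate(cells):
            moved = dataclasses.replace(cell, x_um=float(x[j]), y_um=float(y[j]))
            responded = cell_response(float(local_c[j]), float(t), dose_params, moved)
            frame_states.append(responded)
            rows.append(
                {
                    "track_id": cell.track_id,
                    "time_min": float(t),
                    "x_um": float(x[j]),
                    "y_um": float(y[j]),
                    "area_um2": responded.area_um2,
                    "eccentricity": responded.eccentricity,
                    "local_conc_ug_ml": float(local_c[j]),
                }
            )

        drift = (drift_px_per_frame[0] * i, drift_px_per_frame[1] * i)
        g_img, r_img = render_frame(
            frame_states, dye, imaging, chamber, rng_noise, drift_px=drift
        )
        green_pages.append(_quantize(g_img))
        red_pages.append(_quantize(r_img))

    config_echo = {
        "mode": mode,
        "n_cells": n_cells,
        "seed": int(seed),
        "c_uniform_ug_ml": c_uniform_ug_ml,
        "sigma_step_um_per_15min": sigma_step_um_per_15min,
        "drift_px_per_frame": list(drift_px_per_frame),
        "gradient_time_offset_s": gradient_time_offset_s,
        "source_concentration_ug_ml": perfusion.source_concentration_ug_ml,
        "imaging": dataclasses.asdict(imaging),
    }
    return SimulatedDataset(
        green=np.stack(green_pages) if green_pages else np.empty((0, 0, 0), np.uint16),
        red=np.stack(red_pages) if red_pages else np.empty((0, 0, 0), np.uint16),
        ground_truth=pd.DataFrame(rows),
        chamber=chamber,
        imaging=imaging,
        config=config_echo,
    )


def footprint_mask_px(chamber: ChamberMask, imaging: ImagingConfig) -> np.ndarray:
    """Chamber footprint rasterized onto the imaging pixel grid."""
    shape = imaging.frame_shape(chamber)
    h = chamber.spacing_um
    ny, nx = chamber.shape
    x_um = imaging.px_to_um(np.arange(shape[1], dtype=float))
    y_um = imaging.px_to_um(np.arange(shape[0], dtype=float))
    ix = np.clip(np.round(x_um / h - 0.5).astype(int), 0, nx - 1)
    iy = np.clip(np.round(y_um / h - 0.5).astype(int), 0, ny - 1)
    m = chamber.mask[iy[:, None], ix[None, :]]
    m &= (x_um >= 0)[None, :] & (y_um >= 0)[:, None]
    m &= (x_um <= nx * h)[None, :] & (y_um <= ny * h)[:, None]
    return m
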