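import numpy as np
import pytest

import gradientchip as gc
from gradientchip.config import default_config


@pytest.fixture(scope="session")
def fluid():
    return gc.FluidProperties()


@pytest.fixture(scope="session")
def perfusion():
    return gc.PerfusionConfig()


@pytest.fixture(scope="session")
def hex_geometry():
    return gc.DeviceGeometry()


@pytest.fixture(scope="session")
def hex_chamber(hex_geometry):
    return gc.build_chamber_mask(hex_geometry)


@pytest.fixture(scope="session")
def rect_geometry():
    """Degenerate (rectangular) footprint spanning the full 1.65 mm gradient
    axis; short along the channel axis so 2D solves behave as 1D rows."""
    return gc.DeviceGeometry(
        chamber_length_mm=0.4, chamber_width_min_mm=1.65, chamber_width_max_mm=1.65
    )


@pytest.fixture(scope="session")
def small_geometry():
    """A small square footprint for fast imaging tests (60 x 60 grid cells)."""
    return gc.DeviceGeometry(
        chamber_length_mm=0.6, chamber_width_min_mm=0.6, chamber_width_max_mm=0.6
    )


@pytest.fixture(scope="session")
def small_chamber(small_geometry):
    return gc.build_chamber_mask(small_geometry)


@pytest.fixture(scope="session")
def clean_imaging():
    """Noise-free imaging at 1 μm/px with no PSF: rasterization oracles."""
    return gc.ImagingConfig(
        pixel_size_um=1.0, psf_sigma_px=0.0, shot_noise=False, read_noise_sigma=0.0
    )


@pytest.fixture(scope="session")
def default_pipeline_config():
    return default_config()


@pytest.fixture(scope="session")
def steady_field(hex_geometry, fluid, perfusion, hex_chamber):
    return gc.steady_state(hex_geometry, fluid, perfusion, chamber=hex_chamber)


@pytest.fixture(scope="session")
def default_dataset(default_pipeline_config, hex_chamber, steady_field):
    """The default synthetic gradient dataset: 200 cells, default noise."""
    cfg = default_pipeline_config
    return gc.generate_dataset(
        cfg.geometry,
        cfg.fluid,
        cfg.perfusion,
        cfg.dose_response,
        cfg.imaging,
        mode="gradient",
        n_cells=200,
        seed=7,
        field=steady_field,
        chamber=hex_chamber,
    )


def linear_r2(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(a, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res[0]) if len(res) else float(np.sum((y - a @ coef) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
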