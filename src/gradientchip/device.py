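"""Device geometry, fluid and perfusion descriptions.

The culture chamber is an elongated hexagon: a rectangle spanning the full
chamber length along the side-channel axis, with two shallow triangular
bulges on the channel-facing sides, so the gradient-axis width tapers from
``chamber_width_max`` at the centerline down to ``chamber_width_min`` at the
two ends.  The gradient axis is x (x = 0 at the source face, x = L at the
sink face); the side-channel axis is y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ConfigurationError

#: minimum number of grid cells across the gradient axis
MIN_CELLS_ACROSS = 50


@dataclass(frozen=True)
class DeviceGeometry:
    """Printed dimensions of one microfluidic unit.

    Lengths follow the device drawings: chamber footprint in mm, channel and
    connector cross-sections in μm.  Defaults are the fabricated device:
    3.78 × 1.65–1.32 mm² × 37.5 μm chamber, 200 × 150 μm perfusion channels,
    112.5 × 25 × 37.5 μm connector resistors.
    """

    chamber_length_mm: float = 3.78
    chamber_width_max_mm: float = 1.65
    chamber_width_min_mm: float = 1.32
    chamber_height_um: float = 37.5
    channel_width_um: float = 200.0
    channel_height_um: float = 150.0
    connector_length_um: float = 112.5
    connector_width_um: float = 25.0
    connector_height_um: float = 37.5
    connectors_per_side: int = 20
    grid_spacing_um: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "chamber_length_mm",
            "chamber_width_max_mm",
            "chamber_width_min_mm",
            "chamber_height_um",
            "channel_width_um",
            "channel_height_um",
            "connector_length_um",
            "connector_width_um",
            "connector_height_um",
            "grid_spacing_um",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.connectors_per_side < 1:
            raise ConfigurationError("connectors_per_side must be >= 1")
        if self.chamber_width_min_mm > self.chamber_width_max_mm:
            raise ConfigurationError(
                "chamber_width_min_mm must not exceed chamber_width_max_mm"
            )
        if self.connector_height_um != self.chamber_height_um:
            raise ConfigurationError(
                "connector_height_um must equal chamber_height_um "
                "(connectors are etched in the same layer as the chamber)"
            )

    # -- derived footprint ------------------------------------------------

    def hexagon_vertices_um(self) -> np.ndarray:
        """Vertices (x_um, y_um) of the hexagonal footprint, counterclockwise."""
        w = self.chamber_width_max_mm * 1e3
        wmin = self.chamber_width_min_mm * 1e3
        length = self.chamber_length_mm * 1e3
        taper = 0.5 * (w - wmin)  # bulge depth on each channel-facing side
        return np.array(
            [
                (taper, 0.0),
                (w - taper, 0.0),
                (w, 0.5 * length),
                (w - taper, length),
                (taper, length),
                (0.0, 0.5 * length),
            ]
        )

    def footprint_area_mm2(self) -> float:
        """Closed-form (shoelace) area of the hexagonal footprint, mm²."""
        v = self.hexagon_vertices_um() * 1e-3
        x, y = v[:, 0], v[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass(frozen=True)
class FluidProperties:
    """Carrier fluid and tracked-solute transport properties (SI units).

    The default diffusion coefficient 4.0e-10 m²/s is typical of a ~1 kDa
    organic dye in water and reproduces the device's ~30 min gradient
    equilibration over the 1.65 mm span; it is a parameter, not a constant.
    """

    density_kg_m3: float = 998.0
    dynamic_viscosity_pa_s: float = 1.0e-3
    diffusion_coefficient_m2_s: float = 4.0e-10

    def __post_init__(self) -> None:
        for name in ("density_kg_m3", "dynamic_viscosity_pa_s", "diffusion_coefficient_m2_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class PerfusionConfig:
    """Syringe-pump settings for the two side channels."""

    flow_rate_per_channel_ul_h: float = 8.0
    priming_flow_rate_ul_h: float = 25.0
    source_concentration_ug_ml: float = 5.0
    pressure_imbalance_pa: float = 0.0

    def __post_init__(self) -> None:
        if self.flow_rate_per_channel_ul_h <= 0 or self.priming_flow_rate_ul_h <= 0:
            raise ConfigurationError("flow rates must be > 0")
        if self.source_concentration_ug_ml < 0:
            raise ConfigurationError("source_concentration_ug_ml must be >= 0")


@dataclass
class ChamberMask:
    """Cell-centered boolean footprint grid with flagged boundary faces.

    ``mask[row, col]`` covers the point (x_um[col], y_um[row]); ``source``
    and ``sink`` flag, per row, the first and last in-footprint cell along
    the gradient axis (the faces held at c0 and 0 by the side channels).
    """

    mask: np.ndarray
    source: np.ndarray
    sink: np.ndarray
    spacing_um: float
    x_um: np.ndarray = field(repr=False)
    y_um: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.spacing_um * 1e-3) ** 2

    @property
    def center_row(self) -> int:
        """Row index closest to the chamber centerline (widest section)."""
        return int(np.argmin(np.abs(self.y_um - self.y_um.mean())))


def build_chamber_mask(geometry: DeviceGeometry) -> ChamberMask:
    """Rasterize the hexagonal chamber footprint onto a cell-centered grid.

    Raises
    ------
    ConfigurationError
        If the grid spacing leaves fewer than 50 cells across the gradient
        axis (too coarse for the diffusion solver).
    """
    h = geometry.grid_spacing_um
    w_um = geometry.chamber_width_max_mm * 1e3
    l_um = geometry.chamber_length_mm * 1e3
    nx = int(round(w_um / h))
    ny = int(round(l_um / h))
    if nx < MIN_CELLS_ACROSS:
        raise ConfigurationError(
            f"grid_spacing_um={h} gives {nx} cells across the gradient axis; "
            f"need >= {MIN_CELLS_ACROSS}"
        )
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    xx, yy = np.meshgrid(x, y)
    poly = shapely.Polygon(geometry.hexagon_vertices_um())
    mask = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(ny, nx)

    source = np.zeros_like(mask)
    sink = np.zeros_like(mask)
    for r in range(ny):
        cols = np.flatnonzero(mask[r])
        if cols.size:
            source[r, cols[0]] = True
            sink[r, cols[-1]] = True
    return ChamberMask(mask=mask, source=source, sink=sink, spacing_um=h, x_um=x, y_um=y)
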