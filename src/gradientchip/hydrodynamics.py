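"""Analytic duct hydrodynamics for the side channels and connector resistors.

The side channels run in the laminar, inertia-free regime (Re « 1), so the
mean velocity, Reynolds number and wall shear follow from closed-form
rectangular-duct results.  The connector channels between each side channel
and the chamber act as hydraulic resistors in parallel: with balanced side
pressures no flow crosses them and the chamber sees no shear.
"""

from __future__ import annotations

from dataclasses import dataclass

from .device import DeviceGeometry, FluidProperties, PerfusionConfig

UL_PER_H_TO_M3_PER_S = 1e-9 / 3600.0


@dataclass(frozen=True)
class ChannelHydrodynamics:
    mean_velocity_m_s: float
    reynolds_number: float
    wall_shear_stress_pa: float


def channel_hydrodynamics(
    perfusion: PerfusionConfig,
    geometry: DeviceGeometry,
    fluid: FluidProperties,
) -> ChannelHydrodynamics:
    """Mean velocity, Reynolds number and wall shear in one side channel.

    v = Q / (w·h); Re = ρ v D_h / μ with hydraulic diameter
    D_h = 2wh/(w+h); wall shear uses the wide-slot result τ = 6μQ/(w h²).
    For the fabricated device at 8 μl/h this gives Re ≈ 0.013 and
    τ ≈ 3 mPa.
    """
    q = perfusion.flow_rate_per_channel_ul_h * UL_PER_H_TO_M3_PER_S
    w = geometry.channel_width_um * 1e-6
    h = geometry.channel_height_um * 1e-6
    v = q / (w * h)
    d_h = 2.0 * w * h / (w + h)
    re = fluid.density_kg_m3 * v * d_h / fluid.dynamic_viscosity_pa_s
    tau = 6.0 * fluid.dynamic_viscosity_pa_s * q / (w * h * h)
    return ChannelHydrodynamics(v, re, tau)


def connector_resistance(geometry: DeviceGeometry, fluid: FluidProperties) -> float:
    """Hydraulic resistance of a single connector channel, Pa·s/m³.

    Rectangular-duct approximation R = 12 μ L / (w h³ (1 − 0.63 h/w)) with
    h the smaller cross-section dimension.
    """
    mu = fluid.dynamic_viscosity_pa_s
    length = geometry.connector_length_um * 1e-6
    d1 = geometry.connector_width_um * 1e-6
    d2 = geometry.connector_height_um * 1e-6
    h, w = (d1, d2) if d1 <= d2 else (d2, d1)
    return 12.0 * mu * length / (w * h**3 * (1.0 - 0.63 * h / w))


def connector_flow(
    pressure_imbalance_pa: float,
    geometry: DeviceGeometry,
    fluid: FluidProperties,
) -> float:
    """Net volumetric flow (m³/s) through one side's connector array.

    The array is ``connectors_per_side`` identical resistors in parallel;
    a zero pressure imbalance yields exactly zero flow (the shear-free
    operating point with balanced side channels).
    """
    if pressure_imbalance_pa == 0.0:
        return 0.0
    r_total = connector_resistance(geometry, fluid) / geometry.connectors_per_side
    return pressure_imbalance_pa / r_total
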