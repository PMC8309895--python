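"""Steady-state thermal resistance network for a benchtop skin simulant.

The physical system is a silicone slab (thermal properties close to human
epidermis) heated from below by a temperature-controlled plate and losing
heat to the environment from its upper surface.  A contact skin-temperature
sensor and/or attachment tape placed on the surface adds thermal resistance
above the surface and may also enhance convective exchange by acting as a
fin.  The model resolves two independent one-dimensional columns:

* **undisturbed**: plate -> slab conduction -> surface -> combined
  convective/radiative boundary -> ambient air;
* **disturbed**: plate -> slab conduction -> surface -> contact resistance
  -> sensor node -> top (cover) resistance -> boundary scaled by an area
  factor -> ambient air.

Within the slab the steady-state temperature profile is strictly linear,
so subsurface readings extrapolate exactly to the surface.  The boundary
conductance combines a flat-plate forced-convection correlation
``h_c = a * sqrt(v)`` with radiation linearized at the ambient temperature,
``h_r = 4 * eps * sigma * T_amb**3``; linearizing at a fixed temperature
keeps every node temperature an affine function of the plate-to-ambient
difference, which makes disturbance and bias exactly linear in the
surface-to-environment gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "STEFAN_BOLTZMANN",
    "CONVECTION_COEFF_A",
    "MaterialProps",
    "CoverageSpec",
    "SensorSpec",
    "RigConfig",
    "NodeTemperatures",
    "ValidationError",
    "convective_coefficient",
    "radiative_coefficient",
    "boundary_resistance",
    "solve_thermal_network",
    "default_material",
    "default_coverages",
    "default_sensors",
    "default_plate_setpoints",
    "default_rig_config",
    "COVERAGE_NAMES",
    "COVERAGE_SENSOR",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4

#: Flat-plate forced-convection prefactor in h_c = a * sqrt(v), chosen so
#: that h_c ~= 7 W m^-2 K^-1 at 0.2 m/s and ~= 11 at 0.5 m/s.
CONVECTION_COEFF_A = 7.0 / math.sqrt(0.2)

COVERAGE_NAMES = (
    "custom+tape",
    "grant+tape",
    "ibutton+tape",
    "ibutton_only",
    "tape_only",
    "bare",
)

#: Which sensor type sits on top of the surface for each coverage condition
#: (None when the coverage carries no readable skin-temperature sensor).
COVERAGE_SENSOR = {
    "custom+tape": "custom",
    "grant+tape": "grant",
    "ibutton+tape": "ibutton",
    "ibutton_only": "ibutton",
    "tape_only": None,
    "bare": None,
}


class ValidationError(ValueError):
    """A physically or structurally invalid input."""


@dataclass(frozen=True)
class MaterialProps:
    """Thermal properties of the skin simulant slab.

    Defaults describe a dark-gray PDMS elastomer: conductivity
    ~0.23 W/(m K), diffusivity ~12.8e-8 m^2/s, emissivity ~0.9, density
    ~1350 kg/m^3, cast as a 10 mm slab.
    """

    conductivity: float = 0.23  # W/(m K)
    diffusivity: float = 12.8e-8  # m^2/s
    emissivity: float = 0.9
    density: float = 1350.0  # kg/m^3
    thickness: float = 0.010  # m

    def __post_init__(self) -> None:
        for name in ("conductivity", "diffusivity", "density", "thickness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.emissivity <= 1:
            raise ValidationError("emissivity must be in (0, 1]")


@dataclass(frozen=True)
class CoverageSpec:
    """Surface coverage condition (sensor and/or attachment tape).

    ``contact_resistance`` is the slab-surface-to-sensor interface
    resistance, ``top_resistance`` the resistance from the sensor node
    through any cover (tape, sensor housing) to the outer surface, and
    ``area_factor`` a fin-like convective enhancement (>= 1) of the
    boundary conductance over the covered footprint.
    """

    name: str
    contact_resistance: float = 0.0  # m^2 K / W
    top_resistance: float = 0.0  # m^2 K / W
    area_factor: float = 1.0
    footprint_area: float = 1.75e-3  # m^2 (tape patch)

    def __post_init__(self) -> None:
        if self.name not in COVERAGE_NAMES:
            raise ValidationError(
                f"unknown coverage {self.name!r}; expected one of {COVERAGE_NAMES}"
            )
        if self.contact_resistance < 0 or self.top_resistance < 0:
            raise ValidationError("resistances must be >= 0")
        if self.area_factor < 1.0:
            raise ValidationError("area_factor must be >= 1")
        if self.footprint_area <= 0:
            raise ValidationError("footprint_area must be > 0")
        if self.name == "bare" and (
            self.contact_resistance or self.top_resistance or self.area_factor != 1.0
        ):
            raise ValidationError("bare coverage must have zero added resistance")

    @property
    def has_sensor(self) -> bool:
        return COVERAGE_SENSOR[self.name] is not None


@dataclass(frozen=True)
class SensorSpec:
    """Measurement characteristics of one sensor channel."""

    sensor_type: str  # {custom, grant, ibutton, embedded, hygrometer}
    resolution: float = 0.01  # quantization step, degC
    noise_sd: float = 0.01  # degC
    true_gain: float = 1.0
    true_offset: float = 0.0  # degC
    response_time: float = 20.0  # s

    def __post_init__(self) -> None:
        if self.sensor_type not in {"custom", "grant", "ibutton", "embedded", "hygrometer"}:
            raise ValidationError(f"unknown sensor_type {self.sensor_type!r}")
        if self.resolution < 0:
            raise ValidationError("resolution must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class RigConfig:
    """Environmental and protocol settings for one rig run."""

    ambient_temp: float = 23.8  # degC
    ambient_rh: float = 42.0  # %
    air_velocity: float = 0.5  # m/s
    plate_setpoints: tuple[float, ...] = ()
    step_duration: float = 1800.0  # s
    sample_interval: float = 10.0  # s
    z1: float = 0.00025  # m, primary (reference) embedded sensor depth
    z2: float = 0.005  # m, second embedded sensor depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.air_velocity <= 0:
            raise ValidationError("air_velocity must be > 0")
        if len(self.plate_setpoints) != 5:
            raise ValidationError("exactly 5 plate setpoints required")
        if any(b < a for a, b in zip(self.plate_setpoints, self.plate_setpoints[1:])):
            raise ValidationError("plate setpoints must be nondecreasing")
        if not 0 < self.z1 < self.z2:
            raise ValidationError("require 0 < z1 < z2")
        if self.step_duration % self.sample_interval:
            raise ValidationError("step_duration must be a multiple of sample_interval")

    def validate_geometry(self, material: MaterialProps) -> None:
        if not self.z2 < material.thickness:
            raise ValidationError("z2 must be smaller than the slab thickness")


@dataclass(frozen=True)
class NodeTemperatures:
    """Steady-state solution of the two columns for one plate temperature."""

    surface_disturbed: float
    surface_undisturbed: float
    sensor_node: float
    z1_disturbed: float
    z2_disturbed: float
    z1_undisturbed: float
    z2_undisturbed: float
    flux_disturbed: float  # W/m^2, plate -> ambient through the covered column
    flux_undisturbed: float  # W/m^2


def convective_coefficient(air_velocity: float) -> float:
    """Forced-convection coefficient h_c = a * sqrt(v) in W m^-2 K^-1."""
    if air_velocity <= 0:
        raise ValidationError("air_velocity must be > 0")
    return CONVECTION_COEFF_A * math.sqrt(air_velocity)


def radiative_coefficient(emissivity: float, ambient_temp: float) -> float:
    """Radiation linearized at the ambient temperature: 4*eps*sigma*T^3."""
    t_k = ambient_temp + 273.15
    return 4.0 * emissivity * STEFAN_BOLTZMANN * t_k**3


def boundary_resistance(material: MaterialProps, config: RigConfig) -> float:
    """Surface-to-ambient resistance 1/(h_c + h_r) for a bare surface."""
    h = convective_coefficient(config.air_velocity) + radiative_coefficient(
        material.emissivity, config.ambient_temp
    )
    return 1.0 / h


def solve_thermal_network(
    material: MaterialProps,
    coverage: CoverageSpec,
    config: RigConfig,
    plate_temp: float,
) -> NodeTemperatures:
    """Solve both 1-D columns for one plate temperature.

    Returns steady-state node temperatures; with ``plate_temp`` equal to
    the ambient temperature every node equals ambient and both fluxes are
    zero.  Flux conservation holds exactly by construction (series
    resistances carry a single flux).
    """
    if not math.isfinite(plate_temp):
        raise ValidationError("plate_temp must be finite")
    config.validate_geometry(material)

    t_a = config.ambient_temp
    r_slab = material.thickness / material.conductivity
    r_bnd = boundary_resistance(material, config)
    dt = plate_temp - t_a

    # Undisturbed column.
    q_u = dt / (r_slab + r_bnd)
    surf_u = t_a + q_u * r_bnd

    # Disturbed column: contact + top resistances in series with the
    # area-factor-enhanced boundary.
    r_above = coverage.contact_resistance + coverage.top_resistance + r_bnd / coverage.area_factor
    q_d = dt / (r_slab + r_above)
    surf_d = t_a + q_d * r_above
    sensor = t_a + q_d * (coverage.top_resistance + r_bnd / coverage.area_factor)

    def in_slab(surface: float, q: float, z: float) -> float:
        # Linear profile: temperature rises toward the plate side.
        return surface + q * z / material.conductivity

    return NodeTemperatures(
        surface_disturbed=surf_d,
        surface_undisturbed=surf_u,
        sensor_node=sensor,
        z1_disturbed=in_slab(surf_d, q_d, config.z1),
        z2_disturbed=in_slab(surf_d, q_d, config.z2),
        z1_undisturbed=in_slab(surf_u, q_u, config.z1),
        z2_undisturbed=in_slab(surf_u, q_u, config.z2),
        flux_disturbed=q_d,
        flux_undisturbed=q_u,
    )


def default_material() -> MaterialProps:
    return MaterialProps()


def default_coverages() -> dict[str, CoverageSpec]:
    """Coverage parameter defaults for the six surface conditions.

    Values were chosen so the steady-state disturbance signs reproduce the
    observed phenomenology: tape alone and the silicone-encapsulated custom
    thermistor insulate the surface (warming); the bare metal-bodied
    iButton and the Grant thermistor act as fins (cooling); the taped
    iButton warms at 0.5 m/s but cools at 0.2 m/s.
    """
    return {
        "custom+tape": CoverageSpec(
            "custom+tape", contact_resistance=0.003, top_resistance=0.001,
            area_factor=1.0, footprint_area=1.5e-3,
        ),
        "grant+tape": CoverageSpec(
            "grant+tape", contact_resistance=0.012, top_resistance=0.004,
            area_factor=1.6, footprint_area=1.5e-3,
        ),
        "ibutton+tape": CoverageSpec(
            "ibutton+tape", contact_resistance=0.012, top_resistance=0.004,
            area_factor=1.3, footprint_area=1.75e-3,
        ),
        "ibutton_only": CoverageSpec(
            "ibutton_only", contact_resistance=0.012, top_resistance=0.002,
            area_factor=1.7, footprint_area=2.3e-4,
        ),
        "tape_only": CoverageSpec(
            "tape_only", contact_resistance=0.001, top_resistance=0.002,
            area_factor=1.0, footprint_area=1.25e-3,
        ),
        "bare": CoverageSpec("bare"),
    }


def default_sensors() -> dict[str, SensorSpec]:
    """Measurement models for the sensor families used on the rig."""
    return {
        "custom": SensorSpec("custom", resolution=0.01, noise_sd=0.010, response_time=20.0),
        "grant": SensorSpec("grant", resolution=0.01, noise_sd=0.010, response_time=30.0),
        "ibutton": SensorSpec("ibutton", resolution=0.0625, noise_sd=0.020, response_time=60.0),
        "embedded": SensorSpec("embedded", resolution=0.01, noise_sd=0.005, response_time=5.0),
    }


def default_plate_setpoints(
    material: MaterialProps,
    ambient_temp: float,
    air_velocity: float,
    n_steps: int = 5,
) -> tuple[float, ...]:
    """Plate setpoints spanning the target surface-to-environment gradients.

    The protocol starts with the bare surface at ambient (zero gradient)
    and finishes near 40 degC at 0.5 m/s (gradient ~0-16 degC) or ~42 degC
    at 0.2 m/s (gradient ~0-18 degC); the higher velocity draws more heat
    through the slab, so the same surface temperature needs a hotter plate.
    Setpoints are obtained by inverting the bare column.
    """
    gradient_max = 16.0 if air_velocity >= 0.35 else 18.0
    r_slab = material.thickness / material.conductivity
    h = convective_coefficient(air_velocity) + radiative_coefficient(
        material.emissivity, ambient_temp
    )
    r_bnd = 1.0 / h
    gradients = [gradient_max * i / (n_steps - 1) for i in range(n_steps)]
    return tuple(ambient_temp + g * (r_slab + r_bnd) / r_bnd for g in gradients)


def default_rig_config(air_velocity: float = 0.5, seed: int = 0, **overrides) -> RigConfig:
    """RigConfig with plate setpoints derived for the requested velocity."""
    material = overrides.pop("material", default_material())
    ambient = overrides.pop("ambient_temp", 23.8)
    setpoints = overrides.pop(
        "plate_setpoints",
        default_plate_setpoints(material, ambient, air_velocity),
    )
    return RigConfig(
        ambient_temp=ambient,
        air_velocity=air_velocity,
        plate_setpoints=tuple(setpoints),
        seed=seed,
        **overrides,
    )
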