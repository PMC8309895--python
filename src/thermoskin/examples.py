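"""Worked-example construction: noiseless steady states anchored at a
known sensor/reference operating point.

For desk-scale checks of the fixed-operating-point bias machinery it is
useful to build a set of paired steady states that (a) are exactly
co-linear in sensor temperature, with slopes taken from the thermal
network for the matching coverage and velocity, and (b) pass exactly
through a given operating point (sensor reading, disturbed reference,
undisturbed reference).  Evaluating bias at the operating point's sensor
temperature must then return exactly the operating point's bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disturbance import PairedSteadyState
from .network import (
    CoverageSpec,
    MaterialProps,
    RigConfig,
    default_coverages,
    default_material,
    default_rig_config,
    solve_thermal_network,
)

__all__ = ["OperatingPoint", "anchored_states"]


@dataclass(frozen=True)
class OperatingPoint:
    """A sensor reading with its paired reference temperatures (degC)."""

    t_sen: float
    t_d: float
    t_u: float


def _reference_slopes(
    coverage: CoverageSpec, config: RigConfig, material: MaterialProps
) -> tuple[float, float]:
    """d(T_d)/d(T_sen) and d(T_u)/d(T_sen) along the plate-temperature axis."""
    ta = config.ambient_temp
    sol = solve_thermal_network(material, coverage, config, ta + 20.0)
    dsen = sol.sensor_node - ta
    if dsen == 0:
        raise ValueError("sensor node insensitive to plate temperature")
    return (sol.surface_disturbed - ta) / dsen, (sol.surface_undisturbed - ta) / dsen


def anchored_states(
    coverage: str,
    air_velocity: float,
    operating_point: OperatingPoint,
    n_replicates: int = 5,
    sensor_temps: tuple[float, ...] = (27.0, 29.0, 31.0, 33.0, 35.0),
    material: MaterialProps | None = None,
) -> list[PairedSteadyState]:
    """Noiseless co-linear paired steady states through an operating point.

    Every replicate shares the same line (so replicate spread, hence CI
    width, is zero); slopes of T_d and T_u against T_sen come from the
    thermal network for the given coverage and velocity.
    """
    material = material or default_material()
    cov = default_coverages()[coverage]
    config = default_rig_config(air_velocity=air_velocity)
    slope_d, slope_u = _reference_slopes(cov, config, material)
    op = operating_point
    states = []
    for rep in range(1, n_replicates + 1):
        for step, t_sen in enumerate(sensor_temps, start=1):
            states.append(
                PairedSteadyState(
                    coverage=coverage,
                    air_velocity=air_velocity,
                    replicate=rep,
                    step=step,
                    t_sen=float(t_sen),
                    t_d=op.t_d + slope_d * (t_sen - op.t_sen),
                    t_u=op.t_u + slope_u * (t_sen - op.t_sen),
                    ambient=config.ambient_temp,
                )
            )
    return states
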