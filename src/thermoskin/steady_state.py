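"""Steady-state extraction from rig runs and subsurface-to-surface
correction of the embedded reference readings.

Per 30-min plate step, channel means and SDs are computed over minutes
21-29 (half-open [21, 29)); a step qualifies when every analyzed channel
has SD < 0.05 degC.  Because the embedded reference thermistor sits just
below the surface, its reading is extrapolated to the surface assuming a
linear in-slab temperature profile (Fourier's law with constant flux),
using the second embedded sensor:

    T_surface = T_z1 + (T_z1 - T_z2) * z1 / (z2 - z1)

Surface skin-temperature sensor readings are never corrected this way —
consistent with how such sensors are used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ValidationError
from .synthetic import RigRun

__all__ = [
    "StepSteadyState",
    "SurfaceEstimate",
    "extract_step_means",
    "correct_to_surface",
    "WINDOW_START_MIN",
    "WINDOW_END_MIN",
    "SD_TOL",
]

WINDOW_START_MIN = 21.0
WINDOW_END_MIN = 29.0
SD_TOL = 0.05  # degC


@dataclass
class StepSteadyState:
    """Per-step analysis-window summary of one rig run."""

    run_id: str
    coverage: str
    air_velocity: float
    replicate: int
    step: int  # 1-based
    plate_setpoint: float
    means: dict[str, float]
    sds: dict[str, float]
    qualified: bool
    reason: str = ""


@dataclass(frozen=True)
class SurfaceEstimate:
    """Subsurface reading extrapolated to the surface (z = 0)."""

    surface_temp: float
    correction_magnitude: float
    flux_per_area: float  # implied W/m^2 given the slab conductivity


def extract_step_means(run: RigRun, sd_tol: float = SD_TOL) -> list[StepSteadyState]:
    """Means/SDs over minutes [21, 29) of each step, with an SD gate.

    Every analyzed temperature channel must have SD < ``sd_tol`` for the
    step to qualify; truncated steps are marked unqualified with a reason.
    """
    cfg = run.config
    out: list[StepSteadyState] = []
    n_expected = int(round((WINDOW_END_MIN - WINDOW_START_MIN) * 60.0 / cfg.sample_interval))
    for step_idx, setpoint in enumerate(cfg.plate_setpoints):
        t0 = step_idx * cfg.step_duration
        lo = t0 + WINDOW_START_MIN * 60.0
        hi = t0 + WINDOW_END_MIN * 60.0
        mask = (run.timestamps >= lo) & (run.timestamps < hi)
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        if mask.sum() < n_expected:
            out.append(
                StepSteadyState(
                    run_id=run.run_id(),
                    coverage=run.coverage,
                    air_velocity=run.air_velocity,
                    replicate=run.replicate,
                    step=step_idx + 1,
                    plate_setpoint=setpoint,
                    means=means,
                    sds=sds,
                    qualified=False,
                    reason=f"truncated step: {int(mask.sum())}/{n_expected} samples",
                )
            )
            continue
        unstable = []
        for name, values in run.channels.items():
            seg = values[mask]
            means[name] = float(seg.mean())
            sds[name] = float(seg.std(ddof=0))
            if sds[name] >= sd_tol:
                unstable.append(name)
        out.append(
            StepSteadyState(
                run_id=run.run_id(),
                coverage=run.coverage,
                air_velocity=run.air_velocity,
                replicate=run.replicate,
                step=step_idx + 1,
                plate_setpoint=setpoint,
                means=means,
                sds=sds,
                qualified=not unstable,
                reason="" if not unstable else "SD >= tol on: " + ", ".join(sorted(unstable)),
            )
        )
    return out


def correct_to_surface(
    t_z1: float, t_z2: float, z1: float, z2: float, conductivity: float = 0.23
) -> SurfaceEstimate:
    """Linear extrapolation of the in-slab profile to the surface (z = 0).

    With a linear gradient between depths z1 and z2 (z measured from the
    surface, z2 > z1 > 0):

        T_surface = T_z1 + (T_z1 - T_z2) * z1 / (z2 - z1)

    The implied conductive flux toward the surface is
    ``k * (T_z2 - T_z1) / (z2 - z1)``.
    """
    if not z2 > z1 > 0:
        raise ValidationError("invalid geometry: require z2 > z1 > 0")
    gradient = (t_z1 - t_z2) / (z2 - z1)
    surface = t_z1 + gradient * z1
    return SurfaceEstimate(
        surface_temp=float(surface),
        correction_magnitude=abs(float(surface - t_z1)),
        flux_per_area=float(conductivity * (t_z2 - t_z1) / (z2 - z1)),
    )


def corrected_reference_temps(state: StepSteadyState, run: RigRun) -> dict[str, float]:
    """Surface-corrected disturbed/undisturbed reference temperatures and
    the correction magnitudes, from one step's channel means."""
    cfg = run.config
    out: dict[str, float] = {}
    for label, (ch1, ch2) in {
        "disturbed": ("T_z1_disturbed", "T_z2_disturbed"),
        "undisturbed": ("T_z1_undisturbed", "T_z2_undisturbed"),
    }.items():
        est = correct_to_surface(state.means[ch1], state.means[ch2], cfg.z1, cfg.z2)
        out[f"T_{label[0]}"] = est.surface_temp
        out[f"correction_{label}"] = est.correction_magnitude
    return out
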