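"""Local temperature disturbance and sensor bias.

A surface contact sensor changes the temperature of the surface it
measures.  With a disturbed reference temperature T_d (surface beneath
the sensor/tape), a matched undisturbed reference T_u (same location in
its bare state under equivalent conditions), and the sensor reading
T_sen, the quantities of interest are:

    disturbance  = T_d - T_u
    bias from T_d = T_sen - T_d
    bias from T_u = T_sen - T_u

so that bias-from-T_u = bias-from-T_d + disturbance holds exactly per
paired steady state.  Both disturbance and bias scale linearly with the
surface-to-environment temperature gradient (taken as T_u - ambient), so
fixed-operating-point summaries are obtained by fitting bias against the
sensor reading per replicate and evaluating the line at a fixed sensor
temperature (default 31 degC), then summarizing replicates with an
unadjusted 95% t-interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stats import LineFit, fit_line, summarize_mean_ci

__all__ = [
    "PairedSteadyState",
    "FixedPointSummary",
    "MatchingError",
    "match_undisturbed",
    "compute_disturbance",
    "compute_bias",
    "fit_vs_gradient",
    "evaluate_at_fixed_sensor_temp",
    "summarize_mean_ci",
    "BIAS_FORMS",
]

BIAS_FORMS = ("bias_from_Td", "bias_from_Tu")


class MatchingError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSteadyState:
    """One covered steady state paired with its undisturbed reference."""

    coverage: str
    air_velocity: float
    replicate: int
    step: int
    t_sen: float | None  # None for coverages without a readable sensor
    t_d: float  # corrected disturbed surface temperature, degC
    t_u: float  # corrected, matched undisturbed surface temperature, degC
    ambient: float

    @property
    def gradient(self) -> float:
        """Undisturbed surface-to-environment temperature gradient."""
        return self.t_u - self.ambient

    @property
    def disturbance(self) -> float:
        return compute_disturbance(self.t_d, self.t_u)

    def bias(self, form: str) -> float:
        if self.t_sen is None:
            raise ValueError(f"no surface sensor for coverage {self.coverage!r}")
        ref = self.t_d if form == "bias_from_Td" else self.t_u
        return compute_bias(self.t_sen, ref, form)


@dataclass(frozen=True)
class FixedPointSummary:
    """Mean bias (or disturbance) at a fixed sensor temperature."""

    coverage: str
    air_velocity: float
    form: str
    evaluated_at: float
    mean: float
    ci_low: float | None
    ci_high: float | None
    n: int


def match_undisturbed(disturbed_states, bare_states) -> list[PairedSteadyState]:
    """Pair covered steady states with bare-surface references.

    Each element of both inputs is a mapping with keys ``coverage``,
    ``air_velocity``, ``replicate``, ``step``, ``plate_setpoint``,
    ``ambient``, ``T_d`` (or ``T_u`` for bare), and optionally ``T_sen``.
    Pairing is by (velocity, replicate, step) when the bare replicate
    exists; otherwise T_u is interpolated linearly against the plate
    setpoint across the bare runs of that velocity.  A velocity without
    any bare run raises ``MatchingError`` listing the offending runs.
    """
    bare_index: dict[tuple[float, int, int], float] = {}
    bare_by_velocity: dict[float, list[tuple[float, float]]] = {}
    for b in bare_states:
        key = (b["air_velocity"], b["replicate"], b["step"])
        bare_index[key] = b["T_u"]
        bare_by_velocity.setdefault(b["air_velocity"], []).append(
            (b["plate_setpoint"], b["T_u"])
        )

    missing = sorted(
        {
            f"{d['coverage']} v={d['air_velocity']:g} rep={d['replicate']}"
            for d in disturbed_states
            if d["air_velocity"] not in bare_by_velocity
        }
    )
    if missing:
        raise MatchingError(
            "no bare-surface run for the velocity of: " + "; ".join(missing)
        )

    out: list[PairedSteadyState] = []
    for d in disturbed_states:
        key = (d["air_velocity"], d["replicate"], d["step"])
        if key in bare_index:
            t_u = bare_index[key]
        else:
            pts = sorted(bare_by_velocity[d["air_velocity"]])
            xs = np.array([p[0] for p in pts])
            ys = np.array([p[1] for p in pts])
            t_u = float(np.interp(d["plate_setpoint"], xs, ys))
        out.append(
            PairedSteadyState(
                coverage=d["coverage"],
                air_velocity=d["air_velocity"],
                replicate=d["replicate"],
                step=d["step"],
                t_sen=d.get("T_sen"),
                t_d=d["T_d"],
                t_u=t_u,
                ambient=d["ambient"],
            )
        )
    return out


def compute_disturbance(t_d: float, t_u: float) -> float:
    """disturbance = T_d - T_u (positive: the coverage warms the surface)."""
    return t_d - t_u


def compute_bias(t_sen: float, t_ref: float, form: str = "bias_from_Td") -> float:
    """bias = T_sen - T_ref, with T_ref either T_d or the matched T_u."""
    if form not in BIAS_FORMS:
        raise ValueError(f"form must be one of {BIAS_FORMS}")
    return t_sen - t_ref


def fit_vs_gradient(values, gradients) -> LineFit:
    """OLS of disturbance/bias values on the surface-to-air gradient."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need >= 3 points to characterize the gradient relation")
    return fit_line(gradients, values)


def evaluate_at_fixed_sensor_temp(
    states: list[PairedSteadyState],
    form: str,
    t_fixed: float = 31.0,
) -> FixedPointSummary:
    """Per-replicate linear evaluation of bias at a fixed sensor reading.

    For each replicate, bias (chosen form) is fitted linearly against the
    sensor temperature across that replicate's steady states and evaluated
    at ``t_fixed``; the replicate values are summarized as a mean with an
    unadjusted 95% t-interval (df = n - 1).  Replicates with fewer than
    two states are excluded; with a single usable replicate the CI is
    undefined (None bounds).
    """
    if form == "disturbance":
        # Disturbance is quoted at an equivalent undisturbed surface
        # temperature, so the line is fitted against T_u.
        value = lambda s: s.disturbance
        x_of = lambda s: s.t_u
    else:
        value = lambda s: s.bias(form)
        x_of = lambda s: s.t_sen

    coverages = {s.coverage for s in states}
    velocities = {s.air_velocity for s in states}
    if len(coverages) != 1 or len(velocities) != 1:
        raise ValueError("states must share one coverage and one velocity")

    by_rep: dict[int, list[PairedSteadyState]] = {}
    for s in states:
        by_rep.setdefault(s.replicate, []).append(s)

    rep_values: list[float] = []
    for rep, rep_states in sorted(by_rep.items()):
        if len(rep_states) < 2:
            continue  # excluded: cannot anchor a line
        xs = np.array([x_of(s) for s in rep_states], dtype=float)
        ys = np.array([value(s) for s in rep_states], dtype=float)
        if np.ptp(xs) == 0:
            continue
        line = fit_line(xs, ys)
        rep_values.append(float(line.predict(t_fixed)))

    if not rep_values:
        raise ValueError("no replicate had >= 2 usable steady states")
    if len(rep_values) < 2:
        return FixedPointSummary(
            coverage=coverages.pop(),
            air_velocity=velocities.pop(),
            form=form,
            evaluated_at=t_fixed,
            mean=rep_values[0],
            ci_low=None,
            ci_high=None,
            n=1,
        )
    mean, lo, hi = summarize_mean_ci(rep_values)
    return FixedPointSummary(
        coverage=coverages.pop(),
        air_velocity=velocities.pop(),
        form=form,
        evaluated_at=t_fixed,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        n=len(rep_values),
    )
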