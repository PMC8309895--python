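"""Synthetic rig runs and human-trial datasets.

Stands in for the physical experiments: a stepped-plate rig protocol on
the silicone skin simulant (five 30-min plate steps, 10 s logging,
embedded reference thermistors at two depths in a covered and a bare
column) and a rest/cycling human trial with per-site skin temperature and
relative-humidity records exhibiting a sweat-onset step in absolute vapor
pressure.

Transients are modelled as single-pole relaxation of each node toward the
step's steady state with a conduction time constant ``L^2 / (pi^2 alpha)``
(first diffusion mode of the slab); only steady states are analyzed
downstream, so transients need only be plausible.  Observations follow
``true * gain + offset + N(0, sd)`` and are then quantized to the logger
resolution.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import (
    COVERAGE_SENSOR,
    CoverageSpec,
    MaterialProps,
    RigConfig,
    SensorSpec,
    ValidationError,
    default_coverages,
    default_material,
    default_rig_config,
    default_sensors,
    solve_thermal_network,
)
from .trial import MAGNUS_A, MAGNUS_B, MAGNUS_C, saturation_vapor_pressure

__all__ = [
    "RigRun",
    "TrialPeriodSpec",
    "TrialDataset",
    "simulate_rig_run",
    "simulate_human_trial",
    "default_trial_periods",
    "TRIAL_SITES",
    "TRIAL_SENSOR_TYPES",
]

TRIAL_SITES = ("chest", "arm", "thigh", "leg")
TRIAL_SENSOR_TYPES = ("custom", "grant", "ibutton")


@dataclass
class RigRun:
    """One simulated (or loaded) rig run: aligned uniform channels in degC.

    ``channels`` maps channel name -> ndarray; always present are
    ``T_z1_disturbed``, ``T_z2_disturbed``, ``T_z1_undisturbed``,
    ``T_z2_undisturbed`` and ``ambient``; ``T_sen`` is present only when
    the coverage carries a readable surface sensor.
    """

    coverage: str
    air_velocity: float
    replicate: int
    seed: int
    timestamps: np.ndarray  # elapsed s, strictly increasing
    channels: dict[str, np.ndarray]
    config: RigConfig
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if n == 0:
            raise ValidationError("empty run")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        for name, values in self.channels.items():
            if len(values) != n:
                raise ValidationError(f"channel {name!r} length mismatch")

    @property
    def n_steps(self) -> int:
        return len(self.config.plate_setpoints)

    def run_id(self) -> str:
        return f"{self.coverage}_v{self.air_velocity:g}_r{self.replicate}"


def _quantize(values: np.ndarray, resolution: float) -> np.ndarray:
    if resolution <= 0:
        return values
    return np.round(values / resolution) * resolution


def _observe(true: np.ndarray, spec: SensorSpec, rng: np.random.Generator) -> np.ndarray:
    obs = true * spec.true_gain + spec.true_offset
    if spec.noise_sd > 0:
        obs = obs + rng.normal(0.0, spec.noise_sd, size=true.shape)
    return _quantize(obs, spec.resolution)


def _relax(targets: np.ndarray, t_in_step: np.ndarray, start: float, tau: float) -> np.ndarray:
    """Piecewise first-order relaxation through a sequence of step targets.

    ``targets`` has one steady-state value per step; returns the node
    trajectory sampled at the (step, time-in-step) grid implied by
    ``t_in_step`` repeated per step.
    """
    out = np.empty(len(targets) * len(t_in_step))
    prev = start
    for i, target in enumerate(targets):
        seg = target + (prev - target) * np.exp(-t_in_step / tau)
        out[i * len(t_in_step) : (i + 1) * len(t_in_step)] = seg
        prev = seg[-1]
    return out


def simulate_rig_run(
    material: MaterialProps | None = None,
    coverage: CoverageSpec | str = "bare",
    config: RigConfig | None = None,
    sensors: dict[str, SensorSpec] | None = None,
    seed: int = 0,
    replicate: int = 1,
) -> RigRun:
    """Simulate one coverage x velocity x replicate rig run.

    Each plate step relaxes first-order toward its steady state; samples
    are taken every ``config.sample_interval`` seconds starting at that
    interval.  Identical seeds give identical runs.
    """
    material = material or default_material()
    if isinstance(coverage, str):
        coverage = default_coverages()[coverage]
    config = config or default_rig_config()
    sensors = sensors or default_sensors()
    config.validate_geometry(material)

    rng = np.random.default_rng(seed)
    warnings: list[str] = []

    tau = material.thickness**2 / (math.pi**2 * material.diffusivity)
    if tau >= config.step_duration / 3:
        warnings.append(
            f"time constant {tau:.0f} s >= step_duration/3; steady state may not be reached"
        )

    n_per_step = int(round(config.step_duration / config.sample_interval))
    t_in_step = config.sample_interval * np.arange(1, n_per_step + 1)
    timestamps = config.sample_interval * np.arange(
        1, n_per_step * len(config.plate_setpoints) + 1
    )

    states = [
        solve_thermal_network(material, coverage, config, tp)
        for tp in config.plate_setpoints
    ]

    embedded = sensors.get("embedded", SensorSpec("embedded"))
    node_specs = {
        "T_z1_disturbed": ("z1_disturbed", embedded, 0.0),
        "T_z2_disturbed": ("z2_disturbed", embedded, 0.0),
        "T_z1_undisturbed": ("z1_undisturbed", embedded, 0.0),
        "T_z2_undisturbed": ("z2_undisturbed", embedded, 0.0),
    }
    sensor_type = COVERAGE_SENSOR[coverage.name]
    if sensor_type is not None:
        spec = sensors[sensor_type]
        node_specs["T_sen"] = ("sensor_node", spec, spec.response_time)

    channels: dict[str, np.ndarray] = {}
    for name, (attr, spec, extra_tau) in node_specs.items():
        targets = np.array([getattr(s, attr) for s in states])
        true = _relax(targets, t_in_step, start=config.ambient_temp, tau=tau + extra_tau)
        channels[name] = _observe(true, spec, rng)
    channels["ambient"] = _observe(
        np.full(len(timestamps), config.ambient_temp), embedded, rng
    )

    return RigRun(
        coverage=coverage.name,
        air_velocity=config.air_velocity,
        replicate=replicate,
        seed=seed,
        timestamps=timestamps,
        channels=channels,
        config=config,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Human trial
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialPeriodSpec:
    """One protocol phase of the human trial, minutes from trial start."""

    label: str
    start: float
    end: float
    activity: str  # {rest, exercise, transition}

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"period {self.label!r} has end <= start")


def default_trial_periods() -> list[TrialPeriodSpec]:
    """Rest/cycling timeline: baseline rest to min 40, transition, three
    fixed-load cycling blocks (min 45-90), transition, recovery rest."""
    return [
        TrialPeriodSpec("baseline_rest", 0.0, 40.0, "rest"),
        TrialPeriodSpec("transition1", 40.0, 45.0, "transition"),
        TrialPeriodSpec("FL1", 45.0, 60.0, "exercise"),
        TrialPeriodSpec("FL2", 60.0, 75.0, "exercise"),
        TrialPeriodSpec("FL3", 75.0, 90.0, "exercise"),
        TrialPeriodSpec("transition2", 90.0, 95.0, "transition"),
        TrialPeriodSpec("recovery_rest", 95.0, 135.0, "rest"),
    ]


@dataclass
class TrialDataset:
    """Simulated human trial: per participant x sensor type x site series.

    ``tsk[participant][sensor_type][site]`` and
    ``rh[participant][site]`` / ``site_temp[participant][site]`` are
    aligned with ``time_min``.  ``true_onset_min`` records the injected
    sweat-onset time (minutes from trial start) per participant.
    """

    time_min: np.ndarray
    tsk: dict[int, dict[str, dict[str, np.ndarray]]]
    rh: dict[int, dict[str, np.ndarray]]
    site_temp: dict[int, dict[str, np.ndarray]]
    periods: list[TrialPeriodSpec]
    exercise_start_min: float
    true_onset_min: dict[int, float]
    sensor_offsets: dict[str, float]
    seed: int

    @property
    def participants(self) -> list[int]:
        return sorted(self.tsk)


_SITE_BASELINE = {"chest": 33.5, "arm": 32.5, "thigh": 32.0, "leg": 31.5}
_SITE_EXERCISE_DELTA = {"chest": 1.2, "arm": 0.8, "thigh": 1.5, "leg": 1.0}


def _smooth_trend(
    time_min: np.ndarray,
    baseline: float,
    periods: list[TrialPeriodSpec],
    delta: float,
) -> np.ndarray:
    """Piecewise-smooth skin-temperature trend: slight dip at exercise
    onset, rise during cycling, exponential recovery afterwards."""
    exercise = [p for p in periods if p.activity == "exercise"]
    ex_start = min(p.start for p in exercise)
    ex_end = max(p.end for p in exercise)
    trend = np.full_like(time_min, baseline, dtype=float)
    during = (time_min >= ex_start) & (time_min < ex_end)
    te = time_min[during] - ex_start
    # 3-min vasoconstriction dip then saturating rise.
    trend[during] = (
        baseline
        - 0.3 * np.exp(-te / 3.0)
        + delta * (1.0 - np.exp(-te / 12.0))
    )
    after = time_min >= ex_end
    end_val = baseline - 0.3 * math.exp(-(ex_end - ex_start) / 3.0) + delta * (
        1.0 - math.exp(-(ex_end - ex_start) / 12.0)
    )
    trend[after] = baseline + (end_val - baseline) * np.exp(
        -(time_min[after] - ex_end) / 20.0
    )
    return trend


def simulate_human_trial(
    protocol_periods: list[TrialPeriodSpec] | None = None,
    n_participants: int = 14,
    seed: int = 0,
    sensor_offsets: dict[str, float] | None = None,
    onset_step_kpa: float = 0.6,
    onset_delay_range_min: tuple[float, float] = (4.8, 10.3),
    noise_sd: float = 0.05,
    sample_interval_s: float = 10.0,
    onset_min: float | None = None,
) -> TrialDataset:
    """Simulate rest/exercise/recovery skin temperature and humidity.

    Sensor-type offsets (degC, added to every reading of that type) default
    to small values representative of inter-sensor disagreement; pass an
    explicit dict (e.g. all zeros) for null configurations.  The absolute
    vapor pressure at every site steps up by ``onset_step_kpa`` at the
    participant's sweat onset, drawn uniformly from
    ``onset_delay_range_min`` after exercise start (or fixed via
    ``onset_min``, minutes from trial start).
    """
    periods = protocol_periods or default_trial_periods()
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(f"periods {a.label!r} and {b.label!r} overlap")
    exercise = [p for p in ordered if p.activity == "exercise"]
    if not exercise or not any(p.activity == "rest" for p in ordered):
        raise ValidationError("protocol must include rest and exercise periods")
    ex_start = min(p.start for p in exercise)
    t_end = max(p.end for p in ordered)

    if sensor_offsets is None:
        sensor_offsets = {"custom": 0.0, "grant": -0.15, "ibutton": 0.20}

    rng = np.random.default_rng(seed)
    time_min = (sample_interval_s / 60.0) * np.arange(
        1, int(round(t_end * 60.0 / sample_interval_s)) + 1
    )

    tsk: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    rh: dict[int, dict[str, np.ndarray]] = {}
    site_temp: dict[int, dict[str, np.ndarray]] = {}
    true_onset: dict[int, float] = {}

    for p in range(1, n_participants + 1):
        if onset_min is not None:
            onset = float(onset_min)
        else:
            onset = ex_start + rng.uniform(*onset_delay_range_min)
        true_onset[p] = onset
        part_shift = rng.normal(0.0, 0.25)

        site_trends = {}
        for site in TRIAL_SITES:
            base = _SITE_BASELINE[site] + part_shift + rng.normal(0.0, 0.15)
            site_trends[site] = _smooth_trend(
                time_min, base, ordered, _SITE_EXERCISE_DELTA[site]
            )

        tsk[p] = {}
        for stype in TRIAL_SENSOR_TYPES:
            tsk[p][stype] = {}
            for site in TRIAL_SITES:
                series = (
                    site_trends[site]
                    + sensor_offsets.get(stype, 0.0)
                    + rng.normal(0.0, noise_sd, size=time_min.shape)
                )
                tsk[p][stype][site] = series

        rh[p] = {}
        site_temp[p] = {}
        for site in TRIAL_SITES:
            temp = site_trends[site] + rng.normal(0.0, noise_sd, size=time_min.shape)
            vp_base = 0.45 * saturation_vapor_pressure(site_trends[site])
            vp = vp_base + onset_step_kpa * (time_min >= onset)
            vp = vp + rng.normal(0.0, 0.01, size=time_min.shape)
            rh_series = 100.0 * vp / saturation_vapor_pressure(temp)
            rh[p][site] = np.clip(rh_series, 0.0, 100.0)
            site_temp[p][site] = temp

    return TrialDataset(
        time_min=time_min,
        tsk=tsk,
        rh=rh,
        site_temp=site_temp,
        periods=ordered,
        exercise_start_min=ex_start,
        true_onset_min=true_onset,
        sensor_offsets=dict(sensor_offsets),
        seed=seed,
    )
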