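"""Human-trial calculations: weighted-mean skin temperature, 3-min period
means, absolute vapor pressure, sweat-onset detection, and
within-participant inter-sensor differences.

Skin temperature is summarized with the classic four-site weighted mean
(chest and arm 0.3 each, thigh and leg 0.2 each).  Sweat onset is read
from humidity: the absolute vapor pressure at the skin rises sharply when
sweating begins, and a sustained rise of more than 0.5 kPa above the
pre-exercise baseline marks the onset; the earliest of the four sites is
taken as the participant's onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import summarize_mean_ci

__all__ = [
    "TSK_WEIGHTS",
    "MAGNUS_A",
    "MAGNUS_B",
    "MAGNUS_C",
    "SweatOnset",
    "InterSensorDifference",
    "weighted_mean_tsk",
    "period_means",
    "saturation_vapor_pressure",
    "vapor_pressure",
    "detect_sweat_onset",
    "trial_intersensor_differences",
    "SENSOR_PAIRS",
]

#: Four-site weighting: chest, arm, thigh, leg.
TSK_WEIGHTS = {"chest": 0.3, "arm": 0.3, "thigh": 0.2, "leg": 0.2}

#: Pair labels; the sign convention is first-listed minus second-listed,
#: so a negative mean difference means the first sensor reads cooler.
SENSOR_PAIRS = (("grant", "custom"), ("ibutton", "custom"), ("ibutton", "grant"))

# Magnus saturation-vapor-pressure constants (kPa over liquid water).
MAGNUS_A = 0.61094
MAGNUS_B = 17.625
MAGNUS_C = 243.04


@dataclass(frozen=True)
class SweatOnset:
    """Detected onset of sweating, minutes from trial start."""

    time_min: float
    site: str


@dataclass(frozen=True)
class InterSensorDifference:
    """Group-summarized paired difference between two sensor types."""

    pair: str  # e.g. "grant-custom"
    period: str
    mean: float
    ci_low: float | None  # None when n < 2 (CI undefined)
    ci_high: float | None
    n: int


def weighted_mean_tsk(chest, arm, thigh, leg):
    """Four-site weighted-mean skin temperature (elementwise on arrays).

    weighted-mean Tsk = 0.3*T_chest + 0.3*T_arm + 0.2*T_thigh + 0.2*T_leg
    """
    parts = {"chest": chest, "arm": arm, "thigh": thigh, "leg": leg}
    for site, value in parts.items():
        if value is None or not np.all(np.isfinite(value)):
            raise ValueError(f"site {site!r} missing or non-finite; no reweighting fallback")
    return (
        TSK_WEIGHTS["chest"] * np.asarray(chest, dtype=float)
        + TSK_WEIGHTS["arm"] * np.asarray(arm, dtype=float)
        + TSK_WEIGHTS["thigh"] * np.asarray(thigh, dtype=float)
        + TSK_WEIGHTS["leg"] * np.asarray(leg, dtype=float)
    )


def period_means(
    series: np.ndarray,
    time_min: np.ndarray,
    periods: dict[str, tuple[float, float]],
) -> dict[str, float]:
    """Arithmetic means over half-open [start, end) windows in minutes."""
    series = np.asarray(series, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    out: dict[str, float] = {}
    for label, (start, end) in periods.items():
        mask = (time_min >= start) & (time_min < end)
        if not mask.any() or start < time_min[0] - 1e-9 or end > time_min[-1] + 1e-9:
            raise ValueError(f"period {label!r} [{start}, {end}) outside recording")
        out[label] = float(series[mask].mean())
    return out


def saturation_vapor_pressure(temp_c):
    """Saturation vapor pressure over water (kPa), Magnus form."""
    t = np.asarray(temp_c, dtype=float)
    return MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))


def vapor_pressure(temp_c, rh_percent):
    """Absolute vapor pressure (kPa) from temperature and relative humidity."""
    rh = np.asarray(rh_percent, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100] %")
    return (rh / 100.0) * saturation_vapor_pressure(temp_c)


def detect_sweat_onset(
    vp_by_site: dict[str, np.ndarray],
    time_min: np.ndarray,
    exercise_start_min: float,
    threshold_kpa: float = 0.5,
    sustain_s: float = 60.0,
    baseline_min: float = 3.0,
) -> SweatOnset | None:
    """Earliest sustained vapor-pressure rise above baseline across sites.

    Per site: baseline is the mean vapor pressure over the final
    ``baseline_min`` minutes before exercise start; onset is the first
    sample after exercise start at which ``vp - baseline > threshold_kpa``
    holds continuously for at least ``sustain_s`` seconds.  Returns None
    when no site crosses the threshold.
    """
    time_min = np.asarray(time_min, dtype=float)
    pre = (time_min >= exercise_start_min - baseline_min) & (time_min < exercise_start_min)
    if pre.sum() < 2:
        raise ValueError(f"need >= {baseline_min} min of pre-exercise data")
    dt_s = float(np.median(np.diff(time_min))) * 60.0
    sustain_n = max(1, int(np.ceil(sustain_s / dt_s)))

    best: SweatOnset | None = None
    for site, vp in vp_by_site.items():
        vp = np.asarray(vp, dtype=float)
        baseline = float(vp[pre].mean())
        after = np.flatnonzero(time_min >= exercise_start_min)
        above = vp[after] - baseline > threshold_kpa
        # First index where `above` holds for sustain_n consecutive samples.
        run = 0
        onset_idx = None
        for j, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= sustain_n:
                onset_idx = j - sustain_n + 1
                break
        if onset_idx is None:
            continue
        t_onset = float(time_min[after[onset_idx]])
        if best is None or t_onset < best.time_min:
            best = SweatOnset(time_min=t_onset, site=site)
    return best


def trial_intersensor_differences(
    weighted_means: dict[int, dict[str, dict[str, float]]],
    periods: list[str],
    pairs: tuple[tuple[str, str], ...] = SENSOR_PAIRS,
) -> list[InterSensorDifference]:
    """Within-participant paired differences, summarized per pair x period.

    ``weighted_means[participant][sensor_type][period]`` are the
    weighted-mean skin temperatures; participants missing any sensor type
    are excluded.  Differences follow the first-minus-second convention.
    """
    required = {s for pair in pairs for s in pair}
    complete = [
        p for p, by_type in weighted_means.items() if required.issubset(by_type)
    ]
    if len(complete) < 2:
        raise ValueError("need >= 2 participants with complete sensor data")
    out: list[InterSensorDifference] = []
    for first, second in pairs:
        for period in periods:
            diffs = [
                weighted_means[p][first][period] - weighted_means[p][second][period]
                for p in complete
            ]
            mean, lo, hi = summarize_mean_ci(diffs)
            out.append(
                InterSensorDifference(
                    pair=f"{first}-{second}",
                    period=period,
                    mean=mean,
                    ci_low=lo,
                    ci_high=hi,
                    n=len(diffs),
                )
            )
    return out
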