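"""Inter-sensor comparison via inverse prediction on the skin model.

Because the absolute surface temperature itself determines the magnitude
of inter-sensor differences, comparisons are made at common reference
temperatures: each individual sensor's steady-state readings X are
regressed on the matched undisturbed reference temperature,

    Y' = b0 + b1 * X,

seven reference-temperature anchors Y'_1..7 (one per human-trial summary
period) are computed from the custom-thermistor fits and the human-trial
custom group means, and each sensor's reading at every anchor is
recovered by inverse prediction,

    X' = (Y' - b0) / b1.

Pairwise differences of X' between sensor types (per replicate) are then
summarized exactly as in the human trial (mean, unadjusted 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import fit_line, summarize_mean_ci
from .trial import SENSOR_PAIRS, InterSensorDifference

__all__ = [
    "SensorReferenceFit",
    "AnchorSet",
    "fit_sensor_to_reference",
    "compute_anchors",
    "inverse_predict",
    "intersensor_differences",
    "R2_QUALITY_BAR",
]

R2_QUALITY_BAR = 0.99  # observed quality of linear sensor-reference relations


@dataclass(frozen=True)
class SensorReferenceFit:
    """OLS of undisturbed reference on one sensor's steady-state readings."""

    sensor_id: str
    b0: float  # intercept, degC
    b1: float  # slope
    r_squared: float
    typical_error: float  # mean absolute residual, degC
    n: int
    quality_flag: bool  # True when R^2 exceeds the quality bar

    def predict(self, x: float) -> float:
        return self.b0 + self.b1 * x


@dataclass(frozen=True)
class AnchorSet:
    """Reference-temperature anchors, one per trial summary period."""

    periods: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.values):
            raise ValueError("periods and values must align")
        if not all(np.isfinite(self.values)):
            raise ValueError("anchors must be finite")


def fit_sensor_to_reference(x, y, sensor_id: str = "") -> SensorReferenceFit:
    """Fit Y' = b0 + b1*X for one sensor against matched T_u values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired steady states")
    line = fit_line(x, y)
    resid = y - line.predict(x)
    return SensorReferenceFit(
        sensor_id=sensor_id,
        b0=line.intercept,
        b1=line.slope,
        r_squared=line.r_squared,
        typical_error=float(np.mean(np.abs(resid))),
        n=int(x.size),
        quality_flag=line.r_squared > R2_QUALITY_BAR,
    )


def compute_anchors(
    custom_group_means: dict[str, float],
    custom_fits: list[SensorReferenceFit],
) -> AnchorSet:
    """Anchor temperatures from custom-sensor fits and trial group means.

    When several custom-sensor fits exist (one per replicate sensor), the
    anchor for each period is the mean of the per-sensor predictions.
    """
    if not custom_fits:
        raise ValueError("need at least one custom-sensor fit")
    periods = tuple(custom_group_means)
    values = []
    for period in periods:
        mean = custom_group_means[period]
        if mean is None or not np.isfinite(mean):
            raise ValueError(f"missing group mean for period {period!r}")
        values.append(float(np.mean([f.predict(mean) for f in custom_fits])))
    return AnchorSet(periods=periods, values=tuple(values))


def inverse_predict(fit: SensorReferenceFit, y_prime: float) -> float:
    """X' = (Y' - b0)/b1, the sensor reading at a reference temperature."""
    if fit.b1 == 0:
        raise ZeroDivisionError("fit is not invertible (b1 = 0)")
    return (y_prime - fit.b0) / fit.b1


def intersensor_differences(
    fits_by_type: dict[str, dict[int, SensorReferenceFit]],
    anchors: AnchorSet,
    pairs: tuple[tuple[str, str], ...] = SENSOR_PAIRS,
) -> list[InterSensorDifference]:
    """Pairwise differences of inverse-predicted readings at each anchor.

    ``fits_by_type[sensor_type][replicate]`` holds one fit per individual
    sensor; replicate sets must agree between the two members of a pair.
    Differences follow the first-minus-second sign convention and are
    summarized over replicates with an unadjusted 95% t-interval.
    """
    out: list[InterSensorDifference] = []
    for first, second in pairs:
        reps_a = set(fits_by_type[first])
        reps_b = set(fits_by_type[second])
        if reps_a != reps_b:
            raise ValueError(
                f"unbalanced replicates for {first}-{second}: {sorted(reps_a)} vs {sorted(reps_b)}"
            )
        reps = sorted(reps_a)
        for period, y_prime in zip(anchors.periods, anchors.values):
            diffs = [
                inverse_predict(fits_by_type[first][r], y_prime)
                - inverse_predict(fits_by_type[second][r], y_prime)
                for r in reps
            ]
            if len(diffs) < 2:
                mean, lo, hi = diffs[0], None, None
            else:
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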