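"""In-situ sensor calibration against a precision reference thermometer.

Calibration runs step a chamber through ~5 degC intervals over 15-40 degC.
Eight-minute steady states are identified where the reference standard
deviation is below 0.007 degC; per-sensor window means are then regressed
against the reference by ordinary least squares and the fit inverted into
a correction that maps raw readings onto the reference scale:

    corrected = (raw - offset) / gain

with ``raw ~= gain * true + offset`` for a sensor with multiplicative
gain error and additive offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import fit_line

__all__ = [
    "CalibrationWindow",
    "CalibrationFit",
    "InsufficientDataError",
    "DegenerateFitError",
    "find_steady_windows",
    "fit_calibration",
    "apply_calibration",
]

REFERENCE_SD_TOL = 0.007  # degC
WINDOW_S = 480.0  # 8 min
PLATEAU_SEPARATION = 0.5  # degC between distinct plateau means


class InsufficientDataError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationWindow:
    """One 8-min steady-state window of a calibration run."""

    start_s: float
    end_s: float
    reference_mean: float
    reference_sd: float
    sensor_means: dict[str, float] = field(default_factory=dict)
    sensor_sds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CalibrationFit:
    """Linear correction for one sensor: corrected = (raw - offset)/gain."""

    sensor_id: str
    gain: float
    offset: float
    residual_sd: float
    n_windows: int


def find_steady_windows(
    reference: np.ndarray,
    timestamps: np.ndarray,
    window_s: float = WINDOW_S,
    sd_tol: float = REFERENCE_SD_TOL,
    sensors: dict[str, np.ndarray] | None = None,
) -> list[CalibrationWindow]:
    """Greedy earliest-first scan for qualifying steady windows.

    Windows are non-overlapping, satisfy ``sd(reference) < sd_tol`` over
    the full ``window_s`` span, and at most one window is kept per
    temperature plateau (plateau means separated by more than 0.5 degC).
    The stability criterion gates on the reference only; sensor-channel
    means/SDs inside accepted windows are recorded but not gated.
    A series shorter than one window yields an empty list.
    """
    reference = np.asarray(reference, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    dt = float(np.median(np.diff(timestamps))) if timestamps.size > 1 else window_s
    n_win = int(round(window_s / dt))
    if reference.size < n_win or n_win < 2:
        return []

    sensors = sensors or {}
    windows: list[CalibrationWindow] = []
    i = 0
    while i + n_win <= reference.size:
        seg = reference[i : i + n_win]
        if seg.std(ddof=0) < sd_tol:
            mean = float(seg.mean())
            if all(
                abs(mean - w.reference_mean) > PLATEAU_SEPARATION for w in windows
            ):
                windows.append(
                    CalibrationWindow(
                        start_s=float(timestamps[i]),
                        end_s=float(timestamps[i + n_win - 1]),
                        reference_mean=mean,
                        reference_sd=float(seg.std(ddof=0)),
                        sensor_means={
                            k: float(v[i : i + n_win].mean()) for k, v in sensors.items()
                        },
                        sensor_sds={
                            k: float(v[i : i + n_win].std(ddof=0))
                            for k, v in sensors.items()
                        },
                    )
                )
            i += n_win  # windows never overlap
        else:
            i += 1
    return windows


def fit_calibration(
    windows: list[CalibrationWindow],
    sensor_id: str,
    sensor_means: np.ndarray | None = None,
) -> CalibrationFit:
    """OLS of reference on raw window means, inverted into a correction.

    With the reference regressed on the raw means as
    ``ref = c0 + c1 * raw``, the correction parameters are
    ``gain = 1/c1`` and ``offset = -c0/c1`` so that
    ``(raw - offset)/gain`` maps raw readings onto the reference scale.
    """
    if len(windows) < 2:
        raise InsufficientDataError("need >= 2 steady windows to calibrate")
    ref = np.array([w.reference_mean for w in windows])
    if sensor_means is None:
        try:
            raw = np.array([w.sensor_means[sensor_id] for w in windows])
        except KeyError as exc:
            raise InsufficientDataError(
                f"sensor {sensor_id!r} missing from window means"
            ) from exc
    else:
        raw = np.asarray(sensor_means, dtype=float)
        if raw.size != ref.size:
            raise InsufficientDataError("sensor_means length must match windows")
    if np.ptp(raw) == 0:
        raise DegenerateFitError("zero variance in sensor means")

    line = fit_line(raw, ref)
    if line.slope == 0:
        raise DegenerateFitError("zero slope; correction not invertible")
    resid = ref - line.predict(raw)
    return CalibrationFit(
        sensor_id=sensor_id,
        gain=1.0 / line.slope,
        offset=-line.intercept / line.slope,
        residual_sd=float(resid.std(ddof=1)) if resid.size > 2 else float(resid.std(ddof=0)),
        n_windows=len(windows),
    )


def apply_calibration(series, fit: CalibrationFit):
    """Elementwise correction: (raw - offset) / gain."""
    if fit.gain == 0:
        raise DegenerateFitError("fit has zero gain")
    return (np.asarray(series, dtype=float) - fit.offset) / fit.gain
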