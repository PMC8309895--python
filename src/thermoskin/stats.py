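"""Small shared statistics helpers (t-based unadjusted intervals, OLS)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["LineFit", "fit_line", "summarize_mean_ci"]


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_line(x, y) -> LineFit:
    """Ordinary least squares of y on x with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points for a line fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: predictor has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return LineFit(float(slope), float(intercept), float(r2), int(x.size))


def summarize_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with an unadjusted two-sided t-interval (df = n - 1).

    Returns ``(mean, ci_low, ci_high)``; requires n >= 2.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("CI undefined for n < 2")
    mean = float(values.mean())
    se = float(values.std(ddof=1)) / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df=n - 1))
    return mean, mean - tcrit * se, mean + tcrit * se
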