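"""Inverse-prediction inter-sensor comparison machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoskin.comparison import (
    AnchorSet,
    SensorReferenceFit,
    compute_anchors,
    fit_sensor_to_reference,
    intersensor_differences,
    inverse_predict,
)


def make_fit(b0, b1, sensor_id="s"):
    return SensorReferenceFit(sensor_id, b0, b1, 1.0, 0.0, 5, True)


def test_identity_data_fit():
    x = np.array([24.0, 28.0, 32.0, 36.0, 40.0])
    fit = fit_sensor_to_reference(x, x)
    assert fit.b0 == pytest.approx(0.0, abs=1e-12)
    assert fit.b1 == pytest.approx(1.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_collinear_points_recovered_exactly():
    x = np.array([24.0, 28.0, 32.0, 36.0, 40.0])
    fit = fit_sensor_to_reference(x, 2.0 + 1.1 * x)
    assert fit.b0 == pytest.approx(2.0, abs=1e-9)
    assert fit.b1 == pytest.approx(1.1, abs=1e-12)
    assert fit.typical_error == pytest.approx(0.0, abs=1e-9)


def test_default_design_fit_quality(default_bundle):
    """Simulated sensor-vs-reference relations are highly linear."""
    fits = default_bundle.sensor_fits
    assert (fits.r_squared > 0.99).all()
    assert fits.quality_flag.all()


def test_degenerate_predictor_rejected():
    with pytest.raises(ValueError):
        fit_sensor_to_reference([30.0, 30.0, 30.0], [29.0, 30.0, 31.0])


def test_anchor_computation():
    means = {"BR": 33.0, "FL1": 34.0}
    anchors = compute_anchors(means, [make_fit(0.0, 1.0)])
    assert anchors.values == (33.0, 34.0)
    anchors = compute_anchors({"BR": 33.0}, [make_fit(-2.0, 1.05)])
    assert anchors.values[0] == pytest.approx(32.65)
    # Several custom fits: mean of per-sensor predictions.
    anchors = compute_anchors({"BR": 33.0}, [make_fit(0.0, 1.0), make_fit(1.0, 1.0)])
    assert anchors.values[0] == pytest.approx(33.5)
    with pytest.raises(ValueError):
        compute_anchors({"BR": float("nan")}, [make_fit(0.0, 1.0)])


def test_anchor_order_preserved():
    means = {p: 30.0 + i for i, p in enumerate("ABCDEFG")}
    anchors = compute_anchors(means, [make_fit(0.0, 1.0)])
    assert anchors.periods == tuple("ABCDEFG")
    assert anchors.values == tuple(30.0 + i for i in range(7))


def test_inverse_prediction_arithmetic():
    assert inverse_predict(make_fit(0.0, 1.0), 32.0) == 32.0
    assert inverse_predict(make_fit(-2.0, 1.05), 32.0) == pytest.approx(32.3809524, abs=1e-6)
    with pytest.raises(ZeroDivisionError):
        inverse_predict(make_fit(1.0, 0.0), 32.0)


@given(b0=st.floats(-5, 5), b1=st.floats(0.5, 2.0), x=st.floats(20, 45))
@settings(max_examples=100, deadline=None)
def test_forward_then_inverse_is_identity(b0, b1, x):
    fit = make_fit(b0, b1)
    assert inverse_predict(fit, fit.predict(x)) == pytest.approx(x, abs=1e-12)


def anchors7():
    return AnchorSet(
        periods=tuple(f"P{i}" for i in range(7)),
        values=tuple(30.0 + 0.5 * i for i in range(7)),
    )


def test_identical_fits_give_zero_differences():
    fits = {t: {r: make_fit(0.5, 1.02) for r in range(1, 6)}
            for t in ("custom", "grant", "ibutton")}
    for d in intersensor_differences(fits, anchors7()):
        assert d.mean == pytest.approx(0.0, abs=1e-12)
        assert d.n == 5


def test_shared_slope_intercept_shift_gives_constant_difference():
    """With b1 = 1 and type A's b0 shifted +0.2 relative to B, the A-B
    inverse-predicted difference is -0.2 degC at every anchor."""
    fits = {
        "grant": {r: make_fit(0.2, 1.0) for r in range(1, 6)},
        "custom": {r: make_fit(0.0, 1.0) for r in range(1, 6)},
        "ibutton": {r: make_fit(0.0, 1.0) for r in range(1, 6)},
    }
    for d in intersensor_differences(fits, anchors7()):
        if d.pair == "grant-custom":
            assert d.mean == pytest.approx(-0.2, abs=1e-12)


def test_anchor_invariance_under_common_reading_shift():
    """Adding a constant to every sensor's readings shifts all inverse
    predictions equally and leaves inter-sensor differences unchanged."""
    rng = np.random.default_rng(3)
    base = {
        t: {r: make_fit(rng.normal(0, 1), rng.uniform(0.9, 1.1))
            for r in range(1, 6)}
        for t in ("custom", "grant", "ibutton")
    }
    # A shift c of readings X maps the fit Y = b0 + b1*X onto
    # Y = (b0 - b1*c) + b1*(X + c).
    c = 0.7
    shifted = {
        t: {r: make_fit(f.b0 - f.b1 * c, f.b1) for r, f in by_rep.items()}
        for t, by_rep in base.items()
    }
    d0 = intersensor_differences(base, anchors7())
    d1 = intersensor_differences(shifted, anchors7())
    for a, b in zip(d0, d1):
        assert b.mean == pytest.approx(a.mean, abs=1e-9)


def test_unbalanced_replicates_rejected():
    fits = {
        "grant": {r: make_fit(0.0, 1.0) for r in range(1, 6)},
        "custom": {r: make_fit(0.0, 1.0) for r in range(1, 5)},
        "ibutton": {r: make_fit(0.0, 1.0) for r in range(1, 6)},
    }
    with pytest.raises(ValueError, match="unbalanced"):
        intersensor_differences(fits, anchors7())


def test_null_simulation_ci_coverage():
    """With no systematic inter-sensor offset, the 95% interval on the
    n=5 replicate mean difference contains zero in ~95% of repetitions."""
    from thermoskin.stats import summarize_mean_ci

    rng = np.random.default_rng(777)
    reps = 1000
    hits = 0
    for _ in range(reps):
        diffs = rng.normal(0.0, 0.05, size=5)
        _, lo, hi = summarize_mean_ci(diffs)
        hits += lo <= 0.0 <= hi
    assert abs(hits / reps - 0.95) <= 0.03
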