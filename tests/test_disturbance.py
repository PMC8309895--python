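"""Disturbance, the two bias forms, gradient fits, fixed-point summaries."""

import numpy as np
import pytest

from thermoskin.disturbance import (
    MatchingError,
    PairedSteadyState,
    compute_bias,
    compute_disturbance,
    evaluate_at_fixed_sensor_temp,
    fit_vs_gradient,
    match_undisturbed,
    summarize_mean_ci,
)


def state_dict(coverage="grant+tape", velocity=0.5, rep=1, step=1,
               setpoint=40.0, **kw):
    d = {
        "coverage": coverage, "air_velocity": velocity, "replicate": rep,
        "step": step, "plate_setpoint": setpoint, "ambient": 23.8,
    }
    d.update(kw)
    return d


def test_pairing_by_identity_when_bare_replicate_exists():
    disturbed = [state_dict(rep=2, step=3, T_d=33.0, T_sen=32.0)]
    bare = [
        state_dict(coverage="bare", rep=2, step=3, T_u=33.4),
        state_dict(coverage="bare", rep=1, step=3, T_u=99.0),
    ]
    (pair,) = match_undisturbed(disturbed, bare)
    assert pair.t_u == 33.4
    assert pair.disturbance == pytest.approx(-0.4)


def test_pairing_interpolates_against_plate_setpoint():
    disturbed = [state_dict(rep=3, step=2, setpoint=35.0, T_d=32.0, T_sen=31.0)]
    bare = [
        state_dict(coverage="bare", rep=1, step=1, setpoint=30.0, T_u=28.0),
        state_dict(coverage="bare", rep=1, step=2, setpoint=40.0, T_u=34.0),
    ]
    (pair,) = match_undisturbed(disturbed, bare)
    assert pair.t_u == pytest.approx(31.0)  # midpoint of 28 and 34


def test_missing_velocity_raises_listing_runs():
    disturbed = [state_dict(velocity=0.2, T_d=33.0)]
    bare = [state_dict(coverage="bare", velocity=0.5, T_u=33.0)]
    with pytest.raises(MatchingError, match="0.2"):
        match_undisturbed(disturbed, bare)


def test_disturbance_arithmetic_at_printed_operating_points():
    assert compute_disturbance(33.0, 33.0) == 0.0
    # Un-taped iButton at 0.5 m/s: T_d 33.3 vs matched T_u 34.2.
    assert compute_disturbance(33.3, 34.2) == pytest.approx(-0.9)
    # Custom thermistor + tape at 0.2 m/s: T_d 31.4 vs T_u 31.3.
    assert compute_disturbance(31.4, 31.3) == pytest.approx(0.1)


def test_bias_arithmetic_at_printed_operating_points():
    assert compute_bias(31.0, 31.0) == 0.0
    assert compute_bias(31.0, 33.3, "bias_from_Td") == pytest.approx(-2.3)
    assert compute_bias(31.0, 31.3, "bias_from_Tu") == pytest.approx(-0.3)


def test_additivity_identity_on_simulated_pairs(default_bundle):
    """bias_from_Tu = bias_from_Td + disturbance, exactly, per pair."""
    db = default_bundle.disturbance_bias.dropna(subset=["bias_from_Td"])
    resid = db["bias_from_Tu"] - db["bias_from_Td"] - db["disturbance"]
    assert np.abs(resid).max() < 1e-9


def test_zero_gradient_null(default_bundle):
    """At the first step (plate ~ ambient) disturbance and biases vanish
    within 3 noise SDs of a steady-state mean."""
    db = default_bundle.disturbance_bias
    first = db[db.step == 1]
    # Steady-state means average ~48 samples of <=0.03 degC channel noise;
    # differences of corrected surfaces amplify z1-z2 noise ~1.1x, and the
    # quantized iButton adds up to ~0.02 degC, so 3 sigma ~ 0.06 degC.
    assert np.abs(first["disturbance"]).max() < 0.06
    assert np.abs(first["bias_from_Td"].dropna()).max() < 0.06


def test_sign_pattern_of_default_coverages(default_bundle):
    """Warming for tape and custom+tape, cooling for iButton-only and
    Grant+tape, and a velocity-dependent sign flip for iButton+tape."""
    t1 = default_bundle.table1
    d = t1[t1.form == "disturbance"].set_index(["coverage", "air_velocity"])["mean"]
    for vel in (0.2, 0.5):
        assert d["tape_only", vel] > 0
        assert d["custom+tape", vel] > 0
        assert d["ibutton_only", vel] < 0
        assert d["grant+tape", vel] < 0
    assert d["ibutton+tape", 0.2] < 0 < d["ibutton+tape", 0.5]


def test_noiseless_bias_vs_gradient_is_exactly_linear(noiseless_tables):
    tables, _ = noiseless_tables
    db = tables["disturbance_bias"]
    for (cov, vel), grp in db.dropna(subset=["bias_from_Td"]).groupby(
        ["coverage", "air_velocity"]
    ):
        fit = fit_vs_gradient(grp["bias_from_Td"], grp["gradient"])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12), (cov, vel)
        # Zero-gradient equilibrium pins the intercept to zero.
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)


def test_fit_vs_gradient_contracts():
    g = np.array([0.0, 4.0, 8.0, 12.0])
    fit = fit_vs_gradient(-0.1 * g, g)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fit_vs_gradient([1.0, 2.0], [0.0, 1.0])


def make_states(rep_lines, t_sens=(27.0, 29.0, 31.0, 33.0, 35.0)):
    """Each rep_line is (slope, bias_at_31); builds colinear paired states
    with T_d chosen so bias_from_Td follows the line."""
    states = []
    for rep, (slope, b31) in enumerate(rep_lines, start=1):
        for step, x in enumerate(t_sens, start=1):
            bias = b31 + slope * (x - 31.0)
            states.append(
                PairedSteadyState(
                    coverage="ibutton_only", air_velocity=0.5, replicate=rep,
                    step=step, t_sen=x, t_d=x - bias, t_u=x - bias + 0.5,
                    ambient=23.8,
                )
            )
    return states


def test_fixed_point_recovers_generating_line_exactly():
    """Noiseless oracle: states built from a known linear bias(T_sen)
    evaluate at 31 degC to the generating value to 1e-9."""
    states = make_states([(-0.15, -2.3)] * 5)
    summ = evaluate_at_fixed_sensor_temp(states, "bias_from_Td", t_fixed=31.0)
    assert summ.mean == pytest.approx(-2.3, abs=1e-9)
    assert summ.ci_high - summ.ci_low == pytest.approx(0.0, abs=1e-9)
    assert summ.n == 5


def test_fixed_point_ci_from_spread_replicates():
    reps = [(-0.15, b) for b in (-0.5, -0.45, -0.4, -0.35, -0.3)]
    summ = evaluate_at_fixed_sensor_temp(make_states(reps), "bias_from_Td")
    assert summ.mean == pytest.approx(-0.4, abs=1e-12)
    assert summ.ci_low == pytest.approx(-0.49816, abs=1e-4)
    assert summ.ci_high == pytest.approx(-0.30184, abs=1e-4)


def test_fixed_point_single_replicate_has_undefined_ci():
    summ = evaluate_at_fixed_sensor_temp(make_states([(-0.1, -1.0)]), "bias_from_Td")
    assert summ.n == 1
    assert summ.ci_low is None and summ.ci_high is None


def test_summarize_mean_ci_frozen_values():
    mean, lo, hi = summarize_mean_ci([1, 2, 3, 4, 5])
    assert mean == pytest.approx(3.0)
    assert lo == pytest.approx(1.03676, abs=1e-4)
    assert hi == pytest.approx(4.96324, abs=1e-4)
    mean, lo, hi = summarize_mean_ci([0.0, 1.0])
    assert mean == pytest.approx(0.5)
    assert hi - mean == pytest.approx(6.35310, abs=1e-4)  # t(1) = 12.706
    same = summarize_mean_ci([2.0, 2.0, 2.0])
    assert same[1] == same[2] == 2.0
    with pytest.raises(ValueError):
        summarize_mean_ci([1.0])
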