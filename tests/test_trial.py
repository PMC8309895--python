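"""Human-trial calculations: weighted mean, periods, humidity, onset."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoskin.synthetic import simulate_human_trial
from thermoskin.trial import (
    detect_sweat_onset,
    period_means,
    trial_intersensor_differences,
    vapor_pressure,
    weighted_mean_tsk,
)


def test_weighted_mean_arithmetic():
    assert weighted_mean_tsk(33.0, 33.0, 33.0, 33.0) == pytest.approx(33.0)
    assert weighted_mean_tsk(34.0, 33.0, 32.0, 31.0) == pytest.approx(32.7)


def test_weighted_mean_site_order_matters():
    a = weighted_mean_tsk(34.0, 33.0, 32.0, 31.0)
    b = weighted_mean_tsk(31.0, 32.0, 33.0, 34.0)
    assert a != b


@given(shift=st.floats(-3, 3))
@settings(max_examples=40, deadline=None)
def test_weighted_mean_shift_equivariance(shift):
    base = np.array([34.0, 33.0, 32.0, 31.0])
    shifted = weighted_mean_tsk(*(base + shift))
    assert shifted == pytest.approx(weighted_mean_tsk(*base) + shift, abs=1e-9)


def test_weighted_mean_missing_site_rejected():
    with pytest.raises(ValueError, match="thigh"):
        weighted_mean_tsk(33.0, 33.0, float("nan"), 33.0)


def test_period_means_constant_and_ramp():
    t = (10.0 / 60.0) * np.arange(1, 40 * 6 + 1)  # 40 min at 10 s
    const = np.full_like(t, 31.5)
    ramp = 30.0 + 0.1 * t
    out = period_means(const, t, {"BR": (36.0, 39.0)})
    assert out["BR"] == pytest.approx(31.5)
    # Uniform sampling on a ramp: the window mean is the midpoint value
    # (mean of sample times over [36, 39) at 10 s spacing is 37.4167 min).
    out = period_means(ramp, t, {"BR": (36.0, 39.0)})
    mid = np.mean(t[(t >= 36) & (t < 39)])
    assert out["BR"] == pytest.approx(30.0 + 0.1 * mid, abs=1e-12)


def test_period_means_labels_and_bounds():
    t = (10.0 / 60.0) * np.arange(1, 200 * 6 + 1)
    series = np.ones_like(t)
    periods = {f"P{i}": (10.0 * i, 10.0 * i + 3.0) for i in range(1, 8)}
    out = period_means(series, t, periods)
    assert list(out) == [f"P{i}" for i in range(1, 8)]
    with pytest.raises(ValueError, match="outside"):
        period_means(series, t, {"late": (199.0, 202.0)})


def test_vapor_pressure_values():
    assert vapor_pressure(25.0, 0.0) == 0.0
    # Saturation at 20 degC via the Magnus constants used throughout.
    assert vapor_pressure(20.0, 100.0) == pytest.approx(2.3334, abs=1e-3)
    # Linear in relative humidity.
    assert vapor_pressure(30.0, 50.0) == pytest.approx(
        0.5 * vapor_pressure(30.0, 100.0), abs=1e-12
    )
    assert vapor_pressure(30.0, 100.0) == pytest.approx(4.2367, abs=1e-3)
    with pytest.raises(ValueError):
        vapor_pressure(30.0, 120.0)


def make_vp(t, onset_min=None, step=0.6, base=1.5):
    vp = np.full_like(t, base)
    if onset_min is not None:
        vp = vp + step * (t >= onset_min)
    return vp


def test_onset_detection_and_earliest_site_rule():
    t = (10.0 / 60.0) * np.arange(1, 90 * 6 + 1)
    sites = {
        "chest": make_vp(t, 52.0),
        "arm": make_vp(t, 48.0),
        "thigh": make_vp(t),
        "leg": make_vp(t, 60.0),
    }
    onset = detect_sweat_onset(sites, t, exercise_start_min=45.0)
    assert onset.site == "arm"
    assert onset.time_min == pytest.approx(48.0, abs=10.0 / 60.0 + 1e-9)


def test_subthreshold_rise_gives_no_onset():
    t = (10.0 / 60.0) * np.arange(1, 90 * 6 + 1)
    sites = {s: make_vp(t, 50.0, step=0.4) for s in ("chest", "arm", "thigh", "leg")}
    assert detect_sweat_onset(sites, t, 45.0) is None


def test_onset_translation_equivariance():
    t = (10.0 / 60.0) * np.arange(1, 120 * 6 + 1)
    for delta in (0.0, 5.0, 17.5):
        sites = {s: make_vp(t, 50.0 + delta) for s in ("chest", "arm", "thigh", "leg")}
        onset = detect_sweat_onset(sites, t, 45.0)
        assert onset.time_min == pytest.approx(50.0 + delta, abs=10.0 / 60.0 + 1e-9)


def test_brief_spike_not_sustained_is_ignored():
    t = (10.0 / 60.0) * np.arange(1, 90 * 6 + 1)
    vp = make_vp(t)
    spike = (t >= 50.0) & (t < 50.5)  # 30 s, below the 60 s sustain rule
    vp = vp + 0.8 * spike
    sites = {"chest": vp, "arm": make_vp(t), "thigh": make_vp(t), "leg": make_vp(t)}
    assert detect_sweat_onset(sites, t, 45.0) is None


def wm_dict(values):
    """participant -> type -> period -> value from a nested spec."""
    return {
        p: {t: dict(per) for t, per in types.items()} for p, types in values.items()
    }


def test_identical_types_give_zero_differences_zero_width():
    per = {"BR": 33.0, "FL1": 34.0}
    wm = wm_dict({p: {t: per for t in ("custom", "grant", "ibutton")} for p in range(4)})
    for d in trial_intersensor_differences(wm, ["BR", "FL1"]):
        assert d.mean == 0.0
        assert d.ci_low == d.ci_high == 0.0


def test_difference_sign_convention_first_cooler_negative():
    wm = wm_dict({
        p: {
            "custom": {"BR": 33.0},
            "grant": {"BR": 32.8},  # grant cooler
            "ibutton": {"BR": 33.1},
        }
        for p in range(5)
    })
    by_pair = {d.pair: d for d in trial_intersensor_differences(wm, ["BR"])}
    assert by_pair["grant-custom"].mean == pytest.approx(-0.2)
    assert by_pair["ibutton-grant"].mean == pytest.approx(0.3)


def test_difference_antisymmetry():
    rng = np.random.default_rng(12)
    wm = wm_dict({
        p: {t: {"BR": 33.0 + rng.normal(0, 0.2)} for t in ("custom", "grant", "ibutton")}
        for p in range(6)
    })
    fwd = trial_intersensor_differences(wm, ["BR"], pairs=(("grant", "custom"),))
    rev = trial_intersensor_differences(wm, ["BR"], pairs=(("custom", "grant"),))
    assert fwd[0].mean == pytest.approx(-rev[0].mean, abs=1e-12)


def test_injected_type_offsets_recovered_with_ci_coverage():
    """Monte-Carlo oracle: sensor-type offsets (+0.2, 0, -0.1) injected at
    the participant level are covered by the 95% interval >= 95% of the
    time (500 reps, n = 14)."""
    rng = np.random.default_rng(99)
    offsets = {"custom": 0.0, "grant": -0.1, "ibutton": 0.2}
    truth = {
        "grant-custom": offsets["grant"] - offsets["custom"],
        "ibutton-custom": offsets["ibutton"] - offsets["custom"],
        "ibutton-grant": offsets["ibutton"] - offsets["grant"],
    }
    reps, hits, total = 500, 0, 0
    for _ in range(reps):
        wm = wm_dict({
            p: {
                t: {"BR": 33.0 + rng.normal(0, 0.3) + offsets[t] + rng.normal(0, 0.1)}
                for t in offsets
            }
            for p in range(14)
        })
        for d in trial_intersensor_differences(wm, ["BR"]):
            total += 1
            hits += d.ci_low <= truth[d.pair] <= d.ci_high
    assert hits / total >= 0.93


def test_full_generator_offsets_flow_through_to_differences():
    """End-to-end: offsets injected in the generator appear in the
    trial-level mean differences."""
    from thermoskin.pipeline import analyze_trial

    ds = simulate_human_trial(
        n_participants=8, seed=21,
        sensor_offsets={"custom": 0.0, "grant": -0.15, "ibutton": 0.20},
    )
    analysis = analyze_trial(ds)
    by_pair = {}
    for d in analysis.differences:
        by_pair.setdefault(d.pair, []).append(d.mean)
    assert np.mean(by_pair["grant-custom"]) == pytest.approx(-0.15, abs=0.08)
    assert np.mean(by_pair["ibutton-custom"]) == pytest.approx(0.20, abs=0.08)
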