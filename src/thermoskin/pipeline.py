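"""End-to-end orchestration: simulate the full rig design, extract and
surface-correct steady states, compute disturbance/bias tables and
fixed-operating-point summaries, fit sensors to the undisturbed
reference, and run the inverse-prediction inter-sensor comparison
anchored to a simulated human trial.

The full design is 6 coverage conditions x 5 replicates x 2 air
velocities = 60 runs.  Everything is deterministic under a fixed master
seed: per-run seeds are derived from the master seed via a seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import disturbance as dist
from . import steady_state as ss
from . import trial as trial_mod
from .network import (
    COVERAGE_NAMES,
    COVERAGE_SENSOR,
    MaterialProps,
    default_coverages,
    default_material,
    default_rig_config,
    default_sensors,
)
from .synthetic import (
    RigRun,
    TrialDataset,
    simulate_human_trial,
    simulate_rig_run,
)

__all__ = [
    "SuiteConfig",
    "ResultsBundle",
    "TrialAnalysis",
    "run_rig_suite",
    "analyze_trial",
    "analyze_runs",
    "write_results",
    "TRIAL_SUMMARY_PERIODS",
]

#: Fixed 3-min summary windows (minutes from trial start); FL1-PS is
#: participant-specific (the 3 min immediately preceding sweat onset).
TRIAL_SUMMARY_PERIODS = {
    "BR": (36.0, 39.0),
    "FL1": (57.0, 60.0),
    "FL2": (72.0, 75.0),
    "FL3": (87.0, 90.0),
    "RR-M": (112.0, 115.0),
    "RR-E": (131.0, 134.0),
}

PERIOD_ORDER = ("BR", "FL1-PS", "FL1", "FL2", "FL3", "RR-M", "RR-E")


@dataclass(frozen=True)
class SuiteConfig:
    """Design of a full rig suite."""

    coverages: tuple[str, ...] = COVERAGE_NAMES
    velocities: tuple[float, ...] = (0.2, 0.5)
    replicates: int = 5
    noiseless: bool = False
    t_fixed: float = 31.0
    n_participants: int = 14

    def __post_init__(self) -> None:
        if "bare" not in self.coverages:
            raise ValueError("design must include the bare coverage (reference)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class TrialAnalysis:
    """Derived human-trial quantities."""

    weighted_means: dict[int, dict[str, dict[str, float]]]
    onsets: dict[int, float]
    differences: list[trial_mod.InterSensorDifference]
    custom_group_means: dict[str, float]


@dataclass
class ResultsBundle:
    """All tables produced by one suite run, plus provenance metadata."""

    manifest: pd.DataFrame
    steady_states: pd.DataFrame
    disturbance_bias: pd.DataFrame
    table1: pd.DataFrame
    sensor_fits: pd.DataFrame
    comparison: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _child_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def simulate_design(
    config: SuiteConfig,
    master_seed: int,
    material: MaterialProps | None = None,
) -> tuple[list[RigRun], pd.DataFrame]:
    """Simulate every run of the design with seeds derived from the master."""
    material = material or default_material()
    coverages = default_coverages()
    sensors = default_sensors()
    if config.noiseless:
        # Noiseless mode serves exact steady-state oracles, so sensor lag
        # is dropped along with noise and quantization.
        sensors = {
            k: type(v)(v.sensor_type, resolution=0.0, noise_sd=0.0,
                       response_time=0.0)
            for k, v in sensors.items()
        }

    combos = [
        (cov, vel, rep)
        for vel in config.velocities
        for rep in range(1, config.replicates + 1)
        for cov in config.coverages
    ]
    seeds = _child_seeds(master_seed, len(combos))
    runs: list[RigRun] = []
    rows = []
    for (cov, vel, rep), seed in zip(combos, seeds):
        rig_cfg = default_rig_config(air_velocity=vel, seed=seed, material=material)
        run = simulate_rig_run(
            material, coverages[cov], rig_cfg, sensors, seed=seed, replicate=rep
        )
        runs.append(run)
        rows.append(
            {
                "run_id": run.run_id(),
                "coverage": cov,
                "air_velocity": vel,
                "replicate": rep,
                "seed": seed,
                "warnings": "; ".join(run.warnings),
            }
        )
    return runs, pd.DataFrame(rows)


def analyze_runs(runs: list[RigRun], t_fixed: float = 31.0) -> dict[str, pd.DataFrame]:
    """Steady states -> surface correction -> matching -> disturbance/bias
    tables, fixed-point summaries and per-sensor reference fits."""
    state_rows = []
    disturbed_states = []
    bare_states = []
    for run in runs:
        for state in ss.extract_step_means(run):
            row = {
                "run_id": state.run_id,
                "coverage": state.coverage,
                "air_velocity": state.air_velocity,
                "replicate": state.replicate,
                "step": state.step,
                "plate_setpoint": state.plate_setpoint,
                "qualified": state.qualified,
                "reason": state.reason,
            }
            if state.qualified:
                corr = ss.corrected_reference_temps(state, run)
                row.update(
                    {
                        "T_sen": state.means.get("T_sen"),
                        "ambient": state.means["ambient"],
                        **corr,
                    }
                )
                base = {
                    "coverage": state.coverage,
                    "air_velocity": state.air_velocity,
                    "replicate": state.replicate,
                    "step": state.step,
                    "plate_setpoint": state.plate_setpoint,
                    "ambient": state.means["ambient"],
                }
                if state.coverage == "bare":
                    bare_states.append({**base, "T_u": corr["T_u"]})
                else:
                    disturbed_states.append(
                        {**base, "T_d": corr["T_d"], "T_sen": state.means.get("T_sen")}
                    )
            for ch in sorted(state.means):
                row[f"mean_{ch}"] = state.means[ch]
                row[f"sd_{ch}"] = state.sds[ch]
            state_rows.append(row)

    paired = dist.match_undisturbed(disturbed_states, bare_states)

    db_rows = []
    for p in paired:
        row = {
            "coverage": p.coverage,
            "air_velocity": p.air_velocity,
            "replicate": p.replicate,
            "step": p.step,
            "T_sen": p.t_sen,
            "T_d": p.t_d,
            "T_u": p.t_u,
            "ambient": p.ambient,
            "gradient": p.gradient,
            "disturbance": p.disturbance,
        }
        if p.t_sen is not None:
            row["bias_from_Td"] = p.bias("bias_from_Td")
            row["bias_from_Tu"] = p.bias("bias_from_Tu")
        db_rows.append(row)

    # Fixed-operating-point summaries per coverage x velocity x form.
    t1_rows = []
    by_cond: dict[tuple[str, float], list[dist.PairedSteadyState]] = {}
    for p in paired:
        by_cond.setdefault((p.coverage, p.air_velocity), []).append(p)
    for (cov, vel), states in sorted(by_cond.items()):
        forms = ["disturbance"]
        if COVERAGE_SENSOR[cov] is not None:
            forms += list(dist.BIAS_FORMS)
        for form in forms:
            summ = dist.evaluate_at_fixed_sensor_temp(states, form, t_fixed=t_fixed)
            t1_rows.append(
                {
                    "coverage": cov,
                    "air_velocity": vel,
                    "form": form,
                    "evaluated_at": summ.evaluated_at,
                    "mean": summ.mean,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                    "n": summ.n,
                }
            )

    # Per-individual-sensor fits against the matched undisturbed reference.
    fit_rows = []
    by_sensor: dict[tuple[str, float, int], list[dist.PairedSteadyState]] = {}
    for p in paired:
        if p.t_sen is not None:
            by_sensor.setdefault((p.coverage, p.air_velocity, p.replicate), []).append(p)
    for (cov, vel, rep), states in sorted(by_sensor.items()):
        x = [s.t_sen for s in states]
        y = [s.t_u for s in states]
        fit = cmp.fit_sensor_to_reference(x, y, sensor_id=f"{cov}_v{vel:g}_r{rep}")
        fit_rows.append(
            {
                "sensor_id": fit.sensor_id,
                "coverage": cov,
                "air_velocity": vel,
                "replicate": rep,
                "b0": fit.b0,
                "b1": fit.b1,
                "r_squared": fit.r_squared,
                "typical_error": fit.typical_error,
                "n": fit.n,
                "quality_flag": fit.quality_flag,
            }
        )

    return {
        "steady_states": pd.DataFrame(state_rows),
        "disturbance_bias": pd.DataFrame(db_rows),
        "table1": pd.DataFrame(t1_rows),
        "sensor_fits": pd.DataFrame(fit_rows),
    }


def trial_period_windows(onset_min: float) -> dict[str, tuple[float, float]]:
    """The seven 3-min summary windows given a participant's sweat onset."""
    windows = dict(TRIAL_SUMMARY_PERIODS)
    windows["FL1-PS"] = (onset_min - 3.0, onset_min)
    return {label: windows[label] for label in PERIOD_ORDER}


def analyze_trial(dataset: TrialDataset) -> TrialAnalysis:
    """Weighted means, sweat onsets, period means, inter-sensor differences."""
    weighted: dict[int, dict[str, dict[str, float]]] = {}
    onsets: dict[int, float] = {}
    for p in dataset.participants:
        vp_by_site = {
            site: trial_mod.vapor_pressure(
                dataset.site_temp[p][site], dataset.rh[p][site]
            )
            for site in dataset.rh[p]
        }
        onset = trial_mod.detect_sweat_onset(
            vp_by_site, dataset.time_min, dataset.exercise_start_min
        )
        if onset is None:
            continue  # excluded: no detectable sweating
        onsets[p] = onset.time_min
        windows = trial_period_windows(onset.time_min)
        weighted[p] = {}
        for stype, by_site in dataset.tsk[p].items():
            wm = trial_mod.weighted_mean_tsk(
                by_site["chest"], by_site["arm"], by_site["thigh"], by_site["leg"]
            )
            weighted[p][stype] = trial_mod.period_means(wm, dataset.time_min, windows)

    differences = trial_mod.trial_intersensor_differences(weighted, list(PERIOD_ORDER))
    custom_group_means = {
        period: float(np.mean([weighted[p]["custom"][period] for p in weighted]))
        for period in PERIOD_ORDER
    }
    return TrialAnalysis(
        weighted_means=weighted,
        onsets=onsets,
        differences=differences,
        custom_group_means=custom_group_means,
    )


def run_rig_suite(
    master_seed: int = 0,
    config: SuiteConfig | None = None,
    material: MaterialProps | None = None,
) -> ResultsBundle:
    """Execute the full design and assemble every results table."""
    config = config or SuiteConfig()
    runs, manifest = simulate_design(config, master_seed, material)
    tables = analyze_runs(runs, t_fixed=config.t_fixed)

    # Human trial supplies the anchors for the inter-sensor comparison.
    trial_seed = _child_seeds(master_seed + 1, 1)[0]
    dataset = simulate_human_trial(n_participants=config.n_participants, seed=trial_seed)
    trial_an = analyze_trial(dataset)

    comp_rows = [
        {
            "pair": d.pair,
            "period": d.period,
            "source": "human",
            "mean": d.mean,
            "ci_low": d.ci_low,
            "ci_high": d.ci_high,
            "n": d.n,
        }
        for d in trial_an.differences
    ]

    fits = tables["sensor_fits"]
    model_coverage = {"custom": "custom+tape", "grant": "grant+tape", "ibutton": "ibutton+tape"}
    for vel in config.velocities:
        fits_by_type: dict[str, dict[int, cmp.SensorReferenceFit]] = {}
        for stype, cov in model_coverage.items():
            sub = fits[(fits.coverage == cov) & (fits.air_velocity == vel)]
            fits_by_type[stype] = {
                int(r.replicate): cmp.SensorReferenceFit(
                    sensor_id=r.sensor_id, b0=r.b0, b1=r.b1,
                    r_squared=r.r_squared, typical_error=r.typical_error,
                    n=int(r.n), quality_flag=bool(r.quality_flag),
                )
                for r in sub.itertuples()
            }
        anchors = cmp.compute_anchors(
            trial_an.custom_group_means, list(fits_by_type["custom"].values())
        )
        for d in cmp.intersensor_differences(fits_by_type, anchors):
            comp_rows.append(
                {
                    "pair": d.pair,
                    "period": d.period,
                    "source": f"model-{vel:g}",
                    "mean": d.mean,
                    "ci_low": d.ci_low,
                    "ci_high": d.ci_high,
                    "n": d.n,
                }
            )

    metadata = {
        "master_seed": master_seed,
        "design": {
            "coverages": list(config.coverages),
            "velocities": list(config.velocities),
            "replicates": config.replicates,
            "n_runs": len(runs),
            "noiseless": config.noiseless,
        },
        "t_fixed": config.t_fixed,
        "decisions": {
            "fixed_point_machinery": "per-replicate linear fit of bias vs sensor "
            "temperature, evaluated at t_fixed, summarized over replicates",
            "anchor_aggregation": "anchors average the per-sensor predictions of "
            "the individual custom-thermistor fits",
            "gradient_definition": "undisturbed surface temperature minus ambient",
        },
    }
    return ResultsBundle(
        manifest=manifest,
        steady_states=tables["steady_states"],
        disturbance_bias=tables["disturbance_bias"],
        table1=tables["table1"],
        sensor_fits=tables["sensor_fits"],
        comparison=pd.DataFrame(comp_rows),
        metadata=metadata,
    )


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write every table as CSV plus a YAML metadata file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("manifest", "steady_states", "disturbance_bias", "table1",
                 "sensor_fits", "comparison"):
        path = out_dir / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    meta_path = out_dir / "metadata.yaml"
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.metadata, fh, sort_keys=True)
    written.append(meta_path)
    return written
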