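"""CSV and manifest I/O for rig runs and trial datasets.

Dialect: RFC-4180 comma-separated, dot decimal, UTF-8, mandatory header,
elapsed seconds in the first column.  Temperatures are stored at 1e-4 degC
precision so storage never adds quantization beyond the loggers' own.
Run metadata travels in a YAML sidecar manifest next to the CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import RigConfig, ValidationError
from .synthetic import RigRun, TrialDataset

__all__ = [
    "write_run_csv",
    "load_run_csv",
    "write_trial_csv",
    "manifest_path",
]

KNOWN_CHANNELS = {
    "T_sen",
    "T_z1_disturbed",
    "T_z2_disturbed",
    "T_z1_undisturbed",
    "T_z2_undisturbed",
    "ambient",
}

FLOAT_FMT = "%.4f"


def manifest_path(csv_path: str | os.PathLike) -> Path:
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".manifest.yaml")


def write_run_csv(run: RigRun, path: str | os.PathLike) -> Path:
    """Write a rig run plus its sidecar manifest; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns = {"elapsed_s": run.timestamps}
    for name in sorted(run.channels):
        columns[name] = run.channels[name]
    pd.DataFrame(columns).to_csv(path, index=False, float_format=FLOAT_FMT)

    cfg = run.config
    manifest = {
        "coverage": run.coverage,
        "air_velocity": run.air_velocity,
        "replicate": run.replicate,
        "seed": run.seed,
        "warnings": list(run.warnings),
        "config": {
            "ambient_temp": cfg.ambient_temp,
            "ambient_rh": cfg.ambient_rh,
            "air_velocity": cfg.air_velocity,
            "plate_setpoints": [float(s) for s in cfg.plate_setpoints],
            "step_duration": cfg.step_duration,
            "sample_interval": cfg.sample_interval,
            "z1": cfg.z1,
            "z2": cfg.z2,
            "seed": cfg.seed,
        },
    }
    with open(manifest_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_run_csv(path: str | os.PathLike) -> RigRun:
    """Read a rig run CSV and its sidecar manifest back into a RigRun.

    Raises on ragged rows (with the offending line), non-monotonic or
    duplicated timestamps, and unknown channel names.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    if frame.columns[0] != "elapsed_s":
        raise ValidationError(f"{path}: first column must be 'elapsed_s'")
    unknown = set(frame.columns[1:]) - KNOWN_CHANNELS
    if unknown:
        raise ValidationError(f"{path}: unknown channels {sorted(unknown)}")
    ts = frame["elapsed_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(ts) <= 0)
    if bad.size:
        # +2: one for the header row, one for 0- vs 1-based line numbers.
        raise ValidationError(
            f"{path}: non-increasing timestamp at line {int(bad[0]) + 3}"
        )

    mpath = manifest_path(path)
    if not mpath.exists():
        raise ValidationError(f"manifest not found: {mpath}")
    with open(mpath, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    cfg_d = dict(manifest["config"])
    cfg_d["plate_setpoints"] = tuple(cfg_d["plate_setpoints"])
    config = RigConfig(**cfg_d)

    channels = {
        name: frame[name].to_numpy(dtype=float) for name in frame.columns[1:]
    }
    return RigRun(
        coverage=manifest["coverage"],
        air_velocity=manifest["air_velocity"],
        replicate=manifest["replicate"],
        seed=manifest["seed"],
        timestamps=ts,
        channels=channels,
        config=config,
        warnings=list(manifest.get("warnings", [])),
    )


def write_trial_csv(dataset: TrialDataset, path: str | os.PathLike) -> Path:
    """Write a trial dataset in long format (one row per sample/channel)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    elapsed = dataset.time_min * 60.0
    for p in dataset.participants:
        for stype, by_site in dataset.tsk[p].items():
            for site, series in by_site.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "elapsed_s": elapsed,
                            "participant": p,
                            "channel": f"tsk_{stype}_{site}",
                            "value": series,
                        }
                    )
                )
        for site in dataset.rh[p]:
            rows.append(
                pd.DataFrame(
                    {
                        "elapsed_s": elapsed,
                        "participant": p,
                        "channel": f"rh_{site}",
                        "value": dataset.rh[p][site],
                    }
                )
            )
            rows.append(
                pd.DataFrame(
                    {
                        "elapsed_s": elapsed,
                        "participant": p,
                        "channel": f"temp_{site}",
                        "value": dataset.site_temp[p][site],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)
    manifest = {
        "seed": dataset.seed,
        "exercise_start_min": dataset.exercise_start_min,
        "sensor_offsets": dataset.sensor_offsets,
        "periods": [
            {"label": p.label, "start": p.start, "end": p.end, "activity": p.activity}
            for p in dataset.periods
        ],
    }
    with open(manifest_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
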