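import numpy as np
import pytest

from thermoskin.network import (
    default_coverages,
    default_material,
    default_rig_config,
    default_sensors,
)
from thermoskin.pipeline import SuiteConfig, analyze_runs, run_rig_suite, simulate_design
from thermoskin.synthetic import simulate_human_trial, simulate_rig_run


@pytest.fixture(scope="session")
def material():
    return default_material()


@pytest.fixture(scope="session")
def coverages():
    return default_coverages()


@pytest.fixture(scope="session")
def sensors():
    return default_sensors()


@pytest.fixture(scope="session")
def noiseless_sensors(sensors):
    return {
        k: type(v)(v.sensor_type, resolution=0.0, noise_sd=0.0,
                   response_time=0.0)
        for k, v in sensors.items()
    }


@pytest.fixture(scope="session")
def default_bundle():
    """Full 6 x 5 x 2 design analyzed once for the whole session."""
    return run_rig_suite(master_seed=20210719)


@pytest.fixture(scope="session")
def noiseless_tables():
    """Noiseless single-replicate design: exact network-level oracles."""
    cfg = SuiteConfig(replicates=1, noiseless=True)
    runs, _ = simulate_design(cfg, master_seed=0)
    return analyze_runs(runs), runs


@pytest.fixture(scope="session")
def trial_dataset():
    return simulate_human_trial(n_participants=6, seed=42)


@pytest.fixture()
def bare_run(material, coverages, sensors):
    cfg = default_rig_config(air_velocity=0.5, seed=7)
    return simulate_rig_run(material, coverages["bare"], cfg, sensors, seed=7)
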