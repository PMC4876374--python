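import numpy as np
import pytest

from cardiometa import (
    AnalysisConfig,
    SimConfig,
    make_control_cohort,
    make_table1_cohort,
    simulate_subject,
    write_trials,
)


@pytest.fixture(scope="session")
def table1_cohort():
    return make_table1_cohort()


@pytest.fixture(scope="session")
def control_cohort():
    return make_control_cohort()


@pytest.fixture()
def table1_trials_file(tmp_path, table1_cohort):
    path = tmp_path / "trials.csv"
    write_trials(table1_cohort, path)
    return path


@pytest.fixture(scope="session")
def ideal_observer_10k():
    """Zero-metacognitive-noise observer, d' = 1.5, 10,000 trials."""
    cfg = SimConfig(n_trials=10_000, d_prime_gen=1.5, c_gen=0.0,
                    sigma_meta=0.0, seed=11)
    return cfg, simulate_subject(cfg, 11, with_counting=False)


@pytest.fixture()
def fast_config():
    return AnalysisConfig(seed=5, n_restarts=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
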