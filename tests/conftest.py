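import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hdps import AnalysisConfig, SimConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    """A fast generator configuration for structural (non-statistical) tests."""
    return SimConfig(n_patients=2000, n_true_confounder_codes=4,
                     n_instrument_codes=1, n_noise_codes=5, seed=7)


@pytest.fixture(scope="session")
def small_study(small_sim):
    """Cohort, events and mapping tables for the small configuration."""
    from hdps import synthetic
    cohort = synthetic.generate_cohort(small_sim)
    events = synthetic.emit_code_events(cohort, small_sim)
    tables = synthetic.make_mapping_tables(small_sim)
    return cohort, events, tables


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


def toy_events(rows) -> pd.DataFrame:
    """Build a code-event frame from (patient_id, dimension, raw_code, day)."""
    return pd.DataFrame(rows, columns=["patient_id", "dimension", "raw_code",
                                       "event_date"])


def toy_mapped(rows) -> pd.DataFrame:
    """Build a mapped-event frame from (patient_id, dimension, code, day)."""
    df = pd.DataFrame(rows, columns=["patient_id", "dimension",
                                     "harmonized_code", "event_date"])
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
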