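import numpy as np
import pandas as pd
import pytest

from csfmark.core import IntensityMatrix
from csfmark.simulate import SimConfig, simulate_cohort

TINY = SimConfig(
    n_patients=6,
    schedule=(0, 2, 10, 18),
    patients_per_timepoint=(6, 6, 6, 5),
    n_proteins_tmt=80,
    n_proteins_lfq=30,
    n_shared=28,
    n_planted_deps=6,
    n_coupled=3,
    n_low_quality_samples=1,
    missing_rate=0.06,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return TINY


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """Small simulated cohort shared across tests (read-only)."""
    return simulate_cohort(tiny_config, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full default size (read-only)."""
    return simulate_cohort(SimConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250929)


def make_matrix(values, platform="TMT", scale="raw", proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(values, index=proteins, columns=samples), platform=platform, scale=scale
    )


def make_meta(samples, patients, timepoints, platform="TMT", schedule=(0, 2, 10, 18, 26, 34, 42)):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": patients,
            "timepoint_months": timepoints,
            "platform": platform,
            "batch_id": "b1",
        }
    )
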