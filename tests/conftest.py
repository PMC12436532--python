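import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from drowsecov.config import SimulationConfig, VisualScoringParams
from drowsecov.features import FEATURES, EpochFeatureMatrix
from drowsecov.pipeline import run_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_config():
    """A desk-scale cohort config: short sessions, quick to generate."""
    return SimulationConfig(
        n_subjects=2,
        session_length=300.0,
        episode_duration_range_wakeful=(40.0, 70.0),
        episode_duration_range_drowsy=(35.0, 60.0),
        seed=7,
    )


@pytest.fixture
def scoring_params():
    return VisualScoringParams()


@pytest.fixture(scope="session")
def recovery_config():
    """Cohort conditions for the channel-recovery study: drowsy theta x2 /
    alpha x0.5 on all channels, SNR boosted on F4 (lower noise scale)."""
    return SimulationConfig(
        n_subjects=10,
        session_length=600.0,
        episode_duration_range_wakeful=(60.0, 120.0),
        episode_duration_range_drowsy=(45.0, 90.0),
        channel_noise_scale={"F4": 0.3},
        seed=1,
    )


@pytest.fixture(scope="session")
def cohort(recovery_config):
    """(runs, summary) of the full pipeline on the recovery cohort."""
    return run_cohort(recovery_config)


def make_matrix(values, labels, subject="S00", channel="F4") -> EpochFeatureMatrix:
    """Feature matrix whose every column equals ``values`` (test helper)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({f: values for f in FEATURES})
    return EpochFeatureMatrix(
        subject_id=subject,
        channel_name=channel,
        raw=df.copy(),
        normalized=df.copy(),
        labels=np.asarray(labels, dtype=int),
    )
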