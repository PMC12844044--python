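import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from recovermet import MetabolomicsDataset
from recovermet.preprocess import PreprocessConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(values, sample_ids=None, feature_ids=None, phases=None,
                 arms=None, subjects=None, pathways=None):
    """Hand-build a small MetabolomicsDataset for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    phases = phases or ["Pre"] * n
    arms = arms or ["placebo"] * n
    subjects = subjects or [f"subj{i}" for i in range(n)]
    pathways = pathways or ["other"] * p
    return MetabolomicsDataset(
        abundance=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        samples=pd.DataFrame(
            {"subject_id": subjects, "dataset_id": "toy", "arm": arms,
             "phase": phases},
            index=pd.Index(sample_ids, name="sample_id")),
        features=pd.DataFrame(
            {"display_name": feature_ids, "pathway": pathways},
            index=pd.Index(feature_ids, name="feature_id")),
    )


@pytest.fixture
def toy_dataset():
    return make_dataset([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture
def fast_rf_config():
    """Small forest for Monte-Carlo loops; relative RF-vs-median comparisons
    are insensitive to forest size."""
    return PreprocessConfig(rf_trees=30, rf_max_iter=2, seed=0)
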