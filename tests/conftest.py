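"""Shared fixtures: the calibrated study-condition cohort is expensive to
build, so it is generated once per session and reused across modules."""

import numpy as np
import pytest
from hypothesis import settings

import tnsalvage as tn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STUDY_SEED = 42
STUDY_N = 5000

EPOCH_COV_MAP = {
    "hypertension": "early",
    "v1_involved": "late",
    "latent_resistant": "all",
}


@pytest.fixture(scope="session")
def calibrated_config():
    """Default config with hazards and IL-6 coupling calibrated, n=5000."""
    return tn.default_calibrated_config(n=STUDY_N)


@pytest.fixture(scope="session")
def cohort5000(calibrated_config):
    return tn.generate_cohort(calibrated_config, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def analysis_df(cohort5000):
    df = cohort5000.table.copy()
    df["latent_resistant"] = (df["latent_class"] == "resistant").astype(int)
    return df


@pytest.fixture(scope="session")
def epoch_cox_result(analysis_df):
    """Correctly specified epoch-partitioned Cox fit on the study cohort."""
    return tn.epoch_cox(
        analysis_df[["time_to_recurrence", "event", *EPOCH_COV_MAP]],
        cutpoint=2.0,
        covariate_epoch_map=EPOCH_COV_MAP,
    )


@pytest.fixture(scope="session")
def km_curve(analysis_df):
    return tn.km_estimate(
        analysis_df["time_to_recurrence"].to_numpy(),
        analysis_df["event"].to_numpy(),
    )


@pytest.fixture(scope="session")
def indicators5000(cohort5000):
    return tn.discretize_features(cohort5000)


def true_labels(cohort):
    return (cohort.table["latent_class"] == "resistant").astype(int).to_numpy()


@pytest.fixture(scope="session")
def resistant_cohort(calibrated_config):
    """All-resistant cohort for class-specific biomarker checks."""
    import dataclasses

    cfg = dataclasses.replace(calibrated_config, class_mix=1.0)
    return tn.generate_cohort(cfg, seed=STUDY_SEED + 1)


def within_3se(estimate: float, truth: float, se: float) -> bool:
    return abs(estimate - truth) <= 3.0 * se


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
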