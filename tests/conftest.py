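import numpy as np
import pandas as pd
import pytest

from peblkit import (
    FeatureMatrix,
    ProtocolSpec,
    SubjectParams,
    feature_matrices,
    simulate_aligned_cohort,
)
from peblkit.manifest import FEATURE_NAMES
from peblkit.synthetic import CouplingParams, NoiseParams

# Compact protocol for unit tests: full phase structure at minimal length.
SHORT_PROTOCOL = ProtocolSpec(
    baseline_duration_s=120.0,
    hemorrhage_rate_ml_min=120.0,
    hemorrhage_target_pebl=0.35,
    hold_duration_s=120.0,
    wholeblood_volume_ml=300.0,
    wholeblood_rate_ml_min=150.0,
    crystalloid_rate_ml_min=150.0,
    resuscitation_duration_s=300.0,
)


def quiet_params(subject_id="q", heart_rate=75.0, seed=0):
    """Noiseless, coupling-off subject: perfectly periodic PPG."""
    return SubjectParams(
        subject_id=subject_id,
        baseline_heart_rate=heart_rate,
        coupling=CouplingParams(0.0, 0.0, 0.0),
        noise=NoiseParams(0.0, 0.0, 0.0),
        seed=seed,
    )


def make_matrix(X, y, subjects=None):
    """FeatureMatrix from raw arrays, for model-layer tests."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "subject_id", subjects if subjects is not None else ["s0"] * n)
    df.insert(1, "start_s", np.arange(n, dtype=float))
    df.insert(2, "target", np.asarray(y, dtype=float))
    return FeatureMatrix(df=df, window_length_s=5.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 12 subjects, fixed seed."""
    return simulate_aligned_cohort(12, seed=7)


@pytest.fixture(scope="session")
def default_matrix_5s(default_cohort):
    trunc, _ = default_cohort
    return feature_matrices(trunc, (5,))[5]


@pytest.fixture(scope="session")
def default_extended_matrix_5s(default_cohort):
    _, full = default_cohort
    return feature_matrices(full, (5,), target="fluid_balance")[5]


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects on the compact protocol, for fast multi-config runs."""
    return simulate_aligned_cohort(6, seed=11, protocol=SHORT_PROTOCOL)
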