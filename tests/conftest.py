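import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitphase as gp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort_df():
    """Small multi-speed, multi-surface cohort feature matrix."""
    recs = gp.training_cohort(
        seed=11, n_subjects=2, speeds=(1.33, 0.6), surfaces=("LG", "US"), n_strides=2
    )
    return gp.feature_matrix_from_recordings(recs)


@pytest.fixture(scope="session")
def separable_toy():
    """2-feature, 2-class set perfectly separable on feature 0."""
    rng = np.random.default_rng(42)
    n = 80
    x0 = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)])
    x1 = rng.normal(0, 1, n)
    X = np.column_stack([x0, x1])
    y = np.array(["LR"] * (n // 2) + ["PO"] * (n // 2), dtype=object)
    return X, y


@pytest.fixture(scope="session")
def tiny_trained_model(small_cohort_df):
    """LMT trained quickly on the small cohort (fixed boosting budget)."""
    cfg = gp.LMTTrainConfig(num_boosting_iterations=15, seed=0, prune=False)
    return gp.train_lmt(small_cohort_df, config=cfg)


def make_clean_stream(n_strides=5, run_lengths=(12, 14, 9, 11)):
    """A plausible ground-truth label stream: cyclic runs of the 4 phases."""
    out = []
    for _ in range(n_strides):
        for phase, ln in zip(gp.PHASE_ORDER, run_lengths):
            out.extend([phase] * ln)
    return out
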