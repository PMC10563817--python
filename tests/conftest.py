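import numpy as np
import pytest

from eegfusion.model import AttentionConfig, ModelConfig
from eegfusion.study import (
    make_study_subjects,
    run_ablation,
    run_chance,
    run_recovery,
    run_two_factor_comparison,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    """A deliberately tiny architecture for fast unit tests."""
    return ModelConfig(
        feature_dim=8,
        attention=AttentionConfig(n_heads=2, patch_len=50, embed_dim=8,
                                  encoder_depth=1),
        cnn_channels=(3, 4),
        cnn_time_pool=4,
        classifier_hidden=8,
    )


@pytest.fixture(scope="session")
def study_recovery():
    """Ten-fold CV accuracy on the strong-contrast study cohort."""
    return run_recovery(STUDY_SEED)


@pytest.fixture(scope="session")
def study_chance():
    """CV output on the zero-contrast cohort (shared with two-factor checks)."""
    return run_chance(STUDY_SEED)


@pytest.fixture(scope="session")
def study_ablation():
    """Branch/filter ablation table on shared folds."""
    return run_ablation(STUDY_SEED)


@pytest.fixture(scope="session")
def study_two_factor(study_chance):
    out, result, mmse, truth = study_chance
    return run_two_factor_comparison(result, mmse, truth)


@pytest.fixture(scope="session")
def tiny_subjects():
    """A 6-subject preprocessed strong-contrast cohort for training tests."""
    subjects, mmse, truth = make_study_subjects(seed=3, contrast=1.0, n_per_class=2)
    return subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
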