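"""The packaged synthetic validation study.

A fixed, seeded protocol that exercises the whole pipeline end to end on
synthetic cohorts: parameter recovery under strong class contrast, collapse
to chance under zero contrast, branch/filter ablations on shared folds, and
the two-factor (EEG + MMSE) versus EEG-only comparison.  The same protocol
backs ``scripts/acceptance.py`` and the acceptance test suite.

The study uses a scaled-down network (32-dimensional features, one encoder
block, a two-block CNN) and a 12-subject cohort so that full ten-fold
subject-wise cross-validation runs in minutes on one CPU; the package
defaults elsewhere remain the full-size reference settings.  See
``docs/methods.md`` for the rationale behind each number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AttentionConfig, ModelConfig
from .synthetic import CohortConfig, generate_cohort
from .train_eval import (
    CVResult,
    TrainConfig,
    ablation_run,
    cross_validate,
    kfold_split,
    prepare_cohort,
    summary_metrics,
)
from .two_factor import two_factor_table

__all__ = [
    "scaled_model_config",
    "scaled_train_config",
    "make_study_subjects",
    "run_recovery",
    "run_chance",
    "run_ablation",
    "run_two_factor_comparison",
]

#: temporal average-binning factor applied to the band signals before the CNN
BAND_DECIMATE = 10
#: subjects per diagnostic class in the study cohorts
N_PER_CLASS = 4


def scaled_model_config(branches: str = "vit_cnn", use_filter: bool = True) -> ModelConfig:
    """The study's reduced architecture (structure identical, sizes smaller)."""
    return ModelConfig(
        feature_dim=32,
        attention=AttentionConfig(n_heads=2, patch_len=250, embed_dim=32,
                                  encoder_depth=1),
        cnn_channels=(4, 8),
        cnn_time_pool=4,
        classifier_hidden=32,
        branches=branches,
        use_filter=use_filter,
    )


def scaled_train_config(seed: int, k_folds: int = 10, max_epochs: int = 15) -> TrainConfig:
    """Optimisation settings for the study (Adam, larger batch, few epochs)."""
    return TrainConfig(
        learning_rate=3e-3, max_epochs=max_epochs, batch_size=16,
        k_folds=k_folds, seed=seed,
    )


def make_study_subjects(seed: int, contrast: float, n_per_class: int = N_PER_CLASS):
    """Generate and preprocess a study cohort.

    Returns ``(subjects, mmse_raw, true_class)`` where the last two map
    subject id to MMSE raw score and diagnostic class.
    """
    cohort = generate_cohort(
        n_per_class, seed=seed,
        config=CohortConfig(noise_sd=0.1, contrast=contrast),
    )
    subjects = prepare_cohort(cohort, band_decimate=BAND_DECIMATE)
    mmse = {r.subject_id: int(r.mmse_raw) for r in cohort}
    truth = {r.subject_id: r.class_label for r in cohort}
    return subjects, mmse, truth


def run_recovery(seed: int) -> dict:
    """Ten-fold CV on a strong-contrast cohort; the model should recover the
    class structure almost perfectly."""
    subjects, _, _ = make_study_subjects(seed, contrast=1.0)
    result = cross_validate(
        subjects, scaled_model_config(), scaled_train_config(seed, k_folds=10)
    )
    out = summary_metrics(result)
    out["segment_accuracy"] = result.mean_segment_accuracy * 100.0
    out["subject_accuracy"] = result.mean_subject_accuracy * 100.0
    return out


def run_chance(seed: int) -> tuple[dict, CVResult, dict[str, int], dict[str, int]]:
    """Three-fold CV on a zero-contrast cohort: accuracy collapses to chance.

    Folds are class-stratified: with no class signal, an unstratified split
    leaves the training side imbalanced against the held-out classes and
    biases the (necessarily overfit) model systematically below chance.
    A slightly larger cohort (6 per class) keeps the subject-level variance
    of the chance estimate manageable.  Also returns the CV output and the
    cohort maps so the two-factor comparison can reuse the same
    (EEG-uninformative, MMSE-informative) predictions.
    """
    subjects, mmse, truth = make_study_subjects(seed, contrast=0.0, n_per_class=6)
    folds = kfold_split(sorted(truth), 3, seed, labels=truth)
    result = cross_validate(
        subjects, scaled_model_config(), scaled_train_config(seed, k_folds=3),
        folds=folds,
    )
    out = {"segment_accuracy": result.mean_segment_accuracy * 100.0}
    return out, result, mmse, truth


def run_ablation(seed: int) -> pd.DataFrame:
    """Branch and filter ablations on a strong-contrast cohort, shared folds."""
    subjects, _, _ = make_study_subjects(seed, contrast=1.0)
    return ablation_run(
        subjects,
        scaled_model_config(),
        scaled_train_config(seed, k_folds=3),
        variants=[("cnn_only", True), ("vit_cnn", True), ("vit_cnn", False)],
    )


def run_two_factor_comparison(
    result: CVResult, mmse: dict[str, int], truth: dict[str, int]
) -> dict:
    """Two-factor vs EEG-only subject accuracy on noisy-EEG predictions.

    With uninformative EEG and class-banded MMSE scores, inconsistent
    subjects defer to the MMSE factor, so the joint decision should match or
    beat the EEG-only majority vote.
    """
    ids = sorted(truth)
    eeg_only = float(np.mean([result.subject_pred[s] == truth[s] for s in ids])) * 100.0
    table = two_factor_table(result.records, mmse)
    joint_by_id = dict(zip(table["subject_id"], table["final_class"]))
    joint = float(np.mean([joint_by_id[s] == truth[s] for s in ids])) * 100.0
    return {"eeg_only_subject_accuracy": eeg_only, "joint_subject_accuracy": joint}
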