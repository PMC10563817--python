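"""Training, subject-wise cross-validation, metrics, ROC/AUC, ablations.

All evaluation follows the clinical-screening conventions: accuracy,
sensitivity and 1-specificity are reported in percent from one-vs-rest
confusion counts; ROC curves are built per class by thresholding that
class's probability against the rest, with the area computed by the
trapezoid rule; three-class summaries are unweighted (macro) means over
classes.  Cross-validation splits at the *subject* level so that no
subject's segments ever appear in both the training and test side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DualBranchModel, ModelConfig, cross_entropy
from .nn import Adam, SGD, softmax
from .preprocess import decompose_bands, normalize_recording, segment_time_domain
from .synthetic import EegRecording
from .two_factor import PredictionRecord

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "RocCurve",
    "SubjectData",
    "UndefinedMetricError",
    "prepare_cohort",
    "kfold_split",
    "train",
    "predict_subject",
    "evaluate",
    "cross_validate",
    "confusion_counts",
    "metrics",
    "roc_curve_from_scores",
    "auc",
    "multiclass_roc",
    "ablation_run",
    "channel_weights",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; the defaults are the reference protocol."""

    learning_rate: float = 0.0005
    max_epochs: int = 100
    batch_size: int = 4
    k_folds: int = 10
    seed: int = 0
    optimizer: str = "adam"  # or "sgd"
    #: random circular time shift of each training segment.  Band-limited EEG
    #: noise is phase-random by nature; the shift destroys per-segment phase
    #: fingerprints (which a high-capacity branch would memorise) while
    #: leaving spectral content intact, forcing shift-invariant features.
    augment_time_shift: bool = True

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("invalid batch size or epoch count")


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (e.g. no positives for sensitivity)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """Ordered ROC points (x = 1 - specificity, y = sensitivity)."""

    points: list[tuple[float, float]]

    def __post_init__(self):
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if any(not 0 <= v <= 1 for v in xs + ys):
            raise ValueError("ROC coordinates must lie in [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(xs, xs[1:])):
            raise ValueError("ROC x coordinates must be non-decreasing")
        if self.points and (self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0)):
            raise ValueError("ROC curve must start at (0,0) and end at (1,1)")


@dataclass
class SubjectData:
    """One subject's model-ready inputs."""

    subject_id: str
    label: int
    mmse_raw: int | None
    segments: np.ndarray  # (n_segments, channels, window_samples)
    bands: np.ndarray  # (n_bands, channels, samples)


def _decimate_mean(x: np.ndarray, factor: int, axis: int = -1) -> np.ndarray:
    """Average-bin along ``axis`` by an integer factor (tail cropped)."""
    if factor <= 1:
        return x
    x = np.moveaxis(x, axis, -1)
    n = (x.shape[-1] // factor) * factor
    x = x[..., :n].reshape(*x.shape[:-1], n // factor, factor).mean(axis=-1)
    return np.moveaxis(x, -1, axis)


def prepare_cohort(
    cohort: list[EegRecording],
    window_s: float = 4.0,
    n_segments: int = 10,
    normalize: bool = True,
    band_decimate: int = 1,
) -> list[SubjectData]:
    """Preprocess recordings into per-subject (segments, bands, label) inputs.

    ``band_decimate`` average-bins the band signals in time by an integer
    factor before they reach the CNN branch (the bands are low-pass by
    construction, so modest decimation preserves their envelope structure
    while cutting compute).
    """
    out = []
    for rec in cohort:
        r = normalize_recording(rec) if normalize else rec
        segs = segment_time_domain(r, window_s=window_s, n_segments=n_segments)
        bands = decompose_bands(r).as_array()
        out.append(
            SubjectData(
                subject_id=rec.subject_id,
                label=rec.class_label,
                mmse_raw=rec.mmse_raw,
                segments=segs.as_array(),
                bands=_decimate_mean(bands, band_decimate),
            )
        )
    return out


def kfold_split(
    subject_ids: list[str], k: int, seed: int,
    labels: dict[str, int] | None = None,
) -> list[tuple[list[str], list[str]]]:
    """Seeded subject-level k-fold partition.

    Every subject appears in exactly one test fold; all of a subject's
    segments stay on one side of each split.  When ``labels`` is given the
    folds are class-stratified (subjects of each class dealt round-robin
    across folds), keeping the training side of every fold class-balanced —
    important on small cohorts, where unstratified splits bias an
    uninformative classifier systematically below chance.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subject_ids)})")
    rng = np.random.default_rng(seed)
    order = list(subject_ids)
    rng.shuffle(order)
    if labels is None:
        folds = np.array_split(order, k)
    else:
        folds = [[] for _ in range(k)]
        i = 0
        for cls in sorted({labels[s] for s in order}):
            for sid in (s for s in order if labels[s] == cls):
                folds[i % k].append(sid)
                i += 1
    out = []
    for i in range(k):
        test = list(folds[i])
        train_ids = [s for j in range(k) for s in folds[j] if j != i]
        out.append((train_ids, test))
    return out


def train(
    model: DualBranchModel,
    subjects: list[SubjectData],
    cfg: TrainConfig,
) -> tuple[DualBranchModel, list[float]]:
    """Train in place on all segments of ``subjects``; returns the loss trace.

    One training example = one time segment paired with its subject's band
    array.  The trace holds the mean cross-entropy per epoch; with a fixed
    seed it is bit-reproducible on a single thread (and, with augmentation
    disabled, constant when the learning rate is zero).
    """
    if not subjects:
        raise ValueError("empty training cohort")
    seg_store = np.concatenate([sd.segments for sd in subjects])
    band_store = np.stack([sd.bands for sd in subjects])
    subj_idx = np.concatenate(
        [np.full(len(sd.segments), i) for i, sd in enumerate(subjects)]
    )
    y = np.concatenate(
        [np.full(len(sd.segments), sd.label) for sd in subjects]
    ).astype(int)
    n = len(y)
    params = model.parameters()
    opt = (Adam if cfg.optimizer == "adam" else SGD)(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    model.train()
    trace: list[float] = []
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            segs = seg_store[idx]
            if cfg.augment_time_shift:
                shifts = rng.integers(0, segs.shape[-1], size=len(idx))
                segs = np.stack(
                    [np.roll(s, int(sh), axis=-1) for s, sh in zip(segs, shifts)]
                )
            logits = model.forward(segs, band_store[subj_idx[idx]])
            probs = softmax(logits, axis=-1)
            loss = cross_entropy(probs, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        trace.append(epoch_loss / n)
    model.eval()
    return model, trace


def predict_subject(model: DualBranchModel, sd: SubjectData) -> PredictionRecord:
    """Per-segment class probabilities and hard labels for one subject."""
    n_seg = len(sd.segments)
    bands = np.broadcast_to(sd.bands, (n_seg, *sd.bands.shape))
    probs = model.predict_proba(sd.segments, bands)
    return PredictionRecord(
        subject_id=sd.subject_id,
        segment_probs=[p for p in probs],
        segment_labels=[int(np.argmax(p)) for p in probs],
    )


def evaluate(model: DualBranchModel, subjects: list[SubjectData]) -> dict:
    """Segment- and subject-level (majority-vote) accuracy plus raw predictions."""
    records = [predict_subject(model, sd) for sd in subjects]
    seg_true, seg_pred, seg_probs = [], [], []
    subj_true, subj_pred = [], []
    for sd, rec in zip(subjects, records):
        labels = rec.segment_labels
        seg_true.extend([sd.label] * len(labels))
        seg_pred.extend(labels)
        seg_probs.extend(rec.segment_probs)
        subj_true.append(sd.label)
        subj_pred.append(int(np.bincount(labels, minlength=3).argmax()))
    return {
        "records": records,
        "segment_true": np.array(seg_true),
        "segment_pred": np.array(seg_pred),
        "segment_probs": np.array(seg_probs),
        "subject_true": np.array(subj_true),
        "subject_pred": np.array(subj_pred),
        "segment_accuracy": float(np.mean(np.array(seg_true) == np.array(seg_pred))),
        "subject_accuracy": float(np.mean(np.array(subj_true) == np.array(subj_pred))),
    }


@dataclass
class CVResult:
    """Aggregated subject-wise cross-validation output."""

    fold_segment_accuracy: list[float]
    fold_subject_accuracy: list[float]
    segment_true: np.ndarray
    segment_probs: np.ndarray
    records: list[PredictionRecord]
    subject_true: dict[str, int]
    subject_pred: dict[str, int]

    @property
    def mean_segment_accuracy(self) -> float:
        return float(np.mean(self.fold_segment_accuracy))

    @property
    def mean_subject_accuracy(self) -> float:
        return float(np.mean(self.fold_subject_accuracy))


def cross_validate(
    subjects: list[SubjectData],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    folds: list[tuple[list[str], list[str]]] | None = None,
) -> CVResult:
    """Subject-wise k-fold CV: train a fresh model per fold, pool test output.

    Default folds are class-stratified at the subject level so every fold's
    training side sees all classes (critical on small cohorts).
    """
    by_id = {sd.subject_id: sd for sd in subjects}
    if folds is None:
        labels = {sd.subject_id: sd.label for sd in subjects}
        folds = kfold_split(sorted(by_id), cfg.k_folds, cfg.seed, labels=labels)
    window = subjects[0].segments.shape[-1]
    n_bands = subjects[0].bands.shape[0]
    seg_acc, subj_acc = [], []
    all_true, all_probs, all_records = [], [], []
    subject_true: dict[str, int] = {}
    subject_pred: dict[str, int] = {}
    for i, (train_ids, test_ids) in enumerate(folds):
        # leakage guard: the split must be a partition at subject level
        assert not set(train_ids) & set(test_ids)
        model = DualBranchModel(
            model_cfg, window_samples=window, seed=cfg.seed + i, n_bands=n_bands
        )
        train(model, [by_id[s] for s in train_ids], cfg)
        res = evaluate(model, [by_id[s] for s in test_ids])
        seg_acc.append(res["segment_accuracy"])
        subj_acc.append(res["subject_accuracy"])
        all_true.append(res["segment_true"])
        all_probs.append(res["segment_probs"])
        all_records.extend(res["records"])
        for sid, t, p in zip(test_ids, res["subject_true"], res["subject_pred"]):
            subject_true[sid] = int(t)
            subject_pred[sid] = int(p)
    return CVResult(
        fold_segment_accuracy=seg_acc,
        fold_subject_accuracy=subj_acc,
        segment_true=np.concatenate(all_true),
        segment_probs=np.concatenate(all_probs),
        records=all_records,
        subject_true=subject_true,
        subject_pred=subject_pred,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_counts(y_true, y_pred, positive_class: int) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(conf: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, 1-specificity %) from confusion counts.

    A component whose denominator is zero is reported as NaN — an explicit
    undefined-metric signal, never a silent zero; an empty count set raises
    :class:`UndefinedMetricError`.
    """
    if conf.total == 0:
        raise UndefinedMetricError("no examples")
    acc = (conf.tp + conf.tn) / conf.total * 100.0
    sen = (conf.tp / (conf.tp + conf.fn) * 100.0
           if conf.tp + conf.fn else float("nan"))
    one_minus_spe = ((1.0 - conf.tn / (conf.tn + conf.fp)) * 100.0
                     if conf.tn + conf.fp else float("nan"))
    return acc, sen, one_minus_spe


def roc_curve_from_scores(scores, labels) -> RocCurve:
    """ROC curve from per-example scores and binary labels (1 = positive)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: one class absent")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(sorted_labels)):
        if sorted_labels[i] == 1:
            tp += 1
        else:
            fp += 1
        # emit a point only where the score changes (threshold boundary)
        if i == len(sorted_labels) - 1 or sorted_scores[i + 1] != sorted_scores[i]:
            points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocCurve(points=points)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under a ROC curve."""
    if len(curve.points) < 2:
        raise ValueError("AUC requires at least 2 ROC points")
    xs = np.array([p[0] for p in curve.points])
    ys = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(ys, xs))


def multiclass_roc(probs, labels) -> tuple[dict[int, RocCurve | None], float]:
    """One-vs-rest ROC per class plus the macro (unweighted mean) AUC.

    A class absent from ``labels`` gets ``None`` (undefined curve) and is
    excluded from the macro mean.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    curves: dict[int, RocCurve | None] = {}
    aucs = []
    for cls in range(probs.shape[1]):
        binary = (labels == cls).astype(int)
        try:
            curve = roc_curve_from_scores(probs[:, cls], binary)
        except UndefinedMetricError:
            curves[cls] = None
            continue
        curves[cls] = curve
        aucs.append(auc(curve))
    if not aucs:
        raise UndefinedMetricError("no class has both positives and negatives")
    return curves, float(np.mean(aucs))


def summary_metrics(result: CVResult) -> dict[str, float]:
    """Macro SEN/SPE, overall ACC and macro AUC (percent) from pooled CV output."""
    y_true = result.segment_true
    y_pred = result.segment_probs.argmax(axis=1)
    sens, spes = [], []
    for cls in np.unique(y_true):
        conf = confusion_counts(y_true, y_pred, int(cls))
        acc_c, sen, one_minus_spe = metrics(conf)
        sens.append(sen)
        spes.append(100.0 - one_minus_spe)
    _, macro_auc = multiclass_roc(result.segment_probs, y_true)
    return {
        "SEN": float(np.mean(sens)),
        "SPE": float(np.mean(spes)),
        "ACC": float(np.mean(y_true == y_pred) * 100.0),
        "AUC": macro_auc * 100.0,
    }


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def ablation_run(
    subjects: list[SubjectData],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    variants: list[tuple[str, bool]] | None = None,
) -> pd.DataFrame:
    """Train/evaluate architecture variants on identical folds and seed.

    ``variants`` is a list of ``(branches, use_filter)`` pairs; defaults to
    the five branch layouts with the filter on plus the dual-branch layout
    with the filter off.  Returns one row per variant with macro SEN/SPE,
    ACC and AUC in percent.
    """
    if variants is None:
        variants = [(v, True) for v in
                    ("cnn_only", "vit_only", "cnn_cnn", "vit_vit", "vit_cnn")]
        variants.append(("vit_cnn", False))
    ids = sorted(sd.subject_id for sd in subjects)
    folds = kfold_split(ids, cfg.k_folds, cfg.seed)  # shared across variants
    rows = []
    for branches, use_filter in variants:
        mc = ModelConfig(**{**model_cfg.to_dict(), "branches": branches,
                            "use_filter": use_filter})
        result = cross_validate(subjects, mc, cfg, folds=folds)
        row = {"branches": branches, "feature_filter": use_filter}
        row.update(summary_metrics(result))
        row["segment_accuracy"] = result.mean_segment_accuracy
        rows.append(row)
    return pd.DataFrame(rows)


def channel_weights(model: DualBranchModel) -> np.ndarray:
    """Per-electrode importance from the classifier's first dense layer.

    The flattened fused map is electrode-major, so the absolute weights of
    the first fully-connected layer are summed within each electrode's block
    of feature columns; output length 19 in montage order.  Homogeneous of
    degree 1: scaling the layer scales every importance equally.
    """
    if model is None:
        raise ValueError("a trained model is required")
    w = np.abs(model.head.fc1.weight.data)  # (19 * fused_dim, hidden)
    n_ch = model.cfg.n_channels
    fused_dim = w.shape[0] // n_ch
    return w.reshape(n_ch, fused_dim, -1).sum(axis=(1, 2))
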