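"""Two-factor clinical decision layer: EEG prediction consistency + MMSE.

Factor 1 is the network's per-segment class predictions for a subject;
their internal consistency is quantified by the mean pairwise Pearson
correlation *P* between segment probability vectors.  Factor 2 is the
subject's Mini-Mental State Examination (MMSE) raw score, banded into a
three-level ordinal score aligned with the class coding (NC=0, FTD=1, AD=2).
The two factors are mixed by the consistency weight ``lambda = clamp(P, 0, 1)``:

    AD_score = lambda * mean(segment hard labels) + (1 - lambda) * MMSE_score

and the final class is the nearest integer (half rounded up) clipped to
{0, 1, 2}.  Fully consistent EEG predictions (P = 1) make the decision
independent of the MMSE; fully inconsistent ones (P = 0) defer entirely to
the MMSE banding.

.. warning::
   The default banding maps *high* MMSE (>= 27) to the AD score 2 and *low*
   MMSE (< 10) to the NC score 0 — the reverse of clinical convention, where
   higher MMSE means better cognition.  It is kept because it is the banding
   the method was defined and evaluated with; ``preset="clinical"`` selects
   the conventional direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictionRecord",
    "TwoFactorResult",
    "pearson",
    "consistency",
    "mmse_band",
    "combine",
    "two_factor_table",
]


@dataclass
class PredictionRecord:
    """Per-subject per-segment predictions from the EEG model."""

    subject_id: str
    segment_probs: list[np.ndarray]  # each a length-3 simplex vector
    segment_labels: list[int]

    def __post_init__(self):
        self.segment_probs = [np.asarray(p, dtype=np.float64) for p in self.segment_probs]
        if len(self.segment_probs) != len(self.segment_labels):
            raise ValueError("probability and label lists differ in length")
        if any(label not in (0, 1, 2) for label in self.segment_labels):
            raise ValueError("hard labels must be in {0, 1, 2}")


@dataclass
class TwoFactorResult:
    """Consistency, mixture weight, and the combined decision for a subject."""

    subject_id: str
    P: float
    lam: float
    mmse_score: int
    ad_score: float
    final_class: int


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with a defined zero-variance fallback.

    When either vector is constant the coefficient is undefined; perfect
    agreement between two identical constant vectors is scored 1, any other
    constant case 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.sum(da * db) / denom)


def consistency(rec: PredictionRecord, strategy: str = "pairwise_probs") -> float:
    """Consistency P of a subject's segment predictions, clamped to [0, 1].

    Strategies:

    - ``pairwise_probs`` (default): mean Pearson correlation over all pairs
      of segment class-probability vectors.
    - ``labels_vs_majority``: Pearson correlation between the hard-label
      sequence and the constant majority label (1 iff all segments agree).
    """
    n = len(rec.segment_probs)
    if n < 2:
        raise ValueError("consistency requires at least 2 segment predictions")
    if strategy == "pairwise_probs":
        total = 0.0
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                total += pearson(rec.segment_probs[i], rec.segment_probs[j])
                count += 1
        p = total / count
    elif strategy == "labels_vs_majority":
        labels = np.asarray(rec.segment_labels, dtype=np.float64)
        majority = np.full(n, float(np.bincount(rec.segment_labels).argmax()))
        p = pearson(labels, majority)
    else:
        raise ValueError(f"unknown consistency strategy {strategy!r}")
    return float(min(1.0, max(0.0, p)))


# As-printed screening bands: raw >= 27 -> 2 (AD), 10 <= raw < 27 -> 1 (FTD),
# raw < 10 -> 0 (NC).  thresholds = (low, high) band edges.
DEFAULT_THRESHOLDS: tuple[int, int] = (10, 27)


def mmse_band(raw: int, thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
              preset: str = "as_printed") -> int:
    """Band a raw MMSE score (0-30) into the ordinal score {0, 1, 2}.

    ``preset="as_printed"`` (default) maps high scores to 2 and low to 0;
    ``preset="clinical"`` reverses the direction (high MMSE -> healthy -> 0).
    """
    if not 0 <= raw <= 30:
        raise ValueError(f"MMSE raw score {raw} outside [0, 30]")
    low, high = thresholds
    if raw >= high:
        score = 2
    elif raw >= low:
        score = 1
    else:
        score = 0
    if preset == "clinical":
        return 2 - score
    if preset != "as_printed":
        raise ValueError(f"unknown MMSE banding preset {preset!r}")
    return score


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def combine(rec: PredictionRecord, mmse_score: int,
            strategy: str = "pairwise_probs",
            lam: float | None = None) -> TwoFactorResult:
    """Mix EEG predictions with the banded MMSE score into a final decision.

    ``lam`` overrides the consistency-derived weight (used for the analytic
    EEG-only / MMSE-only limits); otherwise ``lam = clamp(P, 0, 1)``.
    """
    if mmse_score not in (0, 1, 2):
        raise ValueError("banded MMSE score must be in {0, 1, 2}")
    p = consistency(rec, strategy=strategy)
    weight = p if lam is None else float(lam)
    if not 0.0 <= weight <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    mean_eeg = float(np.mean(rec.segment_labels))
    ad_score = weight * mean_eeg + (1.0 - weight) * mmse_score
    final = min(2, max(0, _round_half_up(ad_score)))
    return TwoFactorResult(
        subject_id=rec.subject_id,
        P=p,
        lam=weight,
        mmse_score=int(mmse_score),
        ad_score=float(ad_score),
        final_class=final,
    )


def two_factor_table(records: list[PredictionRecord], mmse_raw: dict[str, int],
                     strategy: str = "pairwise_probs",
                     thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
                     preset: str = "as_printed"):
    """One decision row per subject; returns a pandas DataFrame.

    Columns: subject_id, P, lam, mmse_raw, mmse_score, ad_score, final_class.
    """
    import pandas as pd

    rows = []
    for rec in records:
        raw = mmse_raw[rec.subject_id]
        score = mmse_band(raw, thresholds=thresholds, preset=preset)
        res = combine(rec, score, strategy=strategy)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "P": res.P,
                "lambda": res.lam,
                "mmse_raw": raw,
                "mmse_score": res.mmse_score,
                "ad_score": res.ad_score,
                "final_class": res.final_class,
            }
        )
    return pd.DataFrame(rows)
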