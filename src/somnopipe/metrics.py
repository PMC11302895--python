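"""Agreement metrics for sleep staging: confusion matrix, Cohen's kappa, F1.

Sleep-staging performance is conventionally reported per record (one
night) as Cohen's kappa between the human reference hypnogram and the
model prediction, and per dataset as class-averaged F1.  Epochs that are
unscorable on either side (sentinel code -1: movement time, unknown) are
dropped pairwise before counting — they have no AASM stage to agree on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import StageCode

N_STAGES = 5
STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K agreement counts; rows = reference stage, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_STAGES, N_STAGES) or (c < 0).any():
            raise ValueError(f"counts must be non-negative {N_STAGES}x{N_STAGES}")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(reference: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Count stage agreements, dropping pairs unscored on either side."""
    ref = np.asarray(reference, dtype=np.int64)
    pred = np.asarray(predicted, dtype=np.int64)
    if ref.shape != pred.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {pred.shape}")
    keep = (ref != StageCode.UNSCORED) & (pred != StageCode.UNSCORED)
    ref, pred = ref[keep], pred[keep]
    if ((ref < 0) | (ref >= N_STAGES) | (pred < 0) | (pred >= N_STAGES)).any():
        raise ValueError("stage codes must be in {-1, 0, ..., 4}")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (ref, pred), 1)
    return ConfusionMatrix(counts)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix (no scored epoch pairs)")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / (n * n)
    if p_e == 1.0:
        raise ZeroDivisionError(
            "expected agreement is 1 (both raters constant and equal); "
            "kappa is undefined"
        )
    return float((p_o - p_e) / (1 - p_e))


def per_class_f1(cm: ConfusionMatrix) -> np.ndarray:
    """F1 per stage; NaN for stages absent from both reference and prediction."""
    tp = np.diag(cm.counts).astype(float)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, np.nan)
    return f1


def macro_f1(cm: ConfusionMatrix, weighted: bool = False) -> float:
    """Class-averaged F1, unweighted by default.

    Stages that occur in neither the reference nor the prediction are
    excluded from the average rather than counted as zeros.  With
    ``weighted=True``, classes are weighted by their reference support.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix (no scored epoch pairs)")
    f1 = per_class_f1(cm)
    present = ~np.isnan(f1)
    if not present.any():
        raise ValueError("no stage present on either side")
    if weighted:
        support = cm.counts.sum(axis=1).astype(float)
        w = support[present]
        if w.sum() == 0:
            raise ValueError("weighted F1 undefined: no reference support")
        return float(np.average(f1[present], weights=w))
    return float(np.mean(f1[present]))


def record_metrics(
    reference: Sequence[int], predicted: Sequence[int]
) -> dict[str, float]:
    """Kappa, per-class F1 and macro F1 for one record."""
    cm = confusion(reference, predicted)
    out = {"kappa": cohen_kappa(cm), "macro_f1": macro_f1(cm)}
    for name, f1 in zip(STAGE_NAMES, per_class_f1(cm)):
        out[f"f1_{name}"] = float(f1)
    return out


def export_record_metrics(
    rows: dict[str, tuple[Sequence[int], Sequence[int]]],
    path: Path,
) -> pd.DataFrame:
    """Write per-record metrics (record id, kappa, per-class F1, macro F1) as CSV."""
    table = []
    for record_id, (ref, pred) in rows.items():
        row: dict = {"record_id": record_id}
        row.update(record_metrics(ref, pred))
        table.append(row)
    df = pd.DataFrame(table)
    df.to_csv(path, index=False)
    return df
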