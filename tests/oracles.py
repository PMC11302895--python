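"""Independent brute-force oracles used by several test modules.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def quartile_linear(values, q: float) -> float:
    """Sorted-order-statistic quantile with linear interpolation ("type 7")."""
    x = sorted(float(v) for v in values)
    n = len(x)
    h = (n - 1) * q
    lo = math.floor(h)
    if lo + 1 >= n:
        return x[lo]
    return x[lo] + (h - lo) * (x[lo + 1] - x[lo])


def iqr_brute(values) -> float:
    return quartile_linear(values, 0.75) - quartile_linear(values, 0.25)


def scale_brute(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return (x - x.mean()) / iqr_brute(x)


def kappa_pair_counting(ref, pred) -> float:
    """Cohen's kappa by brute-force pair counting (no confusion matrix)."""
    ref = list(ref)
    pred = list(pred)
    n = len(ref)
    p_o = sum(r == p for r, p in zip(ref, pred)) / n
    classes = set(ref) | set(pred)
    p_e = sum((ref.count(c) / n) * (pred.count(c) / n) for c in classes)
    return (p_o - p_e) / (1 - p_e)


def macro_f1_brute(ref, pred) -> float:
    """Macro F1 from raw label lists, skipping classes absent on both sides."""
    ref = list(ref)
    pred = list(pred)
    scores = []
    for c in range(5):
        tp = sum(r == c and p == c for r, p in zip(ref, pred))
        fp = sum(r != c and p == c for r, p in zip(ref, pred))
        fn = sum(r == c and p != c for r, p in zip(ref, pred))
        if tp + fp + fn == 0:
            continue
        scores.append(2 * tp / (2 * tp + fp + fn))
    return sum(scores) / len(scores)
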