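"""Task metrics and significance testing for relation extraction.

Micro precision/recall/F pool true/false positives over the *positive*
classes only (the shared-task DDI convention: the negative "no interaction"
class is excluded from the pools), per-class scores are one-vs-rest, and the
confusion matrix uses the label-set order with the negative class last.

System comparison uses the approximate-randomization (randomized shuffle)
test: per instance the two systems' predictions are swapped with probability
1/2, the micro-F difference is recomputed for each shuffled assignment, and
the two-sided p-value is the smoothed fraction of shuffles whose absolute
difference reaches the observed one.
"""

from __future__ import annotations

import numpy as np

from .corpus import DDI_LABELS, LabelSet

__all__ = [
    "micro_prf",
    "per_class_prf",
    "confusion_matrix",
    "shuffle_test",
]


def _validate(gold: list[str], pred: list[str], labelset: LabelSet) -> None:
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} pred")
    valid = set(labelset.all_labels)
    for seq, name in ((gold, "gold"), (pred, "pred")):
        for lab in seq:
            if lab not in valid:
                raise KeyError(f"unknown {name} label {lab!r}")


def _counts(gold: list[str], pred: list[str], positives: set[str]):
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        if p in positives:
            if g == p:
                tp += 1
            else:
                fp += 1
        if g in positives and p != g:
            fn += 1
    return tp, fp, fn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def micro_prf(
    gold: list[str], pred: list[str], labelset: LabelSet = DDI_LABELS
) -> tuple[float, float, float]:
    """(P, R, F) pooled over the positive classes, negative excluded."""
    _validate(gold, pred, labelset)
    return _prf(*_counts(gold, pred, set(labelset.positives)))


def per_class_prf(
    gold: list[str], pred: list[str], labelset: LabelSet = DDI_LABELS
) -> dict[str, dict]:
    """One-vs-rest (P, R, F) per positive class; classes absent from both
    gold and predictions are flagged ``empty``."""
    _validate(gold, pred, labelset)
    out: dict[str, dict] = {}
    for cls in labelset.positives:
        tp, fp, fn = _counts(gold, pred, {cls})
        p, r, f = _prf(tp, fp, fn)
        out[cls] = {
            "precision": p,
            "recall": r,
            "f1": f,
            "support": sum(1 for g in gold if g == cls),
            "empty": tp + fp + fn == 0,
        }
    return out


def confusion_matrix(
    gold: list[str], pred: list[str], labelset: LabelSet = DDI_LABELS
) -> np.ndarray:
    """c x c count matrix; rows = gold, columns = predicted, negative last."""
    _validate(gold, pred, labelset)
    order = {lab: i for i, lab in enumerate(labelset.all_labels)}
    cm = np.zeros((labelset.c, labelset.c), dtype=int)
    for g, p in zip(gold, pred):
        cm[order[g], order[p]] += 1
    return cm


def _instance_counts(gold: list[str], pred: list[str], positives: set[str]) -> np.ndarray:
    """Per-instance (tp, fp, fn) contributions, shape (n, 3)."""
    out = np.zeros((len(gold), 3))
    for i, (g, p) in enumerate(zip(gold, pred)):
        if p in positives:
            if g == p:
                out[i, 0] = 1
            else:
                out[i, 1] = 1
        if g in positives and p != g:
            out[i, 2] = 1
    return out


def _f_from_totals(tot: np.ndarray) -> np.ndarray:
    """Micro-F for an array of (tp, fp, fn) rows, 0 where degenerate."""
    tp, fp, fn = tot[..., 0], tot[..., 1], tot[..., 2]
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, 2 * tp / np.maximum(denom, 1e-300), 0.0)
    return f


def shuffle_test(
    gold: list[str],
    pred_a: list[str],
    pred_b: list[str],
    n_shuffles: int = 10_000,
    seed: int = 0,
    labelset: LabelSet = DDI_LABELS,
) -> float:
    """Approximate-randomization p-value for the micro-F difference.

    Per instance the two systems' predictions are exchanged with probability
    1/2; ``p = (1 + #{|d_shuffled| >= |d_observed|}) / (1 + n_shuffles)``
    (the +1 smoothing keeps p > 0 at finite shuffle counts).  Two-sided.
    """
    _validate(gold, pred_a, labelset)
    _validate(gold, pred_b, labelset)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    positives = set(labelset.positives)
    ca = _instance_counts(gold, pred_a, positives)  # (n, 3)
    cb = _instance_counts(gold, pred_b, positives)
    f_a = _f_from_totals(ca.sum(axis=0))
    f_b = _f_from_totals(cb.sum(axis=0))
    observed = abs(float(f_a - f_b))
    rng = np.random.default_rng(seed)
    n = len(gold)
    # micro-F is a function of the summed (tp, fp, fn); a shuffle only swaps
    # which system each instance's counts go to, so the null distribution is
    # computed from matrix products over random swap masks.
    exceed = 0
    chunk = max(1, min(n_shuffles, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        mask = rng.integers(0, 2, size=(m, n)).astype(float)
        tot_a = mask @ ca + (1 - mask) @ cb
        tot_b = mask @ cb + (1 - mask) @ ca
        diffs = np.abs(_f_from_totals(tot_a) - _f_from_totals(tot_b))
        exceed += int(np.sum(diffs >= observed - 1e-12))
        done += m
    return (1 + exceed) / (1 + n_shuffles)
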