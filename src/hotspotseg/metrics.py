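"""Overlap metrics and triage reporting.

Segmentations are scored against expert (here: ground-truth) masks with

    Dice    D(M, N) = 2|M n N| / (|M| + |N|)
    Jaccard J(M, N) =  |M n N| / |M u N|,

which satisfy D = 2J/(1+J) identically.  Two empty masks score 1.0
(correct rejection); empty vs nonempty scores 0.0.  Per-case scores are
averaged per method (per-case mean, not pixel-pooled — recorded in the
report metadata).

Triage predictions are scored as exact three-level accuracy, as binary
TPR/FNR on the hot-spot-present dichotomy (level I vs level III; cases
the classifier routes to the uncertain level II are reported separately),
and as the accuracy obtained when uncertain reassignments (prediction II
on a gold I/III case) are excluded from the denominator.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError, SizeError
from .phantom import LEVEL_I, LEVEL_II, LEVEL_III, PhantomCase

LEVELS = (LEVEL_I, LEVEL_II, LEVEL_III)


def overlap_scores(M: np.ndarray, N: np.ndarray) -> tuple[float, float]:
    """(Dice, Jaccard) between two binary masks of equal shape."""
    M = np.asarray(M, dtype=bool)
    N = np.asarray(N, dtype=bool)
    if M.shape != N.shape:
        raise SizeError(f"mask shapes differ: {M.shape} vs {N.shape}")
    inter = int(np.logical_and(M, N).sum())
    size_m = int(M.sum())
    size_n = int(N.sum())
    union = size_m + size_n - inter
    if size_m + size_n == 0:
        return 1.0, 1.0  # both empty: correct rejection
    dice = 2.0 * inter / (size_m + size_n)
    jaccard = inter / union
    return float(dice), float(jaccard)


def triage_report(pred, gold) -> dict:
    """Accuracy, confusion table and binary TPR/FNR for three-level calls.

    Percentages are on the 0-100 scale.  ``accuracy_excluding_uncertain``
    and ``tpr``/``fnr`` are None when their denominators are empty.
    """
    pred = list(pred)
    gold = list(gold)
    if len(pred) != len(gold):
        raise InputError("pred and gold must have equal length")
    if not pred:
        raise InputError("empty prediction list")
    bad = [x for x in pred + gold if x not in LEVELS]
    if bad:
        raise InputError(f"unknown level label(s): {sorted(set(bad))}")

    n = len(gold)
    idx = {lvl: i for i, lvl in enumerate(LEVELS)}
    confusion = np.zeros((3, 3), dtype=int)  # rows: gold, cols: predicted
    for g, p in zip(gold, pred):
        confusion[idx[g], idx[p]] += 1
    correct = int(np.trace(confusion))
    accuracy = 100.0 * correct / n

    # uncertain reassignments: predicted II on a decided (I or III) gold case
    reassigned = sum(1 for g, p in zip(gold, pred) if p == LEVEL_II and g != LEVEL_II)
    denom_excl = n - reassigned
    accuracy_excl = 100.0 * correct / denom_excl if denom_excl > 0 else None

    # binary stats on the present (I) vs absent (III) dichotomy
    tp = sum(1 for g, p in zip(gold, pred) if g == LEVEL_I and p == LEVEL_I)
    fn = sum(1 for g, p in zip(gold, pred) if g == LEVEL_I and p == LEVEL_III)
    fp = sum(1 for g, p in zip(gold, pred) if g == LEVEL_III and p == LEVEL_I)
    tn = sum(1 for g, p in zip(gold, pred) if g == LEVEL_III and p == LEVEL_III)
    tpr = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    fnr = 100.0 * fn / (tp + fn) if tp + fn > 0 else None
    fpr = 100.0 * fp / (fp + tn) if fp + tn > 0 else None

    return {
        "n": n,
        "accuracy": accuracy,
        "accuracy_excluding_uncertain": accuracy_excl,
        "n_uncertain_reassigned": reassigned,
        "tpr": tpr,
        "fnr": fnr,
        "fpr": fpr,
        "confusion": confusion,
        "levels": list(LEVELS),
    }


def benchmark_methods(
    cases: list[PhantomCase],
    masks_by_method: dict[str, list[np.ndarray]],
    levels: tuple[str, ...] = (LEVEL_I,),
) -> dict:
    """Mean Dice/Jaccard per method over the selected-level cases, ranked.

    Every method must supply one mask per case (aligned with ``cases``).
    """
    keep = [i for i, c in enumerate(cases) if c.gold_label in levels]
    if not keep:
        raise InputError(f"no cases with gold label in {levels}")
    report: dict = {
        "n_cases": len(keep),
        "levels": list(levels),
        "aggregation": "per-case mean",
        "methods": {},
    }
    for method, masks in masks_by_method.items():
        if len(masks) != len(cases) or any(masks[i] is None for i in keep):
            raise InputError(f"method {method!r} is missing masks")
        dice, jacc = [], []
        for i in keep:
            d, j = overlap_scores(cases[i].mask, masks[i])
            dice.append(d)
            jacc.append(j)
        report["methods"][method] = {
            "dice": dice,
            "jaccard": jacc,
            "mean_dice": float(np.mean(dice)),
            "mean_jaccard": float(np.mean(jacc)),
        }
    report["ranking"] = sorted(
        report["methods"], key=lambda m: report["methods"][m]["mean_dice"],
        reverse=True,
    )
    return report
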