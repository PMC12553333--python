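"""Independent brute-force oracles used by the metric tests.

Deliberately naive implementations (explicit loops, threshold enumeration)
kept separate from the library code they check.
"""

from __future__ import annotations

import numpy as np


def confusion_brute(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def roc_auc_brute(y_true, scores):
    """Enumerate every (positive, negative) pair."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def pr_auc_brute(y_true, scores):
    """Threshold enumeration: precision x delta-recall at each distinct
    score threshold, descending."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(s.tolist()), reverse=True):
        pred = s >= thr
        tp = int(((y == 1) & pred).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def macro_f1_brute(y_true, y_pred, num_classes):
    f1s = []
    for c in range(num_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(f1s))


def regression_brute(y_true, y_pred):
    """MSE/MAE by direct sums; rho via rank correlation on average ranks;
    R^2 from the definition."""
    t = np.asarray(y_true, float)
    p = np.asarray(y_pred, float)
    n = len(t)
    mse = sum((a - b) ** 2 for a, b in zip(t, p)) / n
    mae = sum(abs(a - b) for a, b in zip(t, p)) / n
    r2 = 1.0 - sum((a - b) ** 2 for a, b in zip(t, p)) / \
        sum((a - t.mean()) ** 2 for a in t)

    def avg_ranks(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(n)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and x[order[j + 1]] == x[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rt, rp = avg_ranks(t), avg_ranks(p)
    rho = np.corrcoef(rt, rp)[0, 1]
    return mse, mae, float(rho), float(r2)


def random_binary_instance(rng, n_max=50, tie_prob=0.5):
    """Random labels and scores, with tied scores on a coarse grid half
    the time; guaranteed to contain both classes."""
    n = int(rng.integers(4, n_max + 1))
    y = rng.integers(0, 2, size=n)
    while y.min() == y.max():
        y = rng.integers(0, 2, size=n)
    if rng.random() < tie_prob:
        scores = rng.integers(0, 5, size=n) / 4.0
    else:
        scores = rng.random(n)
    return y, scores
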