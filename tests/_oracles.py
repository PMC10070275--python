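"""Independent, from-first-principles reference implementations used only by
tests. Everything here is deliberately naive (loops, raw formulas) and shares
no code with the package."""

import math
from itertools import combinations

import numpy as np


def anova_f(values_by_group):
    """One-way ANOVA F for one gene: SS_between / SS_within from scratch."""
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0 and ssb == 0:
        return 0.0
    if ssw == 0:
        return math.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def softmax_row(z, T=1.0):
    e = [math.exp(v / T) for v in z]
    s = sum(e)
    return [v / s for v in e]


def cross_entropy_sum(p, q):
    total = 0.0
    for pi, qi in zip(p, q):
        for pik, qik in zip(pi, qi):
            total -= pik * math.log(max(qik, 1e-12))
    return total


def kl_divergence(a, b):
    return sum(ai * math.log(max(ai, 1e-12) / max(bi, 1e-12)) for ai, bi in zip(a, b))


def entropy_row(q):
    return -sum(v * math.log(v) for v in q if v > 0)


def confusion_metrics(y_true, y_pred):
    """All seven summary metrics from an explicit confusion matrix."""
    y_true = list(map(str, y_true))
    y_pred = list(map(str, y_pred))
    n = len(y_true)
    truth_classes = sorted(set(y_true))
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n

    prec, rec, f1 = {}, {}, {}
    for c in truth_classes:
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec[c] = tp / (tp + fp) if tp + fp else 0.0
        rec[c] = tp / (tp + fn) if tp + fn else 0.0
        f1[c] = (2 * prec[c] * rec[c] / (prec[c] + rec[c])) if prec[c] + rec[c] else 0.0

    # Cohen's kappa from observed vs chance agreement
    all_classes = sorted(set(y_true) | set(y_pred))
    pe = sum(
        (y_true.count(c) / n) * (y_pred.count(c) / n) for c in all_classes
    )
    kappa = (acc - pe) / (1 - pe) if pe != 1 else 1.0

    # ARI from pair counts
    same_t = {(i, j): y_true[i] == y_true[j] for i, j in combinations(range(n), 2)}
    same_p = {(i, j): y_pred[i] == y_pred[j] for i, j in combinations(range(n), 2)}
    a = sum(same_t[k] and same_p[k] for k in same_t)
    b = sum(same_t[k] and not same_p[k] for k in same_t)
    c_ = sum(not same_t[k] and same_p[k] for k in same_t)
    d = sum(not same_t[k] and not same_p[k] for k in same_t)
    total = a + b + c_ + d
    expected = (a + b) * (a + c_) / total
    max_index = ((a + b) + (a + c_)) / 2
    ari = (a - expected) / (max_index - expected) if max_index != expected else 1.0

    vals = lambda d: [d[c] for c in truth_classes]
    return {
        "accuracy": acc,
        "ari": ari,
        "macro_f1": float(np.mean(vals(f1))),
        "cohen_kappa": kappa,
        "median_f1": float(np.median(vals(f1))),
        "median_precision": float(np.median(vals(prec))),
        "median_recall": float(np.median(vals(rec))),
    }
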