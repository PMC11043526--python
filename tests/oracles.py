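"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-sample tallies, pairwise rank
statistics, exhaustive threshold sweeps, binomial sums) and shares no code
with the package paths it checks.
"""

import math

import numpy as np


def tally_confusion(true_labels, pred_labels, classes):
    """Per-sample tally of a confusion matrix."""
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(list(true_labels), list(pred_labels)):
        counts[idx[t]][idx[p]] += 1
    return counts


def ovr_metrics_from_confusion(counts, classes):
    """One-vs-rest macro metrics recomputed with explicit per-class formulas."""
    total = counts.sum()
    per = []
    for i, _c in enumerate(classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 0.0
        ppv = tp / (tp + fp) if tp + fp else 0.0
        npv = tn / (tn + fn) if tn + fn else 0.0
        f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
        per.append((sens, spec, ppv, npv, f1))
    arr = np.array(per)
    return {
        "accuracy": np.trace(counts) / total,
        "sensitivity": arr[:, 0].mean(),
        "specificity": arr[:, 1].mean(),
        "ppv": arr[:, 2].mean(),
        "npv": arr[:, 3].mean(),
        "f1": arr[:, 4].mean(),
    }


def u_statistic_auc(y_binary, scores):
    """Mann-Whitney U / (n_pos * n_neg); ties count one half."""
    pos = [s for y, s in zip(y_binary, scores) if y == 1]
    neg = [s for y, s in zip(y_binary, scores) if y == 0]
    u = 0.0
    for p in pos:
        for n in neg:
            u += 1.0 if p > n else (0.5 if p == n else 0.0)
    return u / (len(pos) * len(neg))


def threshold_sweep_ap(y_binary, scores):
    """Average precision via an exhaustive sweep over distinct score thresholds."""
    y = np.asarray(y_binary)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        yhat = s >= t
        tp = int((y & yhat).sum())
        fp = int((~y.astype(bool) & yhat).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def stacked_count(n_base, n_meta, min_size=2):
    """Binomial-sum oracle for the catalogue cardinality law."""
    return n_meta * sum(math.comb(n_base, k) for k in range(min_size, n_base + 1))
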