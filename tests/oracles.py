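"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain loops straight from the definitions, sharing
no code with the package, so they can serve as oracles.
"""

import math

import numpy as np


def brute_force_cell_scores(values, entries):
    """Per-cell scores for each cell type, straight from the definition.

    values: (n_cells, n_markers) raw subset in logic-marker order;
    entries: (n_types, n_markers) over {-1, 0, 1}.
    Returns (n_cells, n_types).
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    scaled = np.zeros_like(values)
    for j in range(m):
        lo, hi = values[:, j].min(), values[:, j].max()
        if hi > lo:
            scaled[:, j] = (values[:, j] - lo) / (hi - lo)
    scores = np.zeros((n, len(entries)))
    for i, row in enumerate(entries):
        used = [j for j in range(m) if row[j] != 0]
        vhat = {}
        for j in used:
            col = sorted(scaled[:, j])
            if row[j] == 1:
                # 99th percentile, linear interpolation between order stats
                pos = 0.99 * (n - 1)
                lo_i = math.floor(pos)
                hi_i = math.ceil(pos)
                vhat[j] = col[lo_i] + (pos - lo_i) * (col[hi_i] - col[lo_i])
            else:
                vhat[j] = col[0]
        for q in range(n):
            total = 0.0
            for j in used:
                total += 1.0 - (scaled[q, j] - vhat[j]) ** 2
            scores[q, i] = total / len(used)
    return scores


def brute_force_labels(scores, cell_types, other_threshold, undefined_threshold):
    """Argmax labeling with the ambiguity rules, row by row."""
    out = []
    for row in scores:
        order = sorted(range(len(row)), key=lambda i: (-row[i], i))
        best = row[order[0]]
        second = row[order[1]] if len(row) > 1 else 0.0
        if best < other_threshold:
            out.append("other")
        elif best - second < undefined_threshold:
            out.append("undefined")
        else:
            out.append(cell_types[order[0]])
    return np.array(out, dtype=object)


def pairwise_rand_index(truth, pred):
    """Rand index by enumerating all unordered pairs."""
    n = len(truth)
    agree = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            same_t = truth[i] == truth[j]
            same_p = pred[i] == pred[j]
            if same_t == same_p:
                agree += 1
    return agree / pairs


def confusion_matrix(truth, pred, classes):
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        cm[idx[t], idx[p]] += 1
    return cm


def brute_force_metrics(truth, pred):
    """accuracy, weighted F1, Cohen's kappa, multi-class MCC from the
    confusion matrix, computed with the textbook formulas."""
    classes = sorted(set(truth) | set(pred))
    cm = confusion_matrix(truth, pred, classes)
    n = cm.sum()
    acc = np.trace(cm) / n

    # weighted F1
    wf1 = 0.0
    for i, _ in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        wf1 += (cm[i, :].sum() / n) * f1

    # Cohen's kappa from marginals
    p_o = acc
    p_e = sum(cm[i, :].sum() * cm[:, i].sum() for i in range(len(classes))) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 1.0

    # multi-class MCC
    t = cm.sum(axis=1)  # true counts
    p = cm.sum(axis=0)  # predicted counts
    c = np.trace(cm)
    s = n
    num = c * s - np.dot(t, p)
    den = math.sqrt(float(s * s - np.dot(p, p))) * math.sqrt(float(s * s - np.dot(t, t)))
    mcc = num / den if den else 0.0
    return {"accuracy": acc, "weighted_f1": wf1, "cohens_kappa": kappa, "mcc": mcc}


def brute_force_neighbor_fractions(coords, labels, radius):
    """O(n^2) neighbor-composition matrix (closed ball, self excluded)."""
    coords = np.asarray(coords, dtype=float)
    labels = [str(x) for x in labels]
    types = sorted(set(labels))
    idx = {t: j for j, t in enumerate(types)}
    n = len(coords)
    out = np.zeros((n, len(types)))
    for i in range(n):
        neighbors = []
        for j in range(n):
            if i == j:
                continue
            if math.dist(coords[i], coords[j]) <= radius:
                neighbors.append(j)
        if neighbors:
            for j in neighbors:
                out[i, idx[labels[j]]] += 1
            out[i] /= len(neighbors)
        else:
            out[i, idx[labels[i]]] = 1.0
    return types, out
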