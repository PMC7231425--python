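"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive (double loops, exhaustive
enumeration) and shares no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_sq_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances of complete data by double loop."""
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = sum((values[i, d] - values[j, d]) ** 2 for d in range(values.shape[1]))
    return out


def naive_penalized_sq(values, observed) -> np.ndarray:
    """Variance-penalized squared distances by double loop: shared-dim
    squared differences plus one column variance per missing dim per row."""
    n, d = values.shape
    var = np.zeros(d)
    for k in range(d):
        col = [values[i, k] for i in range(n) if observed[i, k]]
        if len(col) >= 2:
            var[k] = np.var(col)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(d):
                if observed[i, k] and observed[j, k]:
                    acc += (values[i, k] - values[j, k]) ** 2
                if not observed[i, k]:
                    acc += var[k]
                if not observed[j, k]:
                    acc += var[k]
            out[i, j] = acc
    return out


def brute_force_exemplar_optimum(s, candidate_rows) -> tuple[float, np.ndarray]:
    """Global maximum of sum_i S(i, E(i)) over valid configurations.

    Enumerates every nonempty subset of the candidate list as the exemplar
    set; exemplars are self-assigned, everyone else goes to their most
    similar exemplar (optimal given the set).
    """
    candidate_rows = np.asarray(candidate_rows, dtype=int)
    n = s.n_rows
    best_obj = -np.inf
    best_e = None
    for r in range(1, candidate_rows.size + 1):
        for subset in itertools.combinations(candidate_rows, r):
            subset = np.array(subset)
            cols = s.cols(subset)
            e = subset[s.values[:, cols].argmax(axis=1)]
            e[subset] = subset
            obj = float(s.values[np.arange(n), s.cols(e)].sum())
            if obj > best_obj:
                best_obj = obj
                best_e = e
    return best_obj, best_e


def naive_responsibility(s_values: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-entry responsibility update by double loop."""
    n = s_values.shape[0]
    r = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            r[i, k] = s_values[i, k] - max(
                a[i, j] + s_values[i, j] for j in range(n) if j != k
            )
    return r


def naive_availability(r: np.ndarray) -> np.ndarray:
    """Per-entry availability update by double loop."""
    n = r.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            pos = sum(max(0.0, r[j, k]) for j in range(n) if j not in (i, k))
            if i == k:
                a[k, k] = sum(max(0.0, r[j, k]) for j in range(n) if j != k)
            else:
                a[i, k] = min(0.0, r[k, k] + pos)
    return a


def brute_force_accuracy(labels, classes) -> float:
    """Max matched fraction over all injective cluster-to-class mappings."""
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    lab_ids = sorted(set(labels.tolist()))
    cls_ids = sorted(set(classes.tolist()))
    size = max(len(lab_ids), len(cls_ids))
    padded_cls = list(cls_ids) + [None] * (size - len(cls_ids))
    padded_lab = list(lab_ids) + [None] * (size - len(lab_ids))
    best = 0
    for perm in itertools.permutations(padded_cls):
        matched = 0
        for lab, cls in zip(padded_lab, perm):
            if lab is None or cls is None:
                continue
            matched = matched + int(((labels == lab) & (classes == cls)).sum())
        best = max(best, matched)
    return best / labels.size


def direct_nmi(labels, classes) -> float:
    """Literal evaluation of the geometric-mean NMI formula by loops."""
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    n = labels.size
    lab_ids = sorted(set(labels.tolist()))
    cls_ids = sorted(set(classes.tolist()))
    num = 0.0
    for li in lab_ids:
        for cj in cls_ids:
            nij = int(((labels == li) & (classes == cj)).sum())
            ni = int((labels == li).sum())
            nj = int((classes == cj).sum())
            if nij > 0:
                num += nij * np.log(n * nij / (ni * nj))
    hi = sum(int((labels == li).sum()) * np.log(int((labels == li).sum()) / n) for li in lab_ids)
    hj = sum(int((classes == cj).sum()) * np.log(int((classes == cj).sum()) / n) for cj in cls_ids)
    den = np.sqrt(hi * hj)
    if den == 0:
        return 1.0 if (len(lab_ids) == 1 and len(cls_ids) == 1) else 0.0
    return float(num / den)


def naive_energy(data, labels, exemplars, mode="euclidean") -> float:
    """Within-cluster distance sum by explicit loops, using the rescaled
    partial squared distance."""
    total = 0.0
    for k, ex in enumerate(exemplars, start=1):
        for i in np.flatnonzero(np.asarray(labels) == k):
            if i == ex:
                continue
            shared = data.observed[i] & data.observed[ex]
            d2 = (
                data.d
                / shared.sum()
                * float(((data.values[i, shared] - data.values[ex, shared]) ** 2).sum())
            )
            total += d2 if mode == "squared" else float(np.sqrt(d2))
    return total
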