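"""Brute-force oracles shared by the unit and acceptance tests.

These deliberately use naive loops/enumeration, independent of the library
code paths they validate.
"""

import numpy as np


def oracle_accuracy(y, p):
    return sum(a == b for a, b in zip(y, p)) / len(y)


def oracle_f1(y, p, pos):
    tp = sum(1 for a, b in zip(y, p) if a == pos and b == pos)
    fp = sum(1 for a, b in zip(y, p) if a != pos and b == pos)
    fn = sum(1 for a, b in zip(y, p) if a == pos and b != pos)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def oracle_auc(y, s, pos):
    """Pair-counting Mann-Whitney statistic; ties count one half."""
    pos_scores = [si for yi, si in zip(y, s) if yi == pos]
    neg_scores = [si for yi, si in zip(y, s) if yi != pos]
    total = 0.0
    for a in pos_scores:
        for b in neg_scores:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos_scores) * len(neg_scores))


def oracle_f1_macro(y, p):
    classes = sorted(set(y))
    return sum(oracle_f1(y, p, c) for c in classes) / len(classes)


def oracle_f1_weighted(y, p):
    y = list(y)
    classes = sorted(set(y))
    return sum((y.count(c) / len(y)) * oracle_f1(y, p, c) for c in classes)


def oracle_frobenius_cosine(A, B):
    dot = na = nb = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            dot += A[i, j] * B[i, j]
            na += A[i, j] ** 2
            nb += B[i, j] ** 2
    return dot / np.sqrt(na * nb)
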