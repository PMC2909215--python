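"""Independent oracle implementations used to cross-check the package.

Everything here is written from the definitional formulas with plain loops
and exhaustive enumeration — deliberately naive and independent of the
library code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def nsc_brute_force(X, y, shrinkage, priors=None):
    """Nearest-shrunken-centroid fit/predict from the definitional formulas.

    X: samples x genes, y: labels.  Returns a dict of intermediate
    quantities plus a predict(X*) closure, all computed with plain loops.
    """
    classes = sorted(set(y))
    n, p = X.shape
    K = len(classes)
    idx = {c: [i for i in range(n) if y[i] == c] for c in classes}
    counts = {c: len(idx[c]) for c in classes}
    centroids = {
        c: [sum(X[i, j] for i in idx[c]) / counts[c] for j in range(p)]
        for c in classes
    }
    overall = [sum(X[i, j] for i in range(n)) / n for j in range(p)]
    s = []
    for j in range(p):
        ss = 0.0
        for c in classes:
            for i in idx[c]:
                ss += (X[i, j] - centroids[c][j]) ** 2
        s.append(math.sqrt(ss / (n - K)))
    s0 = float(np.median(s))
    m = {c: math.sqrt(1.0 / counts[c] - 1.0 / n) for c in classes}
    d = {
        c: [
            (centroids[c][j] - overall[j]) / (m[c] * (s[j] + s0))
            for j in range(p)
        ]
        for c in classes
    }

    def soft(v):
        return math.copysign(max(abs(v) - shrinkage, 0.0), v)

    d_shrunk = {c: [soft(v) for v in d[c]] for c in classes}
    shrunken = {
        c: [
            overall[j] + m[c] * (s[j] + s0) * d_shrunk[c][j]
            for j in range(p)
        ]
        for c in classes
    }
    active = [j for j in range(p) if any(d_shrunk[c][j] != 0 for c in classes)]
    if priors is None:
        priors = {c: counts[c] / n for c in classes}

    def predict(Xstar):
        labels = []
        for row in Xstar:
            best, best_score = None, math.inf
            for c in classes:  # sorted: first minimum wins ties
                score = sum(
                    (row[j] - shrunken[c][j]) ** 2 / (s[j] + s0) ** 2
                    for j in active
                ) - 2.0 * math.log(priors[c])
                if score < best_score - 1e-12:
                    best, best_score = c, score
            labels.append(best)
        return labels

    return {
        "classes": classes,
        "s": s,
        "s0": s0,
        "d": d,
        "d_shrunk": d_shrunk,
        "shrunken": shrunken,
        "active": active,
        "predict": predict,
    }


def hypergeom_tail_enum(k, N, K, n):
    """P(|A ∩ B| >= k) by exhaustive enumeration of all size-n subsets of a
    size-N universe, with A a fixed size-K subset.  Only feasible for small N.
    """
    universe = list(range(N))
    a = set(universe[:K])
    hits = 0
    total = 0
    for b in combinations(universe, n):
        total += 1
        if len(a & set(b)) >= k:
            hits += 1
    return hits / total


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher exact p for a 2x2 table by enumerating all tables
    with the same margins and summing probabilities <= the observed one.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    N = row1 + row2

    def prob(x):  # P(first cell = x) under fixed margins
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(N, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def pearson_r_definitional(x, y):
    """Pearson correlation from the textbook formula, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(
        sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
    )
    return num / den


def pooled_sam_scale(x1, x2):
    """s(i) from the definitional pooled-error formula, plain loops."""
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    return math.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
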