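"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: MI is a
double loop over joint-histogram cells, AUC enumerates positive/negative
pairs, and the greedy-mRMR oracle recomputes every step's criterion from
scratch.
"""

import itertools
import math
from collections import Counter

import numpy as np


def naive_mi(x, y):
    """Plug-in mutual information in bits via an explicit cell loop."""
    x, y = list(x), list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return max(total, 0.0)


def naive_entropy(x):
    n = len(list(x))
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(x).values() if c
    )


def pairwise_auc(scores, labels):
    """Mann-Whitney AUC by enumerating all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_mrmr(codes, y, k, variant="difference", eps=1e-12):
    """Exhaustive greedy mRMR on small discretized matrices.

    ``codes`` is (n, d) integer bin codes; names are x0..x{d-1} with the
    same lexicographic tie-break as the implementation.
    """
    n, d = codes.shape
    names = [f"x{j}" for j in range(d)]
    rel = [naive_mi(codes[:, j], y) for j in range(d)]
    selected = []
    while len(selected) < k:
        best = None
        for j in range(d):
            if j in selected:
                continue
            if selected:
                red = sum(naive_mi(codes[:, j], codes[:, s]) for s in selected)
                red /= len(selected)
                crit = rel[j] - red if variant == "difference" else rel[j] / max(red, eps)
            else:
                crit = rel[j]
            key = (-crit, names[j])
            if best is None or key < best[0]:
                best = (key, j)
        selected.append(best[1])
    return [names[j] for j in selected]
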