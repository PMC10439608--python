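"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive: plain Python loops, textbook
formulas, exact rational arithmetic where floating point could blur a
boundary decision. None of it shares code with the implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def brute_silhouette(points, labels):
    """Silhouette per point by direct enumeration of all pairs.

    points: list of coordinate tuples; labels: parallel list of cluster
    names. Members of singleton clusters score 0.
    """

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    n = len(points)
    out = []
    for i in range(n):
        same = [dist(points[i], points[j]) for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            out.append(0.0)
            continue
        a = sum(same) / len(same)
        b = math.inf
        for other in set(labels) - {labels[i]}:
            ds = [dist(points[i], points[j]) for j in range(n) if labels[j] == other]
            b = min(b, sum(ds) / len(ds))
        m = max(a, b)
        out.append(0.0 if m == 0 else (b - a) / m)
    return out


def brute_ari(labels_a, labels_b):
    """Adjusted Rand index by counting concordant pairs directly."""
    n = len(labels_a)
    assert n == len(labels_b)
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    index = ss
    sum_a = ss + sd
    sum_b = ss + ds
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0 if index == maximum else 0.0
    return (index - expected) / (maximum - expected)


def brute_point_in_polygon(x, y, polygon):
    """Even-odd membership with exact rational arithmetic.

    Boundary points are inside. Uses the crossing-number rule with a
    half-open vertex convention, evaluated in Fractions so no float
    rounding can flip a decision on rational inputs.
    """
    px, py = Fraction(x), Fraction(y)
    verts = [(Fraction(a), Fraction(b)) for a, b in polygon]
    n = len(verts)
    for i in range(n):
        (ax, ay), (bx, by) = verts[i], verts[(i + 1) % n]
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if cross == 0 and min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by):
            return True
    crossings = 0
    for i in range(n):
        (ax, ay), (bx, by) = verts[i], verts[(i + 1) % n]
        if ay == by:
            continue
        if min(ay, by) <= py < max(ay, by):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            if x_int > px:
                crossings += 1
    return crossings % 2 == 1


def pca_eigen_embedding(X):
    """First two principal components via an explicit eigen-decomposition
    of the covariance matrix (no SVD, no sklearn)."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return Xc @ vecs[:, order[:2]], vals[order]
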