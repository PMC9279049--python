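"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the grade formulas, direct enumeration for convolution,
pooling, k-means partitions and concordant pairs.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def gpa_oracle(courses, denominator="score"):
    """Exact rational GPA: sum(credit * (score-50)/10) / sum(score)."""
    num = Fraction(0)
    den = Fraction(0)
    for _, score, credit in courses:
        f = (Fraction(score) - 50) / 10
        num += Fraction(credit) * f
        den += Fraction(score) if denominator == "score" else Fraction(credit)
    return num / den


def entropy_oracle(counts):
    """-sum p ln p computed term by term with math.fsum."""
    total = sum(counts)
    terms = []
    for c in counts:
        if c > 0:
            p = c / total
            terms.append(-p * math.log(p))
    return math.fsum(terms)


def anomaly_oracle(point, centroid, cluster_size, cohort_size):
    d = math.sqrt(
        math.fsum((a - b) ** 2 for a, b in zip(point, centroid))
    )
    return d * (1 - cluster_size / cohort_size)


def conv_valid_oracle(x, k):
    """Direct four-loop valid convolution (cross-correlation) of 2-D arrays."""
    xh, xw = x.shape
    kh, kw = k.shape
    out = np.zeros((xh - kh + 1, xw - kw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (x[i : i + kh, j : j + kw] * k).sum()
    return out


def mean_pool_oracle(x):
    """2x2 block means; odd edges averaged over the genuine cells only."""
    h, w = x.shape
    out = np.zeros((-(-h // 2), -(-w // 2)))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
            out[i, j] = block.mean()
    return out


def kmeans_sse_oracle(points, k=3):
    """Global optimum SSE by exhaustive enumeration of all k^n assignments."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    assignments = np.array(list(itertools.product(range(k), repeat=n)))
    best = np.inf
    for a in assignments:
        sse = 0.0
        for c in range(k):
            members = points[a == c]
            if len(members):
                centroid = members.mean(axis=0)
                sse += ((members - centroid) ** 2).sum()
        best = min(best, sse)
    return best


def kmeans_sse_oracle_fast(points, k=3):
    """Vectorized exhaustive enumeration (all k^n assignments at once)."""
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    grids = np.array(list(itertools.product(range(k), repeat=n)))  # (A, n)
    sse = np.zeros(len(grids))
    for c in range(k):
        mask = grids == c  # (A, n)
        counts = mask.sum(axis=1)  # (A,)
        sums = mask @ points  # (A, d)
        sumsq = mask @ (points**2).sum(axis=1)  # (A,)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = sumsq - (sums**2).sum(axis=1) / counts
        sse += np.where(counts > 0, contrib, 0.0)
    return float(sse.min())


def confusion_oracle(labels, preds):
    tp = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 1)
    fp = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 1)
    fn = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 0)
    tn = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 0)
    return tp, fp, fn, tn


def auc_pairs_oracle(labels, scores):
    """Concordant-pair fraction with half credit for ties, O(n^2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return float("nan")
    num = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(pos) * len(neg))
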