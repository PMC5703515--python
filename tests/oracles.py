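"""Independent brute-force reference implementations used only by tests.

Each function follows its textbook definition as literally as possible
(explicit loops, dictionaries, pairwise comparisons) so that it shares no
code path with the package implementation it checks.
"""

import math
from collections import Counter

import numpy as np
from scipy.stats import percentileofscore


def sampen_bruteforce(x, m, r, sd=None):
    x = list(map(float, x))
    n = len(x)
    tol = r * (float(np.std(x)) if sd is None else sd)
    if tol == 0:
        return 0.0

    def matches(mm):
        count = 0
        for i in range(n - mm + 1):
            for j in range(i + 1, n - mm + 1):
                if all(abs(x[i + t] - x[j + t]) <= tol for t in range(mm)):
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def ctm_bruteforce(x, rho):
    x = list(map(float, x))
    inside = total = 0
    for t in range(len(x) - 2):
        d1 = x[t + 1] - x[t]
        d2 = x[t + 2] - x[t + 1]
        total += 1
        if math.sqrt(d1 * d1 + d2 * d2) < rho:
            inside += 1
    return inside / total


def entropy_bruteforce(labels):
    counts = Counter(labels)
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def su_bruteforce(x_labels, y_labels):
    hx = entropy_bruteforce(x_labels)
    hy = entropy_bruteforce(y_labels)
    hxy = entropy_bruteforce(list(zip(x_labels, y_labels)))
    if hx + hy == 0:
        return 0.0
    ig = hx + hy - hxy
    return 2.0 * ig / (hx + hy)


def auc_mannwhitney(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mountain_bruteforce(differences):
    out = []
    for d in sorted(differences):
        p = percentileofscore(differences, d, kind="mean")
        out.append((float(d), min(p, 100.0 - p)))
    return out


def moments_bruteforce(x):
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    if m2 == 0:
        return mu, 0.0, 0.0, 0.0
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return mu, m2, m3 / m2 ** 1.5, m4 / m2 ** 2
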