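"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(triple enumeration, dense linear algebra, closed-form entropy, exhaustive
substring search) without touching the implementation path it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def cocitation_bruteforce(edges, candidates):
    """Edge weights by enumerating all (citer, a, b) triples."""
    candidates = sorted(set(candidates))
    citers = {c for c, _ in edges}
    weights = {}
    for citer in citers:
        cited = {b for a, b in edges if a == citer}
        for i, u in enumerate(candidates):
            for v in candidates[i + 1 :]:
                if u in cited and v in cited:
                    weights[(u, v)] = weights.get((u, v), 0) + 1
    return weights


def pagerank_dense(nodes, edges, damping=0.85, tol=1e-12, max_iter=100000):
    """Dense power iteration with uniform dangling redistribution."""
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    out_deg = np.zeros(n)
    m = np.zeros((n, n))
    for u, v in edges:
        if u in index and v in index:
            m[index[v], index[u]] += 1.0
            out_deg[index[u]] += 1.0
    for j in range(n):
        if out_deg[j] > 0:
            m[:, j] /= out_deg[j]
    dangling = out_deg == 0
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = damping * (m @ p + p[dangling].sum() / n) + (1 - damping) / n
        if np.abs(nxt - p).sum() < tol:
            return nxt
        p = nxt
    return p


def nmi_entropy_oracle(n11, n10, n01, n00):
    """NMI of a 2x2 contingency table from first principles."""
    n = n11 + n10 + n01 + n00
    ps = [n11 / n, n10 / n, n01 / n, n00 / n]
    pa = ps[0] + ps[1]
    pb = ps[0] + ps[2]

    def h(probs):
        return -sum(p * math.log(p) for p in probs if p > 0)

    ha, hb = h([pa, 1 - pa]), h([pb, 1 - pb])
    if ha == 0 or hb == 0:
        return 0.0
    hj = h(ps)
    mi = ha + hb - hj
    return max(0.0, mi) / math.sqrt(ha * hb)


def tfidf_oracle(count_rows, vocab_size):
    """Smoothed add-one TF-IDF with L2 row normalisation, coded directly.

    ``count_rows``: list of dicts column->raw count.  Returns a dense array.
    """
    n = len(count_rows)
    df = np.zeros(vocab_size)
    for row in count_rows:
        for j in row:
            df[j] += 1
    idf = np.log((1 + n) / (1 + df)) + 1
    out = np.zeros((n, vocab_size))
    for i, row in enumerate(count_rows):
        for j, c in row.items():
            out[i, j] = c * idf[j]
        norm = np.linalg.norm(out[i])
        if norm > 0:
            out[i] /= norm
    return out


_ALNUM = set("abcdefghijklmnopqrstuvwxyz0123456789")


def naive_synonym_scan(text, synonym):
    """Exhaustive separator-variant substring scan with boundary checks.

    Independent of the regex matcher: enumerates every separator assignment
    between the synonym's alphanumeric runs and searches each variant as a
    plain lowercase substring with manual word-boundary checks.
    """
    runs = []
    cur = ""
    for ch in synonym.lower():
        if ch in _ALNUM:
            cur += ch
        elif cur:
            runs.append(cur)
            cur = ""
    if cur:
        runs.append(cur)
    if not runs:
        return False
    text = text.lower()
    for seps in product(["", "-", " ", "/"], repeat=len(runs) - 1):
        variant = runs[0]
        for sep, run in zip(seps, runs[1:]):
            variant += sep + run
        start = 0
        while True:
            i = text.find(variant, start)
            if i < 0:
                break
            before = text[i - 1] if i > 0 else " "
            after = text[i + len(variant)] if i + len(variant) < len(text) else " "
            if before not in _ALNUM and after not in _ALNUM:
                return True
            start = i + 1
    return False


def kde_right_tail_quadrature(points, x0, bandwidth):
    """Right-tail mass of a Gaussian KDE by numerical quadrature."""
    from scipy.integrate import quad

    points = np.asarray(points, dtype=float)

    def density(x):
        z = (x - points) / bandwidth
        return np.exp(-0.5 * z * z).sum() / (
            len(points) * bandwidth * math.sqrt(2 * math.pi)
        )

    hi = points.max() + 12 * bandwidth
    if x0 >= hi:
        return 0.0
    val, _ = quad(density, x0, hi, limit=400)
    return val
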