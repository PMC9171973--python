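"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a quantity from first principles (explicit
loops, exhaustive enumeration, textbook formulas) without touching the
package's vectorized or library-backed code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pair_counts_loop(x, y):
    a = b = c = d = 0
    for xi, yi in zip(x, y):
        if xi and yi:
            a += 1
        elif xi and not yi:
            b += 1
        elif yi and not xi:
            c += 1
        else:
            d += 1
    return a, b, c, d


def rogot_goldberg_loop(x, y):
    a, b, c, d = pair_counts_loop(x, y)
    s = 0.0
    if 2 * a + b + c:
        s += a / (2 * a + b + c)
    if 2 * d + b + c:
        s += d / (2 * d + b + c)
    return s


def tanimoto_loop(x, y):
    a, b, c, _ = pair_counts_loop(x, y)
    return a / (a + b + c) if a + b + c else 0.0


def mcc_formula(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc_pair_counting(scores, is_active):
    """P(random active outranks random inactive), ties counted 1/2."""
    wins = ties = 0
    pos = [s for s, a in zip(scores, is_active) if a]
    neg = [s for s, a in zip(scores, is_active) if not a]
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ef_direct(scores, is_active, chi):
    """EF on the list sorted by decreasing score (stable on ties)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n = len(scores)
    n_chi = max(1, int(math.floor(chi * n + 0.5)))
    p_chi = sum(1 for i in order[:n_chi] if is_active[i])
    p_tot = sum(is_active)
    return (p_chi / n_chi) / (p_tot / n)


def gmean_best_threshold(scores, is_active):
    """Lowest threshold maximizing sqrt(sens * spec); calls score >= t."""
    p = sum(is_active)
    n = len(is_active) - p
    best_t, best_g = None, -1.0
    for t in sorted(set(scores)):
        tp = sum(1 for s, a in zip(scores, is_active) if a and s >= t)
        tn = sum(1 for s, a in zip(scores, is_active) if not a and s < t)
        g = math.sqrt((tp / p) * (tn / n))
        if g > best_g + 1e-12:
            best_t, best_g = t, g
    return best_t


def _comb2(n):
    return n * (n - 1) // 2


def ari_pair_counting(la, lb):
    """Adjusted Rand index from the pair-level contingency table."""
    la, lb = list(la), list(lb)
    n = len(la)
    classes_a = sorted(set(la))
    classes_b = sorted(set(lb))
    nij = {(i, j): 0 for i in classes_a for j in classes_b}
    for x, y in zip(la, lb):
        nij[(x, y)] += 1
    sum_ij = sum(_comb2(v) for v in nij.values())
    sum_a = sum(_comb2(la.count(i)) for i in classes_a)
    sum_b = sum(_comb2(lb.count(j)) for j in classes_b)
    total = _comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def nmi_entropy(la, lb):
    """NMI with arithmetic-mean normalization, from entropy tables."""
    la, lb = list(la), list(lb)
    n = len(la)

    def entropy(labels):
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / n
            h -= p * math.log(p)
        return h

    ha, hb = entropy(la), entropy(lb)
    mi = 0.0
    for ca in set(la):
        for cb in set(lb):
            nab = sum(1 for x, y in zip(la, lb) if x == ca and y == cb)
            if nab:
                mi += (nab / n) * math.log(n * nab / (la.count(ca) * lb.count(cb)))
    denom = (ha + hb) / 2
    if denom == 0:
        return 1.0
    return mi / denom


def silhouette_direct(dist, labels):
    """Mean per-point (b - a)/max(a, b); singleton clusters contribute 0."""
    labels = list(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(dist[i][j] for j in own) / len(own)
        b = math.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist[i][j] for j in other) / len(other))
        scores.append((b - a) / max(a, b))
    return sum(scores) / n


def spearman_rank_formula(u, v):
    """Spearman rho via Pearson correlation of average ranks."""

    def ranks(x):
        order = sorted(range(len(x)), key=lambda i: x[i])
        r = [0.0] * len(x)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    ru, rv = ranks(list(u)), ranks(list(v))
    mu, mv = sum(ru) / len(ru), sum(rv) / len(rv)
    num = sum((a - mu) * (b - mv) for a, b in zip(ru, rv))
    den = math.sqrt(
        sum((a - mu) ** 2 for a in ru) * sum((b - mv) ** 2 for b in rv)
    )
    return num / den


def set_partitions(items):
    """All set partitions of a sequence, as label vectors."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        k = max(part, default=-1) + 1
        for c in range(k + 1):
            yield [c] + part


def min_normalized_cut(W):
    """Exhaustive minimum normalized cut over all 2-partitions (n <= ~12)."""
    n = len(W)
    best, best_mask = math.inf, None
    for mask in range(1, 2 ** (n - 1)):  # fix vertex n-1 in side B
        A = [i for i in range(n) if mask >> i & 1]
        B = [i for i in range(n) if not mask >> i & 1]
        cut = sum(W[i][j] for i in A for j in B)
        volA = sum(W[i][j] for i in A for j in range(n))
        volB = sum(W[i][j] for i in B for j in range(n))
        if volA == 0 or volB == 0:
            continue
        ncut = cut / volA + cut / volB
        if ncut < best:
            best, best_mask = ncut, [1 if i in A else 0 for i in range(n)]
    return best, best_mask
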