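"""Brute-force reference implementations used to cross-check the package.

These are deliberately naive (double loops, explicit enumeration) and share
no code with the implementations they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def hamming(matrix):
    """Pairwise mismatch counts between columns by double loop."""
    n = matrix.shape[1]
    out = np.zeros((n, n), dtype=int)
    for a in range(n):
        for b in range(n):
            out[a, b] = int((matrix[:, a] != matrix[:, b]).sum())
    return out


def mst_total_weight(dist):
    """Minimum spanning-tree weight by exhaustive enumeration (small k)."""
    k = dist.shape[0]
    if k == 1:
        return 0
    all_edges = [(a, b) for a in range(k) for b in range(a + 1, k)]
    best = None
    for subset in combinations(all_edges, k - 1):
        # connectivity check
        seen = {0}
        frontier = [0]
        adj = {i: [] for i in range(k)}
        for a, b in subset:
            adj[a].append(b)
            adj[b].append(a)
        while frontier:
            node = frontier.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        if len(seen) == k:
            w = sum(dist[a, b] for a, b in subset)
            best = w if best is None else min(best, w)
    return best


def identity_probability(haps):
    """P(two haplotypes drawn without replacement are identical strings)."""
    n = haps.shape[1]
    same = 0
    for a in range(n):
        for b in range(n):
            if a != b and (haps[:, a] == haps[:, b]).all():
                same += 1
    return same / (n * (n - 1))


def ehh_curve(haps, core, side):
    """EHH per flank, counting identical haplotype strings explicitly."""
    n_var = haps.shape[0]
    values = []
    if side == "right":
        flanks = range(core + 1, n_var)
        for x in flanks:
            values.append(identity_probability(haps[core : x + 1]))
    else:
        flanks = range(core - 1, -1, -1)
        for x in flanks:
            values.append(identity_probability(haps[x : core + 1]))
    return values


def class_freqs(haps):
    counts = {}
    for col in range(haps.shape[1]):
        key = tuple(haps[:, col])
        counts[key] = counts.get(key, 0) + 1
    return sorted((c / haps.shape[1] for c in counts.values()), reverse=True)


def garud_h(haps):
    p = class_freqs(haps)
    h1 = sum(x * x for x in p)
    h12 = (sum(p[:2])) ** 2 + sum(x * x for x in p[2:])
    h123 = (sum(p[:3])) ** 2 + sum(x * x for x in p[3:])
    return h1, h12, h123, (h1 - p[0] ** 2) / h1


def hap_diversity(haps):
    p = class_freqs(haps)
    n = haps.shape[1]
    return (1 - sum(x * x for x in p)) * n / (n - 1)


def pi(haps, accessible):
    """Mean pairwise Hamming distance per accessible site."""
    n = haps.shape[1]
    total = 0
    for a, b in combinations(range(n), 2):
        total += int((haps[:, a] != haps[:, b]).sum())
    return total / (n * (n - 1) / 2) / accessible


def dxy(hapsA, hapsB, accessible):
    total = 0
    for a in range(hapsA.shape[1]):
        for b in range(hapsB.shape[1]):
            total += int((hapsA[:, a] != hapsB[:, b]).sum())
    return total / (hapsA.shape[1] * hapsB.shape[1]) / accessible


def patterson_d(freqs):
    """Site-pattern D with the A~C-positive sign convention; O polarised."""
    num = den = 0.0
    for pA, pB, pC, pO in freqs:
        if pO > 0.5:
            pA, pB, pC, pO = 1 - pA, 1 - pB, 1 - pC, 1 - pO
        ac = pA * (1 - pB) * pC * (1 - pO)
        bc = (1 - pA) * pB * pC * (1 - pO)
        num += ac - bc
        den += ac + bc
    return num / den if den else float("nan")
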