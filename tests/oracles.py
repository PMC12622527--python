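"""Independent brute-force reference implementations for the metrics.

These deliberately avoid the package's own code paths: sorting + counting
loops only, so they can arbitrate the vectorised implementations.
"""

import math

import numpy as np


def rank_order(scores, ids):
    """Indices sorted by descending score, ids breaking ties ascending."""
    return sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))


def ef_brute(scores, labels, ids, fraction):
    order = rank_order(scores, ids)
    n = len(scores)
    top = math.ceil(fraction * n)
    hits = sum(labels[i] for i in order[:top])
    total = sum(labels)
    return (hits / top) / (total / n)


def auroc_brute(scores, labels):
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


def spearman_brute(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def bedroc_brute(scores, labels, ids, alpha):
    """Truchon-Bayly BEDROC from the defining RIE sum, loop arithmetic."""
    order = rank_order(scores, ids)
    n = len(scores)
    act_ranks = [k + 1 for k, i in enumerate(order) if labels[i] == 1]
    n_act = len(act_ranks)
    s = sum(math.exp(-alpha * r / n) for r in act_ranks)
    rand = (n_act / n) * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
    rie = s / rand
    ra = n_act / n
    factor = ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    return rie * factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))


def contact_counts_brute(pose, cutoff):
    """All-pairs recount of typed close contacts."""
    counts = {}
    for ra in pose.receptor.atoms:
        for la in pose.ligand.atoms:
            d = math.dist(ra.coords, la.coords)
            if d <= cutoff:
                t1, t2 = sorted((ra.autodock_type, la.autodock_type))
                key = f"{cutoff:.1f}({t1}, {t2})"
                counts[key] = counts.get(key, 0) + 1
    return counts


def electrostatics_brute(pose, cutoff):
    sums = {}
    for ra in pose.receptor.atoms:
        for la in pose.ligand.atoms:
            d = math.dist(ra.coords, la.coords)
            if d <= cutoff:
                t1, t2 = sorted((ra.autodock_type, la.autodock_type))
                key = f"elec({t1}, {t2})"
                sums[key] = sums.get(key, 0.0) + ra.partial_charge * la.partial_charge / d
    return sums
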