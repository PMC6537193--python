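"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles with plain loops and
exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def knn_brute(values: np.ndarray, samples: list[str], i: int, k: int) -> list[str]:
    scored = [
        (-values[i, j], samples[j]) for j in range(len(samples)) if j != i
    ]
    scored.sort()
    return [s for _, s in scored[:k]]


def _dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def dunn_brute(points, labels) -> float:
    pts = [list(np.atleast_1d(p)) for p in points]
    groups = {}
    for p, lab in zip(pts, labels):
        groups.setdefault(lab, []).append(p)
    diam = 0.0
    for mem in groups.values():
        for a, b in itertools.combinations(mem, 2):
            diam = max(diam, _dist(a, b))
    inter = math.inf
    for la, lb in itertools.combinations(groups, 2):
        for a in groups[la]:
            for b in groups[lb]:
                inter = min(inter, _dist(a, b))
    return inter / diam


def silhouette_brute(points, labels) -> float:
    pts = [list(np.atleast_1d(p)) for p in points]
    labs = list(labels)
    uniq = sorted(set(labs), key=str)
    scores = []
    for i, p in enumerate(pts):
        own = [j for j in range(len(pts)) if labs[j] == labs[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(_dist(p, pts[j]) for j in own) / len(own)
        b = math.inf
        for lab in uniq:
            if lab == labs[i]:
                continue
            mem = [j for j in range(len(pts)) if labs[j] == lab]
            b = min(b, sum(_dist(p, pts[j]) for j in mem) / len(mem))
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return sum(scores) / len(scores)


def davies_bouldin_brute(points, labels) -> float:
    pts = [list(np.atleast_1d(p)) for p in points]
    groups = {}
    for p, lab in zip(pts, labels):
        groups.setdefault(lab, []).append(p)
    labs = sorted(groups, key=str)
    cent = {
        lab: [sum(c) / len(mem) for c in zip(*mem)] for lab, mem in groups.items()
    }
    sig = {
        lab: sum(_dist(p, cent[lab]) for p in mem) / len(mem)
        for lab, mem in groups.items()
    }
    total = 0.0
    for la in labs:
        worst = 0.0
        for lb in labs:
            if la == lb:
                continue
            worst = max(worst, (sig[la] + sig[lb]) / _dist(cent[la], cent[lb]))
        total += worst
    return total / len(labs)


def viterbi_brute(obs, means, sd, switch_prob):
    """Exhaustive argmax over all state paths of the 3-state chain."""
    n_states = len(means)
    log_stay = math.log(1.0 - (n_states - 1) * switch_prob)
    log_switch = math.log(switch_prob)
    start = [log_switch, log_stay, log_switch][:n_states]

    def loglik(path):
        total = start[path[0]]
        for t in range(1, len(path)):
            total += log_stay if path[t] == path[t - 1] else log_switch
        for t, s in enumerate(path):
            total += -0.5 * ((obs[t] - means[s]) / sd) ** 2
        return total

    best, best_ll = None, -math.inf
    for path in itertools.product(range(n_states), repeat=len(obs)):
        ll = loglik(path)
        if ll > best_ll:
            best, best_ll = path, ll
    return list(best), best_ll


def count_overlaps_brute(chrom, start, end, targets) -> int:
    n = 0
    for t in targets:
        if t.chrom != chrom:
            continue
        if max(start, t.start) < min(end, t.end):
            n += 1
    return n


def max_matching_brute(calls, gold, min_recip_overlap=0.5) -> int:
    """Size of the maximum 1-to-1 matching between eligible call/gold pairs."""
    G = nx.Graph()
    for ci, c in enumerate(calls):
        for gi, g in enumerate(gold):
            if c.sample != g.sample or c.type != g.type or c.chrom != g.chrom:
                continue
            ov = max(0, min(c.end, g.end) - max(c.start, g.start))
            ro = min(ov / (c.end - c.start), ov / (g.end - g.start))
            if ro >= min_recip_overlap:
                G.add_edge(("c", ci), ("g", gi))
    if G.number_of_edges() == 0:
        return 0
    return len(nx.algorithms.matching.max_weight_matching(G, maxcardinality=True))
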