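"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (math/stdlib plus raw
itertools enumeration) and deliberately shares no code with the package.
"""
from __future__ import annotations

import math
from collections import Counter
from itertools import combinations, product


def entropy_oracle(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    return -sum((v / n) * math.log2(v / n) for v in Counter(labels).values())


# ---------------------------------------------------------------------------
# MDL discretization by exhaustive recursion
# ---------------------------------------------------------------------------

def _boundary_candidates(pairs):
    """Midpoints between consecutive distinct values with impure label union."""
    distinct, labels = [], []
    for v, l in pairs:
        if distinct and v == distinct[-1]:
            labels[-1].add(l)
        else:
            distinct.append(v)
            labels.append({l})
    return [(distinct[i] + distinct[i + 1]) / 2.0
            for i in range(len(distinct) - 1)
            if len(labels[i] | labels[i + 1]) > 1]


def mdl_cuts_oracle(values, labels) -> list[float]:
    pairs = sorted(zip(values, labels), key=lambda p: p[0])

    def rec(pairs):
        n = len(pairs)
        labs = [l for _, l in pairs]
        cands = _boundary_candidates(pairs)
        if not cands:
            return []
        best = None
        for cut in cands:
            left = [p for p in pairs if p[0] < cut]
            right = [p for p in pairs if p[0] >= cut]
            l_labs = [l for _, l in left]
            r_labs = [l for _, l in right]
            gain = (entropy_oracle(labs)
                    - len(left) / n * entropy_oracle(l_labs)
                    - len(right) / n * entropy_oracle(r_labs))
            if best is None or gain > best[0]:
                best = (gain, cut, left, right, l_labs, r_labs)
        gain, cut, left, right, l_labs, r_labs = best
        c, c1, c2 = len(set(labs)), len(set(l_labs)), len(set(r_labs))
        delta = math.log2(3 ** c - 2) - (c * entropy_oracle(labs)
                                         - c1 * entropy_oracle(l_labs)
                                         - c2 * entropy_oracle(r_labs))
        if gain > math.log2(n - 1) / n + delta / n:
            return rec(left) + [cut] + rec(right)
        return []

    return sorted(rec(pairs))


# ---------------------------------------------------------------------------
# Spanning trees
# ---------------------------------------------------------------------------

def max_spanning_tree_weight(weights) -> float:
    """Maximum total weight over all spanning trees of the complete graph
    given a dense symmetric weight matrix (exhaustive enumeration)."""
    p = len(weights)
    if p <= 1:
        return 0.0
    edges = list(combinations(range(p), 2))
    best = None
    for subset in combinations(edges, p - 1):
        parent = list(range(p))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        w = sum(weights[a][b] for a, b in subset)
        if best is None or w > best:
            best = w
    return best


# ---------------------------------------------------------------------------
# Full-joint posterior enumeration
# ---------------------------------------------------------------------------

def posterior_oracle(model, evidence: dict) -> float:
    """P(class=positive | evidence) by summing the full joint table."""
    nodes = list(model.structure.nodes)
    cls = model.class_name
    state_idx = {n: {s: i for i, s in enumerate(model.states[n])} for n in nodes}
    fixed = {n: state_idx[n][str(v)] for n, v in evidence.items()}
    free = [n for n in nodes if n not in fixed]
    mass = [0.0, 0.0]
    for combo in product(*[range(len(model.states[n])) for n in free]):
        assign = dict(zip(free, combo)) | fixed
        w = 1.0
        for n in nodes:
            cpt = model.cpts[n]
            idx = tuple(assign[p] for p in cpt.parents) + (assign[n],)
            w *= float(cpt.table[idx])
        mass[assign[cls]] += w
    return mass[1] / (mass[0] + mass[1])


# ---------------------------------------------------------------------------
# AUC by pair counting
# ---------------------------------------------------------------------------

def auc_pairs_oracle(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0
               for sp in pos for sn in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Exhaustive subset search
# ---------------------------------------------------------------------------

def exhaustive_best_subset(attributes, evaluator):
    """Highest-scoring nonempty subset; ties -> smaller, then lexicographic."""
    best = None
    attrs = sorted(attributes)
    for r in range(1, len(attrs) + 1):
        for combo in combinations(attrs, r):
            s = evaluator(frozenset(combo))
            key = (-s, r, combo)
            if best is None or key < best[0]:
                best = (key, frozenset(combo), s)
    return best[1], best[2]
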