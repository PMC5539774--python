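"""Bayesian-network classifiers: TAN and K2 structure learning, CPT
estimation, and exact posterior inference under full or partial evidence.

The joint distribution factorizes over the directed acyclic structure as
P(V1, ..., Vn) = prod_i P(Vi | Pa(Vi)).  In a TAN (tree-augmented naive
Bayes) structure the class has no parents and every predictor has the class
plus at most one predictor parent, the predictor tree being the maximum-
weight spanning tree under conditional mutual information I(X; Y | C).  K2
greedily adds, within a fixed node ordering, the predecessor parents that
maximize the Cooper–Herskovits marginal-likelihood score.

Inference marginalizes unobserved predictors exactly by variable
elimination, so posterior queries work under any partial evidence — the
mechanism behind incremental symptom observation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import CLASS, DISCRETE, DataTable, HcesError, get_logger

__all__ = [
    "NetworkStructure",
    "CPTable",
    "BayesClassifier",
    "Evidence",
    "conditional_mutual_information",
    "build_tan",
    "naive_bayes_structure",
    "ch_score",
    "k2_search",
    "fit_cpts",
    "posterior",
    "posterior_batch",
    "predict_proba",
]

log = get_logger("bayesnet")


class UnobservedConfigError(HcesError):
    """A CPT row for an unobserved parent configuration was queried while
    fitted with pseudocount 0."""


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkStructure:
    """Acyclic parent map over the class and predictor nodes."""

    nodes: tuple[str, ...]
    class_name: str
    parents: dict[str, tuple[str, ...]]
    edge_weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.class_name not in self.nodes:
            raise HcesError("class node missing from structure")
        if self.parents.get(self.class_name):
            raise HcesError("class node cannot have parents")
        known = set(self.nodes)
        for node, pa in self.parents.items():
            if node not in known or set(pa) - known:
                raise HcesError(f"unknown node in parent map near {node!r}")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        remaining = {n: set(self.parents.get(n, ())) for n in self.nodes}
        order: list[str] = []
        while remaining:
            ready = sorted(n for n, pa in remaining.items() if not pa)
            if not ready:
                raise HcesError("structure contains a cycle")
            for n in ready:
                order.append(n)
                del remaining[n]
            for pa in remaining.values():
                pa.difference_update(ready)
        return order

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if node in self.parents.get(n, ())]

    def tree_edges(self) -> set[frozenset]:
        """Undirected predictor–predictor edges (the augmenting tree)."""
        out = set()
        for node, pa in self.parents.items():
            for p in pa:
                if node != self.class_name and p != self.class_name:
                    out.add(frozenset((node, p)))
        return out


def naive_bayes_structure(table: DataTable) -> NetworkStructure:
    cls = table.class_name
    preds = tuple(table.predictor_names)
    parents = {cls: ()} | {p: (cls,) for p in preds}
    return NetworkStructure((cls, *preds), cls, parents)


# ---------------------------------------------------------------------------
# Conditional mutual information and TAN
# ---------------------------------------------------------------------------

def _codes3(table: DataTable, x: str, y: str):
    cx, cy = table.codes(x), table.codes(y)
    cc = table.class_codes()
    kx = len(table.states(x))
    ky = len(table.states(y))
    kc = len(table.states(table.class_name))
    counts = np.bincount((cx * ky + cy) * kc + cc,
                         minlength=kx * ky * kc).reshape(kx, ky, kc)
    return counts


def conditional_mutual_information(table: DataTable, x: str, y: str) -> float:
    """I(X; Y | C) in bits from maximum-likelihood frequencies."""
    if x == table.class_name or y == table.class_name:
        raise HcesError("conditional mutual information is between predictors")
    if x == y:
        raise HcesError("x and y must differ")
    counts = _codes3(table, x, y).astype(float)
    n = counts.sum()
    p_xyc = counts / n
    p_c = counts.sum(axis=(0, 1)) / n
    p_xc = counts.sum(axis=1) / n  # shape (kx, kc)
    p_yc = counts.sum(axis=0) / n  # shape (ky, kc)
    cmi = 0.0
    kx, ky, kc = counts.shape
    for c in range(kc):
        if p_c[c] == 0:
            continue
        joint = p_xyc[:, :, c]
        prod = np.outer(p_xc[:, c], p_yc[:, c]) / p_c[c]
        mask = joint > 0
        cmi += (joint[mask] * np.log2(joint[mask] * p_c[c]
                                      / prod[mask] / p_c[c])).sum()
    return float(max(cmi, 0.0))


def _prim_max_spanning_tree(weights: np.ndarray) -> list[tuple[int, int]]:
    """Prim on a dense weight matrix; ties break toward the lexicographically
    smallest (i, j) index pair so the tree is deterministic."""
    p = weights.shape[0]
    in_tree = {0}
    edges: list[tuple[int, int]] = []
    while len(in_tree) < p:
        best = None  # (weight, i, j)
        for i in sorted(in_tree):
            for j in range(p):
                if j in in_tree:
                    continue
                a, b = min(i, j), max(i, j)
                cand = (weights[i, j], -a, -b)
                if best is None or cand > best[0]:
                    best = (cand, i, j)
        _, i, j = best
        edges.append((min(i, j), max(i, j)))
        in_tree.add(j)
    return edges


def build_tan(table: DataTable) -> NetworkStructure:
    """Tree-augmented naive Bayes structure.

    Computes I(X;Y|C) for all predictor pairs, takes the maximum-weight
    spanning tree, directs it away from the root (the first predictor in
    column order — the choice does not affect the classifier's likelihood),
    and finally adds the class as a parent of every predictor.
    """
    preds = table.predictor_names
    cls = table.class_name
    p = len(preds)
    parents: dict[str, tuple[str, ...]] = {cls: ()}
    weights: dict[tuple[str, str], float] = {}
    if p >= 2:
        w = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                w[i, j] = w[j, i] = conditional_mutual_information(
                    table, preds[i], preds[j])
        edges = _prim_max_spanning_tree(w)
        adj: dict[int, list[int]] = {i: [] for i in range(p)}
        for i, j in edges:
            adj[i].append(j)
            adj[j].append(i)
            weights[(preds[i], preds[j])] = float(w[i, j])
        # direct away from the root by BFS
        tree_parent: dict[int, int] = {}
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for u in frontier:
                for v in sorted(adj[u]):
                    if v not in seen:
                        seen.add(v)
                        tree_parent[v] = u
                        nxt.append(v)
            frontier = nxt
        for i, name in enumerate(preds):
            if i in tree_parent:
                parents[name] = (cls, preds[tree_parent[i]])
            else:
                parents[name] = (cls,)
    else:
        for name in preds:
            parents[name] = (cls,)
    return NetworkStructure((cls, *preds), cls, parents, weights or None)


# ---------------------------------------------------------------------------
# Cooper–Herskovits score and K2
# ---------------------------------------------------------------------------

def ch_score(table: DataTable, node: str, parents: Sequence[str]) -> float:
    """Log Cooper–Herskovits score of ``node`` given an ordered parent list.

    sum_j [ lnGamma(r) - lnGamma(N_j + r) + sum_k lnGamma(N_jk + 1) ] over
    the observed parent configurations j, where r is the node's state count.
    """
    r = len(table.states(node))
    node_codes = table.codes(node)
    if table.n == 0:
        return 0.0
    if parents:
        cards = [len(table.states(p)) for p in parents]
        flat = np.zeros(table.n, dtype=np.int64)
        for p, k in zip(parents, cards):
            flat = flat * k + table.codes(p)
        n_config = int(np.prod(cards))
    else:
        flat = np.zeros(table.n, dtype=np.int64)
        n_config = 1
    counts = np.bincount(flat * r + node_codes, minlength=n_config * r)
    counts = counts.reshape(n_config, r).astype(float)
    observed = counts.sum(axis=1) > 0
    nj = counts[observed].sum(axis=1)
    score = (gammaln(r) - gammaln(nj + r)).sum()
    score += gammaln(counts[observed] + 1.0).sum()
    return float(score)


def k2_search(table: DataTable, order: Sequence[str] | None = None,
              max_parents: int = 1) -> NetworkStructure:
    """K2 structure search with the class as mandatory first parent.

    ``max_parents`` counts the class: 1 reproduces naive Bayes exactly.  For
    larger caps each node greedily gains, from its predecessors in
    ``order``, the single extra parent yielding the largest score
    improvement, until no candidate improves or the cap is reached.
    """
    cls = table.class_name
    preds = table.predictor_names
    if order is None:
        order = list(preds)
    if set(order) != set(preds):
        raise HcesError("K2 order must cover exactly the predictors")
    if max_parents < 1:
        raise HcesError("max_parents must be >= 1")
    parents: dict[str, tuple[str, ...]] = {cls: ()}
    for i, node in enumerate(order):
        pa = [cls]
        if max_parents > 1:
            current = ch_score(table, node, pa)
            candidates = list(order[:i])
            while len(pa) < max_parents and candidates:
                scored = [(ch_score(table, node, pa + [c]), c) for c in candidates]
                best_score, best_c = max(scored, key=lambda t: (t[0], -order.index(t[1])))
                if best_score > current:
                    pa.append(best_c)
                    candidates.remove(best_c)
                    current = best_score
                else:
                    break
        parents[node] = tuple(pa)
    return NetworkStructure((cls, *preds), cls, parents)


# ---------------------------------------------------------------------------
# CPT estimation
# ---------------------------------------------------------------------------

@dataclass
class CPTable:
    """Conditional probability table P(node | parents) with additive smoothing.

    ``table`` has shape (*parent_cards, node_card); every slice along the
    last axis sums to 1, except rows for unobserved parent configurations
    under pseudocount 0, which are NaN and error on use.
    """

    node: str
    parents: tuple[str, ...]
    states: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    table: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=-1)
        ok = np.isnan(sums) | (np.abs(sums - 1.0) <= 1e-12)
        if not ok.all():
            raise HcesError(f"CPT rows of {self.node!r} do not sum to 1")


def fit_cpts(table: DataTable, structure: NetworkStructure,
             pseudocount: float = 0.5) -> "BayesClassifier":
    """Estimate all CPTs by smoothed relative frequencies.

    P(v | pa) = (N_{v,pa} + pseudocount) / (N_pa + pseudocount * |states|)
    over the full Cartesian product of parent configurations; unobserved
    configurations become uniform when pseudocount > 0.
    """
    if pseudocount < 0:
        raise HcesError("pseudocount must be >= 0")
    cpts: dict[str, CPTable] = {}
    for node in structure.nodes:
        pa = structure.parents.get(node, ())
        r = len(table.states(node))
        cards = [len(table.states(p)) for p in pa]
        n_config = int(np.prod(cards)) if cards else 1
        flat = np.zeros(table.n, dtype=np.int64)
        for p, k in zip(pa, cards):
            flat = flat * k + table.codes(p)
        counts = np.bincount(flat * r + table.codes(node),
                             minlength=n_config * r).reshape(n_config, r).astype(float)
        denom = counts.sum(axis=1, keepdims=True) + pseudocount * r
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = (counts + pseudocount) / denom
        if pseudocount == 0:
            probs[counts.sum(axis=1) == 0] = np.nan
        cpts[node] = CPTable(node, tuple(pa), table.states(node),
                             tuple(table.states(p) for p in pa),
                             probs.reshape(*cards, r) if cards else probs.reshape(r),
                             pseudocount)
    return BayesClassifier(structure, cpts,
                           {n: table.states(n) for n in structure.nodes},
                           {"n": table.n, "smoothing": pseudocount})


# ---------------------------------------------------------------------------
# Classifier and inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Evidence:
    """Observed predictor states (any subset; never the class)."""

    assignments: Mapping[str, str]


@dataclass
class BayesClassifier:
    structure: NetworkStructure
    cpts: dict[str, CPTable]
    states: dict[str, tuple[str, ...]]
    training_meta: dict = field(default_factory=dict)

    @property
    def class_name(self) -> str:
        return self.structure.class_name

    @property
    def predictors(self) -> list[str]:
        return [n for n in self.structure.nodes if n != self.class_name]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "class_name": self.class_name,
            "nodes": list(self.structure.nodes),
            "structure": {n: list(self.structure.parents.get(n, ()))
                          for n in self.structure.nodes},
            "states": {n: list(s) for n, s in self.states.items()},
            "cpts": {n: c.table.tolist() for n, c in self.cpts.items()},
            "smoothing": {n: c.pseudocount for n, c in self.cpts.items()},
            "edge_weights": (
                {f"{a}|{b}": w for (a, b), w in self.structure.edge_weights.items()}
                if self.structure.edge_weights else None),
            "meta": self.training_meta,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BayesClassifier":
        d = json.loads(text)
        ew = None
        if d.get("edge_weights"):
            ew = {tuple(k.split("|")): v for k, v in d["edge_weights"].items()}
        structure = NetworkStructure(tuple(d["nodes"]), d["class_name"],
                                     {n: tuple(p) for n, p in d["structure"].items()},
                                     ew)
        states = {n: tuple(s) for n, s in d["states"].items()}
        cpts = {}
        for n in structure.nodes:
            pa = structure.parents.get(n, ())
            cpts[n] = CPTable(n, tuple(pa), states[n],
                              tuple(states[p] for p in pa),
                              np.asarray(d["cpts"][n], dtype=float),
                              d["smoothing"][n])
        return cls(structure, cpts, states, d.get("meta", {}))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "BayesClassifier":
        return cls.from_json(Path(path).read_text())


# -- variable elimination ----------------------------------------------------

def _factor_for(model: BayesClassifier, node: str,
                evidence_idx: Mapping[str, int]):
    """CPT as a (vars, array) factor, restricted by the evidence."""
    cpt = model.cpts[node]
    variables = list(cpt.parents) + [node]
    arr = cpt.table
    if arr.ndim != len(variables):
        arr = arr.reshape([len(model.states[v]) for v in variables])
    keep = []
    index: list = []
    for v in variables:
        if v in evidence_idx:
            index.append(evidence_idx[v])
        else:
            index.append(slice(None))
            keep.append(v)
    return keep, arr[tuple(index)]


def _multiply(f1, f2):
    v1, a1 = f1
    v2, a2 = f2
    merged = list(v1) + [v for v in v2 if v not in v1]
    sh1 = [a1.shape[v1.index(v)] if v in v1 else 1 for v in merged]
    sh2 = [a2.shape[v2.index(v)] if v in v2 else 1 for v in merged]
    a1b = a1.transpose([v1.index(v) for v in merged if v in v1]).reshape(sh1) \
        if v1 else a1.reshape(sh1)
    a2b = a2.transpose([v2.index(v) for v in merged if v in v2]).reshape(sh2) \
        if v2 else a2.reshape(sh2)
    return merged, a1b * a2b


def _marginalize(factor, var):
    variables, arr = factor
    ax = variables.index(var)
    return [v for v in variables if v != var], arr.sum(axis=ax)


def _barren_prune(model: BayesClassifier, observed: set[str]) -> list[str]:
    """Drop unobserved non-class leaves; their CPTs integrate to one."""
    nodes = set(model.structure.nodes)
    changed = True
    while changed:
        changed = False
        for node in sorted(nodes):
            if node in observed or node == model.class_name:
                continue
            if not any(node in model.structure.parents.get(c, ())
                       for c in nodes if c != node):
                nodes.discard(node)
                changed = True
    return [n for n in model.structure.topological_order() if n in nodes]


def posterior(model: BayesClassifier, ev: Evidence | Mapping[str, str]) -> float:
    """P(class = positive | evidence), marginalizing unobserved predictors.

    Exact inference by variable elimination; with a TAN or bounded-parent
    structure the intermediate factors stay small.
    """
    assignments = ev.assignments if isinstance(ev, Evidence) else ev
    evidence_idx: dict[str, int] = {}
    for name, state in assignments.items():
        if name == model.class_name:
            raise HcesError("class cannot be observed as evidence")
        if name not in model.states:
            raise HcesError(f"evidence on unknown attribute {name!r}")
        try:
            evidence_idx[name] = model.states[name].index(str(state))
        except ValueError:
            raise HcesError(
                f"unknown state {state!r} for attribute {name!r}") from None
    nodes = _barren_prune(model, set(evidence_idx))
    factors = [_factor_for(model, n, evidence_idx) for n in nodes]
    hidden = [n for n in reversed(nodes)
              if n != model.class_name and n not in evidence_idx]
    for h in hidden:
        involved = [f for f in factors if h in f[0]]
        rest = [f for f in factors if h not in f[0]]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        factors = rest + [_marginalize(prod, h)]
    result = ([], np.asarray(1.0))
    for f in factors:
        result = _multiply(result, f)
    variables, arr = result
    if variables != [model.class_name]:
        arr = np.moveaxis(arr, variables.index(model.class_name), 0).reshape(
            len(model.states[model.class_name]), -1).sum(axis=1)
    if np.isnan(arr).any():
        raise UnobservedConfigError(
            "query touches an unobserved parent configuration fitted with pseudocount 0")
    total = arr.sum()
    if total == 0:
        raise HcesError("evidence has probability zero under the model")
    return float(arr[1] / total)


# -- vectorized scoring ------------------------------------------------------

def predict_proba(model: BayesClassifier, table: DataTable) -> np.ndarray:
    """P(class = positive | all predictors) for every record, vectorized."""
    cls = model.class_name
    kc = len(model.states[cls])
    n = table.n
    codes = {p: table.codes(p) for p in model.predictors}
    log_joint = np.zeros((kc, n))
    for c in range(kc):
        codes_c = dict(codes)
        codes_c[cls] = np.full(n, c, dtype=np.int64)
        for node in model.structure.nodes:
            cpt = model.cpts[node]
            arr = cpt.table
            idx = tuple(codes_c[p] for p in cpt.parents) + (codes_c[node],)
            probs = arr[idx]
            if np.isnan(probs).any():
                raise UnobservedConfigError(
                    "record touches an unobserved parent configuration "
                    "fitted with pseudocount 0")
            with np.errstate(divide="ignore"):
                log_joint[c] += np.log(probs)
    norm = logsumexp(log_joint, axis=0)
    return np.exp(log_joint[1] - norm)


def posterior_batch(model: BayesClassifier, table: DataTable,
                    observed: Iterable[str]) -> np.ndarray:
    """Posterior per record with evidence restricted to ``observed``.

    Full-evidence calls dispatch to the vectorized joint-product path;
    partial evidence goes through variable elimination with per-pattern
    caching (records sharing the same observed states share one query).
    """
    observed = [o for o in observed]
    if set(observed) == set(model.predictors):
        return predict_proba(model, table)
    if not observed:
        prior = model.cpts[model.class_name].table
        return np.full(table.n, float(prior[1] / prior.sum()))
    cols = [table.frame[o].astype(str).to_numpy() for o in observed]
    cache: dict[tuple, float] = {}
    out = np.empty(table.n)
    for i in range(table.n):
        key = tuple(col[i] for col in cols)
        if key not in cache:
            cache[key] = posterior(model, dict(zip(observed, key)))
        out[i] = cache[key]
    return out
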