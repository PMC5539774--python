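"""Synthetic tabular data sampled from a planted TAN-structured model.

Emulates the shape of the COPD-exacerbation learning base the toolkit is
aimed at — a couple of thousand records, ~60 mixed-type predictors, a
binary minority class — without any real patient data.  The class is drawn
Bernoulli(prevalence); relevant predictors follow planted conditional
probability tables along a TAN chain; a configurable subset of them is
"continuousized" by per-state Gaussian emissions (a planted, recoverable
cut for the discretizer); noise attributes are independent of everything.

The generator also reports the planted model's closed-form Bayes-optimal
AUC, the ceiling any classifier on this data can reach.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .core import (CLASS, CONTINUOUS, DISCRETE, PREDICTOR, AttributeSpec,
                   DataTable, HcesError, get_logger)
from .bayesnet import NetworkStructure

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_spec",
    "sample_dataset",
    "structure_recovery_rate",
]

log = get_logger("synthetic")


@dataclass
class SyntheticSpec:
    """Full description of the planted generating model."""

    n: int
    prevalence: float
    structure: NetworkStructure
    cpts: dict[str, np.ndarray]  # node -> table, shape (*parent_cards, card)
    states: dict[str, tuple[str, ...]]
    emissions: dict[str, dict[int, tuple[float, float]]]  # node -> state -> (mean, sd)
    n_noise_discrete: int
    n_noise_continuous: int
    seed: int

    @property
    def n_noise(self) -> int:
        return self.n_noise_discrete + self.n_noise_continuous


@dataclass
class GroundTruth:
    structure: NetworkStructure
    relevant: set[str]
    bayes_auc: float


def make_spec(n: int = 2000, prevalence: float = 0.15, n_relevant: int = 8,
              n_emitted: int = 4, n_noise_discrete: int = 6,
              n_noise_continuous: int = 6, seed: int = 0,
              strength: float = 0.85, base: float = 0.1,
              class_shift: float = 0.3, parent_shift: float = 0.4,
              emission_sd: float = 1.0,
              emission_separation: float = 3.0) -> SyntheticSpec:
    """Build the default planted model.

    ``n_relevant`` binary predictors form a chain X1 -> X2 -> ... under the
    class.  The root follows the class with fidelity ``strength``; every
    later node has P(x=1 | c, xp) = base + class_shift*c + parent_shift*xp
    (clipped to [0.02, 0.98]), so each attribute carries both a direct
    class signal and a strong tree dependence.  Raising ``parent_shift``
    toward 0.8 with a small ``class_shift`` gives the strong-dependency
    regime where every CPT row puts >= 0.8 mass on one state.  The first
    ``n_emitted`` relevant attributes are emitted as Gaussians whose
    per-state means sit ``emission_separation`` standard deviations apart,
    so the MDL discretizer has a recoverable planted cut.  Defaults give
    2000 records, 8 relevant predictors plus 12 mixed-type noise
    attributes, minority prevalence 0.15; the full-scale envelope of the
    intended application (~60 predictors, 20 of them continuous) is
    reached with ``n_noise_discrete=36, n_noise_continuous=16``.
    """
    if not 0 < prevalence < 1:
        raise HcesError("prevalence must be in (0, 1)")
    cls = "Exacer"
    relevant = [f"X{i+1:02d}" for i in range(n_relevant)]
    states = {cls: ("0", "1")} | {r: ("0", "1") for r in relevant}
    parents: dict[str, tuple[str, ...]] = {cls: ()}
    cpts: dict[str, np.ndarray] = {cls: np.array([1 - prevalence, prevalence])}
    s, w = strength, 1 - strength

    def row(p1: float) -> list[float]:
        p1 = float(np.clip(p1, 0.02, 0.98))
        return [1.0 - p1, p1]

    for i, r in enumerate(relevant):
        if i == 0:
            parents[r] = (cls,)
            # informative root: strongly tied to the class
            cpts[r] = np.array([[s, w], [w, s]])  # rows: class state
        else:
            parents[r] = (cls, relevant[i - 1])
            cpts[r] = np.array([
                [row(base), row(base + parent_shift)],                # c = 0
                [row(base + class_shift),
                 row(base + class_shift + parent_shift)],             # c = 1
            ])
    structure = NetworkStructure((cls, *relevant), cls, parents)
    emissions = {relevant[i]: {0: (0.0, emission_sd),
                               1: (emission_separation * emission_sd, emission_sd)}
                 for i in range(min(n_emitted, n_relevant))}
    return SyntheticSpec(n, prevalence, structure, cpts, states, emissions,
                         n_noise_discrete, n_noise_continuous, seed)


def _bayes_optimal_auc(spec: SyntheticSpec) -> float:
    """Closed-form AUC of the planted posterior over all discrete
    predictor configurations, weighted by their class-conditional mass."""
    order = spec.structure.topological_order()
    preds = [n for n in order if n != spec.structure.class_name]
    cards = [len(spec.states[p]) for p in preds]
    cls = spec.structure.class_name
    kc = len(spec.states[cls])
    configs = list(product(*[range(k) for k in cards]))
    w = np.zeros((kc, len(configs)))
    for c in range(kc):
        for j, cfg in enumerate(configs):
            val = dict(zip(preds, cfg))
            val[cls] = c
            prob = 1.0
            for p in preds:
                idx = tuple(val[q] for q in spec.structure.parents[p]) + (val[p],)
                prob *= spec.cpts[p][idx]
            w[c, j] = prob
    prior = spec.cpts[cls]
    joint = w * prior[:, None]
    post1 = joint[1] / joint.sum(axis=0)
    # AUC = P(s+ > s-) + 0.5 P(s+ = s-), weights = class-conditional masses
    w1 = w[1] / w[1].sum()
    w0 = w[0] / w[0].sum()
    order_idx = np.argsort(post1, kind="stable")
    s_sorted = post1[order_idx]
    w1s, w0s = w1[order_idx], w0[order_idx]
    auc = 0.0
    cum0 = 0.0
    j = 0
    while j < len(s_sorted):
        k = j
        while k < len(s_sorted) and s_sorted[k] == s_sorted[j]:
            k += 1
        g1, g0 = w1s[j:k].sum(), w0s[j:k].sum()
        auc += g1 * cum0 + 0.5 * g1 * g0
        cum0 += g0
        j = k
    return float(auc)


def sample_dataset(spec: SyntheticSpec) -> tuple[DataTable, GroundTruth]:
    """Ancestral sampling from the planted model; reproducible under seed."""
    for node, cpt in spec.cpts.items():
        sums = np.asarray(cpt).sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise HcesError(f"invalid planted CPT for {node!r}")
    rng = np.random.default_rng(spec.seed)
    cls = spec.structure.class_name
    order = spec.structure.topological_order()
    draws: dict[str, np.ndarray] = {}
    n = spec.n
    for node in order:
        pa = spec.structure.parents[node]
        cpt = np.asarray(spec.cpts[node], dtype=float)
        k = cpt.shape[-1]
        if not pa:
            p = cpt
            u = rng.random(n)
            draws[node] = (u[:, None] > np.cumsum(p)[:-1][None, :]).sum(axis=1)
        else:
            idx = tuple(draws[q] for q in pa)
            rows = cpt[idx]  # (n, k)
            u = rng.random(n)
            draws[node] = (u[:, None] > np.cumsum(rows, axis=1)[:, :-1]).sum(axis=1)
    columns: dict[str, np.ndarray | list] = {}
    specs: list[AttributeSpec] = []
    relevant = [p for p in order if p != cls]
    specs.append(AttributeSpec(cls, DISCRETE, CLASS, spec.states[cls]))
    columns[cls] = np.asarray(spec.states[cls])[draws[cls]]
    for p in relevant:
        if p in spec.emissions:
            em = spec.emissions[p]
            means = np.array([em[s][0] for s in range(len(spec.states[p]))])
            sds = np.array([em[s][1] for s in range(len(spec.states[p]))])
            columns[p] = means[draws[p]] + sds[draws[p]] * rng.standard_normal(n)
            specs.append(AttributeSpec(p, CONTINUOUS, PREDICTOR))
        else:
            columns[p] = np.asarray(spec.states[p])[draws[p]]
            specs.append(AttributeSpec(p, DISCRETE, PREDICTOR, spec.states[p]))
    for i in range(spec.n_noise_discrete):
        name = f"ND{i+1:02d}"
        k = 2 + (i % 2)  # alternate binary / ternary noise
        st = tuple(str(s) for s in range(k))
        columns[name] = np.asarray(st)[rng.integers(0, k, size=n)]
        specs.append(AttributeSpec(name, DISCRETE, PREDICTOR, st))
    for i in range(spec.n_noise_continuous):
        name = f"NC{i+1:02d}"
        columns[name] = rng.standard_normal(n)
        specs.append(AttributeSpec(name, CONTINUOUS, PREDICTOR))
    frame = pd.DataFrame({s.name: columns[s.name] for s in specs})
    table = DataTable(frame, specs)
    truth = GroundTruth(spec.structure, set(relevant), _bayes_optimal_auc(spec))
    return table, truth


def structure_recovery_rate(learned: NetworkStructure,
                            truth: NetworkStructure) -> float:
    """Fraction of the truth's undirected predictor tree edges present
    (undirected) in the learned structure."""
    truth_preds = set(truth.nodes) - {truth.class_name}
    learned_preds = set(learned.nodes) - {learned.class_name}
    if truth_preds != learned_preds:
        raise HcesError("node sets differ between learned and true structures")
    true_edges = truth.tree_edges()
    if not true_edges:
        return 1.0
    return len(true_edges & learned.tree_edges()) / len(true_edges)
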