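"""Supervised discretization of continuous predictors (Fayyad–Irani MDL).

Each continuous predictor is cut, recursively and greedily, at the boundary
point maximizing class-information gain; a cut is kept only when the minimum
description length criterion (MDLPC) says the two-part encoding is cheaper
than no split.  Intervals are half-open ``[a, b)``: a value equal to a cut
belongs to the upper bin.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    CONTINUOUS, DISCRETE, PREDICTOR, AttributeSpec, CountVector, DataTable,
    HcesError, entropy, get_logger,
)

__all__ = [
    "CutPoints",
    "DiscretizationScheme",
    "candidate_cuts",
    "mdlpc_accepts",
    "mdl_discretize_attribute",
    "build_scheme",
    "apply_scheme",
]

log = get_logger("discretize")


@dataclass(frozen=True)
class CutPoints:
    """Ordered cut thresholds for one attribute, defining |cuts|+1 intervals."""

    attribute: str
    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cuts must be strictly increasing")

    @property
    def interval_labels(self) -> tuple[str, ...]:
        edges = ["-inf"] + [repr(c) for c in self.cuts] + ["inf"]
        return tuple(f"[{a},{b})" for a, b in zip(edges, edges[1:]))

    @property
    def inert(self) -> bool:
        """An attribute with no accepted cut carries a single state."""
        return len(self.cuts) == 0

    def assign(self, values: Sequence[float]) -> np.ndarray:
        """Interval index per value; half-open [a, b) so v == cut goes up."""
        return np.searchsorted(np.asarray(self.cuts), np.asarray(values, float),
                               side="right")


@dataclass
class DiscretizationScheme:
    """Per-attribute cut points covering every continuous predictor."""

    cuts: dict[str, CutPoints]
    provenance: dict[str, int] = field(default_factory=dict)  # criterion evaluations

    def to_json(self) -> str:
        return json.dumps({a: list(c.cuts) for a, c in sorted(self.cuts.items())},
                          indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        payload = json.loads(text)
        return cls({a: CutPoints(a, tuple(v)) for a, v in payload.items()})

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "DiscretizationScheme":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Candidate generation and the MDLPC stopping rule
# ---------------------------------------------------------------------------

def candidate_cuts(values: Sequence[float], labels: Sequence) -> list[float]:
    """Boundary-point candidate thresholds.

    Midpoints between consecutive distinct sorted values whose pooled label
    set is not pure (a distinct-value block with mixed labels makes both
    flanking midpoints candidates).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size == 0:
        raise HcesError("empty input")
    if v.size != y.size:
        raise HcesError("values and labels length mismatch")
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    distinct: list[float] = []
    label_sets: list[set] = []
    for val, lab in zip(v, y):
        if distinct and val == distinct[-1]:
            label_sets[-1].add(lab)
        else:
            distinct.append(float(val))
            label_sets.append({lab})
    cuts = []
    for i in range(len(distinct) - 1):
        if len(label_sets[i] | label_sets[i + 1]) > 1:
            cuts.append((distinct[i] + distinct[i + 1]) / 2.0)
    return cuts


def _n_classes(counts) -> int:
    if isinstance(counts, CountVector):
        counts = counts.counts
    return int(np.count_nonzero(np.asarray(counts)))


def mdlpc_accepts(S, S1, S2, N: int) -> bool:
    """Minimum-description-length test for a binary cut.

    Accept iff ``Gain > log2(N-1)/N + Delta/N`` where
    ``Gain = Ent(S) - (N1/N) Ent(S1) - (N2/N) Ent(S2)`` and
    ``Delta = log2(3^c - 2) - [c Ent(S) - c1 Ent(S1) - c2 Ent(S2)]``
    with c, c1, c2 the numbers of classes present in S, S1, S2.
    """
    s = np.asarray(S.counts if isinstance(S, CountVector) else S, dtype=float)
    s1 = np.asarray(S1.counts if isinstance(S1, CountVector) else S1, dtype=float)
    s2 = np.asarray(S2.counts if isinstance(S2, CountVector) else S2, dtype=float)
    if not np.array_equal(s, s1 + s2) or N != s.sum() or N < 2:
        raise HcesError("inconsistent partition in MDLPC test")
    n1, n2 = s1.sum(), s2.sum()
    ent, ent1, ent2 = entropy(s), entropy(s1), entropy(s2)
    gain = ent - (n1 / N) * ent1 - (n2 / N) * ent2
    c, c1, c2 = _n_classes(s), _n_classes(s1), _n_classes(s2)
    delta = np.log2(3.0 ** c - 2.0) - (c * ent - c1 * ent1 - c2 * ent2)
    return bool(gain > np.log2(N - 1) / N + delta / N)


# ---------------------------------------------------------------------------
# Recursive discretization
# ---------------------------------------------------------------------------

def _class_counts(y_codes: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y_codes, minlength=k)


def mdl_discretize_attribute(values: Sequence[float], labels: Sequence,
                             _counter: list | None = None) -> CutPoints:
    """Greedy top-down MDL discretization of one continuous column.

    At each node the candidate cut maximizing information gain is tested
    with :func:`mdlpc_accepts`; on acceptance the recursion continues on
    both sides.  Gain ties break toward the smallest threshold, making the
    result deterministic given the data.
    """
    v = np.asarray(values, dtype=float)
    y_codes, uniques = _factorize(labels)
    if v.size < 2:
        raise HcesError("need at least 2 records to discretize")
    k = len(uniques)
    order = np.argsort(v, kind="stable")
    v, y_codes = v[order], y_codes[order]
    counter = _counter if _counter is not None else []
    cuts = sorted(_recurse(v, y_codes, k, counter))
    return CutPoints("", tuple(cuts))


def _factorize(labels):
    import pandas as pd

    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.int64), list(uniques)


def _recurse(v: np.ndarray, y: np.ndarray, k: int, counter: list) -> list[float]:
    cands = candidate_cuts(v, y) if v.size >= 2 else []
    if not cands:
        return []
    total = _class_counts(y, k)
    n = v.size
    ent = entropy(total)
    best = None  # (gain, cut, left_counts, right_counts, split_at)
    for cut in cands:
        split = int(np.searchsorted(v, cut, side="right"))
        left = _class_counts(y[:split], k)
        right = total - left
        gain = ent - (split / n) * entropy(left) - ((n - split) / n) * entropy(right)
        if best is None or gain > best[0]:
            best = (gain, cut, left, right, split)
    counter.append(1)
    gain, cut, left, right, split = best
    if not mdlpc_accepts(total, left, right, n):
        return []
    return (_recurse(v[:split], y[:split], k, counter) + [cut]
            + _recurse(v[split:], y[split:], k, counter))


def build_scheme(table: DataTable) -> DiscretizationScheme:
    """Learn MDL cut points for every continuous predictor of ``table``."""
    cuts: dict[str, CutPoints] = {}
    evaluations: dict[str, int] = {}
    y = table.frame[table.class_name].to_numpy()
    for name in table.predictor_names:
        if table.spec(name).kind != CONTINUOUS:
            continue
        counter: list = []
        cp = mdl_discretize_attribute(table.values(name), y, counter)
        cuts[name] = CutPoints(name, cp.cuts)
        evaluations[name] = len(counter)
        if not cp.cuts:
            log.info("attribute %s: no MDL-accepted cut, flagged inert", name)
    return DiscretizationScheme(cuts, evaluations)


def apply_scheme(table: DataTable, scheme: DiscretizationScheme) -> DataTable:
    """Replace each continuous predictor by its discretized counterpart.

    Values outside the training range fall into the terminal intervals by
    construction of the half-open binning (a form of clamping).  Attributes
    with zero cuts become single-state columns flagged inert and should be
    excluded downstream.
    """
    cont = [n for n in table.predictor_names if table.spec(n).kind == CONTINUOUS]
    missing = set(cont) - set(scheme.cuts)
    if missing:
        raise HcesError(f"scheme does not cover continuous predictors {sorted(missing)}")
    out = table
    for name in cont:
        cp = scheme.cuts[name]
        labels = cp.interval_labels
        idx = cp.assign(table.values(name))
        spec = AttributeSpec(name, DISCRETE, PREDICTOR, labels)
        out = out.with_column(spec, [labels[i] for i in idx])
    return out


def inert_attributes(table: DataTable) -> list[str]:
    """Predictors with at most one observed state (zero information)."""
    out = []
    for name in table.predictor_names:
        if table.spec(name).kind == DISCRETE:
            if len(np.unique(table.codes(name))) <= 1:
                out.append(name)
    return out
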