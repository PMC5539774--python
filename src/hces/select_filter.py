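"""Filter-style relevant-attribute selection.

Two classifier-independent heuristics over a fully discrete table:

* gain-ratio ranking with the half-of-maximum elimination threshold
  (alpha = max gain ratio / 2; attributes strictly below alpha are dropped);
* CFS subset selection — the Hall merit k*rzi / sqrt(k + k(k-1)*rii) with
  symmetrical uncertainty as the correlation, searched by forward
  Best-First with stale limit 5.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import (CONTINUOUS, DISCRETE, DataTable, HcesError, entropy,
                   get_logger, symmetrical_uncertainty)
from .search import best_first_subsets

__all__ = [
    "RankingEntry",
    "Ranking",
    "CfsMerit",
    "gain_ratio",
    "rank_attributes",
    "gain_ratio_filter",
    "cfs_merit",
    "cfs_select",
]

log = get_logger("select_filter")


@dataclass(frozen=True)
class RankingEntry:
    attribute: str
    gain: float        # Gain(T, A), bits
    split_info: float  # SplitInfo(T, A), bits
    gain_ratio: float  # gain / split_info, or 0 when split_info == 0


@dataclass
class Ranking:
    """Entries sorted by gain ratio descending (ties: name ascending)."""

    entries: list[RankingEntry]

    @property
    def alpha(self) -> float:
        """Elimination threshold: half the maximum gain ratio."""
        return max(e.gain_ratio for e in self.entries) / 2.0

    @property
    def ordered_attributes(self) -> list[str]:
        return [e.attribute for e in self.entries]

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "entries": [{"attribute": e.attribute, "gain": e.gain,
                         "split_info": e.split_info, "gain_ratio": e.gain_ratio}
                        for e in self.entries],
        }, indent=2)


@dataclass(frozen=True)
class CfsMerit:
    subset: frozenset
    k: int
    avg_class_corr: float
    avg_inter_corr: float
    merit: float


# ---------------------------------------------------------------------------
# Gain ratio
# ---------------------------------------------------------------------------

def gain_ratio(table: DataTable, attr: str) -> RankingEntry:
    """Gain(T,A) = H(T) - sum_v (n_v/n) H(T|A=v); SplitInfo is H of the
    attribute's own value distribution; the ratio corrects gain's bias
    toward many-valued attributes."""
    spec = table.spec(attr)
    if spec.role == "class":
        raise HcesError("gain ratio of the class against itself is undefined")
    if spec.kind == CONTINUOUS:
        raise HcesError(f"attribute {attr!r} is continuous; discretize first")
    a = table.codes(attr)
    y = table.class_codes()
    n = table.n
    ka = len(table.states(attr))
    ky = len(table.states(table.class_name))
    joint = np.bincount(a * ky + y, minlength=ka * ky).reshape(ka, ky).astype(float)
    nv = joint.sum(axis=1)
    h_t = entropy(joint.sum(axis=0))
    cond = sum((nv[v] / n) * entropy(joint[v]) for v in range(ka) if nv[v] > 0)
    gain = h_t - cond
    split_info = entropy(nv)
    gr = gain / split_info if split_info > 0 else 0.0
    return RankingEntry(attr, float(max(gain, 0.0)), float(split_info),
                        float(min(max(gr, 0.0), 1.0)))


def rank_attributes(table: DataTable) -> Ranking:
    """One entry per non-inert discrete predictor, sorted for presentation
    in descending gain-ratio order."""
    entries = []
    for name in table.predictor_names:
        if table.spec(name).kind != DISCRETE:
            raise HcesError(f"predictor {name!r} is continuous; discretize first")
        e = gain_ratio(table, name)
        if e.split_info == 0:
            log.info("attribute %s is inert (single state); excluded from ranking",
                     name)
            continue
        entries.append(e)
    if not entries:
        raise HcesError("no rankable predictors")
    entries.sort(key=lambda e: (-e.gain_ratio, e.attribute))
    return Ranking(entries)


def gain_ratio_filter(ranking: Ranking) -> set[str]:
    """Keep attributes whose gain ratio is >= alpha (strictly-below are
    eliminated; equality is kept)."""
    if not ranking.entries:
        raise HcesError("empty ranking")
    alpha = ranking.alpha
    return {e.attribute for e in ranking.entries if e.gain_ratio >= alpha}


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def cfs_merit(table: DataTable, subset) -> CfsMerit:
    """Hall merit of a subset: high class correlation, low redundancy."""
    subset = frozenset(subset)
    if not subset:
        raise HcesError("empty subset")
    cls = table.class_name
    k = len(subset)
    rzi = float(np.mean([symmetrical_uncertainty(table.codes(a),
                                                 table.class_codes())
                         for a in sorted(subset)]))
    if k > 1:
        rii = float(np.mean([symmetrical_uncertainty(table.codes(a),
                                                     table.codes(b))
                             for a, b in combinations(sorted(subset), 2)]))
    else:
        rii = 0.0
    denom = np.sqrt(k + k * (k - 1) * rii)
    merit = k * rzi / denom if denom > 0 else 0.0
    return CfsMerit(subset, k, rzi, rii, float(merit))


def cfs_select(table: DataTable, stale_limit: int | None = 5) -> set[str]:
    """Forward Best-First search over subsets scored by the CFS merit."""
    candidates = [n for n in table.predictor_names
                  if table.spec(n).kind == DISCRETE
                  and len(np.unique(table.codes(n))) > 1]
    if not candidates:
        raise HcesError("no discrete, non-inert predictors to select from")

    y = table.class_codes()
    su_class = {a: symmetrical_uncertainty(table.codes(a), y) for a in candidates}
    su_pair: dict[frozenset, float] = {}

    def su(a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in su_pair:
            su_pair[key] = symmetrical_uncertainty(table.codes(a), table.codes(b))
        return su_pair[key]

    def merit(subset: frozenset) -> float:
        k = len(subset)
        rzi = sum(su_class[a] for a in subset) / k
        if k > 1:
            pairs = list(combinations(sorted(subset), 2))
            rii = sum(su(a, b) for a, b in pairs) / len(pairs)
        else:
            rii = 0.0
        denom = np.sqrt(k + k * (k - 1) * rii)
        return k * rzi / denom if denom > 0 else 0.0

    best, best_merit, _ = best_first_subsets(candidates, merit, stale_limit)
    if best_merit <= 1e-9:
        log.warning("CFS found no subset with positive merit (all noise?)")
    return set(best)
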