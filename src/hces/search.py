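"""Forward Best-First subset search shared by the CFS filter and the
wrapper selectors.

The open list holds every generated-but-unexpanded subset ordered by score
(ties: smaller subset first, then lexicographic attribute order).  Search
starts from the empty set, repeatedly expands the best open subset by
single-attribute additions, and stops after ``stale_limit`` consecutive
expansions that fail to improve the global best (``stale_limit=None``
explores the whole lattice).  Evaluator results are memoized per subset.
"""
from __future__ import annotations

import heapq
from typing import Callable, Iterable, Sequence

__all__ = ["best_first_subsets"]


def best_first_subsets(attributes: Sequence[str],
                       evaluator: Callable[[frozenset], float],
                       stale_limit: int | None = 5,
                       ) -> tuple[frozenset, float, dict[frozenset, float]]:
    """Return (best subset, its score, all memoized evaluations)."""
    attrs = sorted(attributes)
    if not attrs:
        raise ValueError("no attributes to search over")
    memo: dict[frozenset, float] = {}

    def score(subset: frozenset) -> float:
        if subset not in memo:
            memo[subset] = evaluator(subset) if subset else float("-inf")
        return memo[subset]

    def entry(subset: frozenset):
        # heapq is a min-heap: negate score; ties -> smaller size, lex order
        return (-score(subset), len(subset), tuple(sorted(subset)), subset)

    start = frozenset()
    open_list = [entry(start)]
    seen = {start}
    best_subset, best_score = start, score(start)
    stale = 0
    while open_list:
        _, _, _, current = heapq.heappop(open_list)
        improved = False
        for a in attrs:
            if a in current:
                continue
            child = current | {a}
            if child in seen:
                continue
            seen.add(child)
            s = score(child)
            heapq.heappush(open_list, entry(child))
            if s > best_score or (s == best_score and
                                  (len(child), tuple(sorted(child))) <
                                  (len(best_subset), tuple(sorted(best_subset)))):
                if s > best_score:
                    improved = True
                best_subset, best_score = child, s
        if improved:
            stale = 0
        else:
            stale += 1
            if stale_limit is not None and stale >= stale_limit:
                break
    return best_subset, best_score, memo
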