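"""Stratified cross-validation, ROC/AUC, cutoff selection, and the
gain-ratio-ordered incremental-observation evaluation.

AUC is computed twice on every call — trapezoid over the ROC operating
points and the tie-corrected midrank (Mann–Whitney) statistic — and the two
must agree to 1e-12; pooling of out-of-fold scores into one ROC follows the
convention of the Weka evaluation stack.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import DataTable, HcesError, get_logger
from . import bayesnet

__all__ = [
    "CVPlan",
    "ROCCurve",
    "ModelSpec",
    "IncrementalReport",
    "stratified_folds",
    "cross_validated_scores",
    "roc_auc",
    "rank_auc",
    "select_cutoff",
    "classify",
    "incremental_auc",
]

log = get_logger("evaluate")


class FoldError(HcesError):
    """A class has fewer members than the requested fold count."""


@dataclass(frozen=True)
class CVPlan:
    """A stratified k-fold partition of record indices."""

    k: int
    seed: int
    folds: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        if len(np.unique(all_idx)) != len(all_idx):
            raise HcesError("folds overlap")


@dataclass
class ROCCurve:
    """Thresholded operating points, AUC, and (optionally) a selected cutoff.

    ``points`` are (threshold, sensitivity, 1 - specificity) sorted by
    threshold descending.
    """

    points: list[tuple[float, float, float]]
    auc: float
    cutoff: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """What to fit inside each CV fold: structure family and smoothing."""

    structure: str = "tan"  # nb | tan | k2
    max_parents: int = 1    # K2 only; counts the class parent
    smoothing: float = 0.5

    def learn(self, train: DataTable) -> bayesnet.BayesClassifier:
        if self.structure == "nb":
            struct = bayesnet.naive_bayes_structure(train)
        elif self.structure == "tan":
            struct = bayesnet.build_tan(train)
        elif self.structure == "k2":
            struct = bayesnet.k2_search(train, max_parents=self.max_parents)
        else:
            raise HcesError(f"unknown structure {self.structure!r}")
        return bayesnet.fit_cpts(train, struct, self.smoothing)


@dataclass
class IncrementalReport:
    """AUC as a function of the number m of observed attributes."""

    ordering: list[str]
    auc_by_m: dict[int, float]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def stratified_folds(labels: Sequence, k: int = 10, seed: int = 0) -> CVPlan:
    """Class-wise shuffle under ``seed`` then round-robin fold assignment.

    Guarantees per-fold class counts within 1 of perfect stratification and
    identical folds for identical seeds.
    """
    y = np.asarray(labels)
    if k < 2:
        raise HcesError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in sorted(map(str, np.unique(y))):
        idx = np.flatnonzero(y.astype(str) == value)
        if len(idx) < k:
            raise FoldError(
                f"class value {value!r} has {len(idx)} records, fewer than k={k}")
        idx = rng.permutation(idx)
        for pos, record in enumerate(idx):
            folds[pos % k].append(int(record))
    return CVPlan(k, seed, tuple(np.sort(np.array(f, dtype=np.int64))
                                 for f in folds))


# ---------------------------------------------------------------------------
# Cross-validated scoring
# ---------------------------------------------------------------------------

def cross_validated_scores(table: DataTable, model_spec: ModelSpec,
                           cv: CVPlan) -> np.ndarray:
    """Out-of-fold posterior score for every record.

    Structure and CPTs are learned per fold on the complement; each record
    is scored exactly once by the model that never saw it.
    """
    scores = np.full(table.n, np.nan)
    all_idx = np.arange(table.n)
    for f, test_idx in enumerate(cv.folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        try:
            model = model_spec.learn(table.subset_rows(train_idx))
            scores[test_idx] = bayesnet.predict_proba(
                model, table.subset_rows(test_idx))
        except HcesError as err:
            raise HcesError(f"fold {f}: {err}") from err
    assert not np.isnan(scores).any(), "every record must be scored exactly once"
    return scores


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected rank (Mann–Whitney) AUC: P(score+ > score-) + 0.5 P(=)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise HcesError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve over all distinct thresholds with dual-computed AUC.

    The trapezoidal area of the curve is asserted against the tie-corrected
    rank statistic (tolerance 1e-12); disagreement would mean an internal
    inconsistency and raises.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc_rank = rank_auc(s, y)  # raises on single-class input
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc_trap = float(np.trapezoid(tpr, fpr))
    if abs(auc_trap - auc_rank) > 1e-12:
        raise HcesError(
            f"AUC cross-check failed: trapezoid {auc_trap} vs rank {auc_rank}")
    points = [(float(t), float(se), float(fp))
              for t, se, fp in zip(thresholds, tpr, fpr)]
    return ROCCurve(points, auc_trap)


def select_cutoff(roc: ROCCurve) -> float:
    """Threshold of the ROC point nearest the ideal corner (fpr 0, sens 1).

    Minimizes (1 - sensitivity)^2 + (1 - specificity)^2; ties resolve to
    the smaller (more sensitive) threshold.  The returned cutoff is clipped
    into [0, 1] so it is usable as a posterior-probability threshold.
    """
    if not roc.points:
        raise HcesError("empty ROC curve")
    best = None
    for t, sens, fpr in roc.points:
        d = (1.0 - sens) ** 2 + fpr ** 2
        key = (d, t)
        if best is None or key < best:
            best = key
    return float(min(max(best[1], 0.0), 1.0))


def classify(model: bayesnet.BayesClassifier, ev, cutoff: float) -> str:
    """"alert" iff the posterior strictly exceeds the cutoff, else "no-alert"."""
    if not 0.0 <= cutoff <= 1.0:
        raise HcesError("cutoff must be in [0, 1]")
    return "alert" if bayesnet.posterior(model, ev) > cutoff else "no-alert"


# ---------------------------------------------------------------------------
# Incremental observation
# ---------------------------------------------------------------------------

def incremental_auc(table: DataTable, model_spec: ModelSpec, cv: CVPlan,
                    ordering: Sequence[str], start_m: int = 8,
                    retrain_per_m: bool = False) -> IncrementalReport:
    """AUC when only the top-m attributes of ``ordering`` are observed.

    Default mode fits one full model per fold and restricts the *evidence*
    to the top-m attributes, marginalizing the rest — the deployed-
    application reading where symptoms are observed one by one.  With
    ``retrain_per_m`` a reduced model is refitted per m instead.  At full m
    both modes coincide with the standard full-evidence evaluation.
    """
    ordering = list(ordering)
    preds = table.predictor_names
    if set(ordering) != set(preds):
        raise HcesError("ordering must cover exactly the model's predictors")
    if start_m < 0:
        raise HcesError("start_m must be >= 0")
    y = table.class_codes()
    all_idx = np.arange(table.n)
    auc_by_m: dict[int, float] = {}
    ms = list(range(start_m, len(ordering) + 1))
    models = []
    for test_idx in cv.folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        models.append(model_spec.learn(table.subset_rows(train_idx)))
    for m in ms:
        observed = ordering[:m]
        if m == 0:
            # An empty evidence set carries no record-specific information:
            # the scorer is constant by construction (per-fold prior jitter
            # is fold arithmetic, not patient signal).
            auc_by_m[m] = roc_auc(np.zeros(table.n), y).auc
            continue
        if retrain_per_m and m < len(ordering):
            sub = table.project(observed)
            scores = cross_validated_scores(sub, model_spec, cv)
        else:
            scores = np.full(table.n, np.nan)
            for model, test_idx in zip(models, cv.folds):
                scores[test_idx] = bayesnet.posterior_batch(
                    model, table.subset_rows(test_idx), observed)
        auc_by_m[m] = roc_auc(scores, y).auc
    return IncrementalReport(ordering, auc_by_m)
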