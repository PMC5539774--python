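"""Stratified CV, ROC/AUC, cutoff selection and incremental observation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hces.bayesnet import fit_cpts, naive_bayes_structure
from hces.core import HcesError
from hces.evaluate import (FoldError, ModelSpec, ROCCurve, classify,
                           cross_validated_scores, incremental_auc, rank_auc,
                           roc_auc, select_cutoff, stratified_folds)
from hces.select_filter import rank_attributes
from hces import synthetic
from conftest import build_table
from oracles import auc_pairs_oracle


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = [1] * 10 + [0] * 90
        cv = stratified_folds(y, k=10, seed=1)
        for fold in cv.folds:
            labels = [y[i] for i in fold]
            assert labels.count(1) == 1 and labels.count(0) == 9

    def test_determinism(self):
        y = [0] * 40 + [1] * 15
        a = stratified_folds(y, 5, seed=9)
        b = stratified_folds(y, 5, seed=9)
        assert all(np.array_equal(x, z) for x, z in zip(a.folds, b.folds))
        c = stratified_folds(y, 5, seed=10)
        assert any(not np.array_equal(x, z) for x, z in zip(a.folds, c.folds))

    def test_partition_and_near_stratification(self):
        rng = np.random.default_rng(0)
        y = (rng.random(137) < 0.23).astype(int)
        cv = stratified_folds(y, 7, seed=3)
        all_idx = np.sort(np.concatenate(cv.folds))
        assert np.array_equal(all_idx, np.arange(137))
        pos = [sum(y[i] for i in f) for f in cv.folds]
        assert max(pos) - min(pos) <= 1

    def test_class_smaller_than_k(self):
        with pytest.raises(FoldError):
            stratified_folds([0] * 50 + [1] * 3, 10, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.3] * 10, [1, 0] * 5).auc == pytest.approx(0.5)

    def test_enumerated_pairs(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]).auc == \
            pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        scores = np.round(rng.random(n), 2)  # ties likely
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pairs_oracle(scores, labels), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        labels = np.r_[np.ones(10, int), rng.integers(0, 2, 30)]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores) - 1, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(HcesError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_rank_auc_agrees(self):
        rng = np.random.default_rng(4)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        y[0] = 1
        y[1] = 0
        assert rank_auc(s, y) == pytest.approx(roc_auc(s, y).auc, abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        roc = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        sens = [p[1] for p in roc.points]
        fpr = [p[2] for p in roc.points]
        assert sens == sorted(sens) and fpr == sorted(fpr)


class TestSelectCutoff:
    def test_perfect_point_wins(self):
        roc = ROCCurve([(0.9, 0.2, 0.0), (0.6, 1.0, 0.0), (0.1, 1.0, 0.9)], 0.9)
        assert select_cutoff(roc) == 0.6

    def test_two_point_hand_distances(self):
        # d(0.7) = (1-0.6)^2 + 0.1^2 = 0.17; d(0.3) = 0.04 + 0.25 = 0.29
        roc = ROCCurve([(0.7, 0.6, 0.1), (0.3, 0.8, 0.5)], 0.7)
        assert select_cutoff(roc) == 0.7

    def test_degenerate_single_point(self):
        assert select_cutoff(ROCCurve([(0.4, 0.5, 0.5)], 0.5)) == 0.4

    def test_tie_prefers_smaller_threshold(self):
        roc = ROCCurve([(0.8, 0.6, 0.2), (0.2, 0.6, 0.2)], 0.5)
        assert select_cutoff(roc) == 0.2

    def test_empty_curve(self):
        with pytest.raises(HcesError):
            select_cutoff(ROCCurve([], 0.5))


class TestClassify:
    @pytest.fixture
    def prior_model(self):
        t = build_table([0, 0, 0, 1], {"a": [0, 1, 0, 1]})
        return fit_cpts(t, naive_bayes_structure(t), pseudocount=0.0)

    def test_strictly_greater_rule(self, prior_model):
        prior = 0.25  # empty evidence posterior
        assert classify(prior_model, {}, cutoff=prior) == "no-alert"
        assert classify(prior_model, {}, cutoff=prior - 1e-9) == "alert"

    def test_cutoff_one_never_alerts(self, prior_model):
        assert classify(prior_model, {"a": "1"}, cutoff=1.0) == "no-alert"

    def test_invalid_cutoff(self, prior_model):
        with pytest.raises(HcesError):
            classify(prior_model, {}, cutoff=1.5)


class TestCrossValidatedScores:
    def test_separable_fixture_fully_separated(self):
        y = [0] * 20 + [1] * 20
        t = build_table(y, {"a": y})
        cv = stratified_folds(t.class_codes(), 4, seed=0)
        s = cross_validated_scores(t, ModelSpec("nb"), cv)
        assert s[np.array(y) == 1].min() > s[np.array(y) == 0].max()

    def test_deterministic_given_seed(self):
        spec = synthetic.make_spec(n=300, n_emitted=0, n_noise_continuous=0,
                                   seed=2)
        t, _ = synthetic.sample_dataset(spec)
        cv = stratified_folds(t.class_codes(), 5, seed=8)
        a = cross_validated_scores(t, ModelSpec("tan"), cv)
        b = cross_validated_scores(t, ModelSpec("tan"), cv)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def setup():
    spec = synthetic.make_spec(n=400, n_emitted=0, n_noise_discrete=2,
                               n_noise_continuous=0, n_relevant=4, seed=6)
    t, _ = synthetic.sample_dataset(spec)
    cv = stratified_folds(t.class_codes(), 5, seed=1)
    ranking = rank_attributes(t)
    return t, cv, ranking


class TestIncremental:

    def test_full_m_equals_standard_evaluation_exactly(self, setup):
        t, cv, ranking = setup
        spec = ModelSpec("tan")
        rep = incremental_auc(t, spec, cv, ranking.ordered_attributes, start_m=0)
        full = roc_auc(cross_validated_scores(t, spec, cv),
                       t.class_codes()).auc
        assert rep.auc_by_m[len(ranking.entries)] == full  # exact, not approx

    def test_m_zero_is_chance(self, setup):
        t, cv, ranking = setup
        rep = incremental_auc(t, ModelSpec("tan"), cv,
                              ranking.ordered_attributes, start_m=0)
        assert rep.auc_by_m[0] == 0.5

    def test_retrain_mode_agrees_at_full_m(self, setup):
        t, cv, ranking = setup
        spec = ModelSpec("tan")
        a = incremental_auc(t, spec, cv, ranking.ordered_attributes,
                            start_m=len(ranking.entries))
        b = incremental_auc(t, spec, cv, ranking.ordered_attributes,
                            start_m=len(ranking.entries), retrain_per_m=True)
        assert a.auc_by_m == b.auc_by_m

    def test_ordering_must_cover_predictors(self, setup):
        t, cv, ranking = setup
        with pytest.raises(HcesError):
            incremental_auc(t, ModelSpec("tan"), cv,
                            ranking.ordered_attributes[:-1])
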