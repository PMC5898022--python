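import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paretodr.config import MethodConfig
from paretodr.data_model import Dataset, GoldenAssociations, ValidationError
from paretodr.evaluation import (
    ConfusionCounts,
    auc_pr,
    auc_roc,
    confusion_at_k,
    leave_one_out,
    pr_curve_points,
    precision_recall_f1,
    specificity,
    upper_bounds,
)
from paretodr.items import predict
from paretodr.synthetic import expected_sparsity, generate

from conftest import make_golden, make_matrix, noiseless_spec
from oracles import brute_force_auc_roc, threshold_sweep_auc_pr


class TestClosedFormMetrics:
    def test_precision_recall_f1_worked_example(self):
        c = ConfusionCounts(tp=1, fp=1, fn=3, tn=5, k=2)
        assert precision_recall_f1(c) == pytest.approx((0.5, 0.25, 1 / 3))

    def test_empty_prediction_scores_zero(self):
        c = ConfusionCounts(tp=0, fp=0, fn=2, tn=8, k=4)
        assert precision_recall_f1(c) == (0.0, 0.0, 0.0)

    def test_perfect_prediction(self):
        c = ConfusionCounts(tp=3, fp=0, fn=0, tn=7, k=3)
        assert precision_recall_f1(c) == (1.0, 1.0, 1.0)

    def test_specificity_values(self):
        assert specificity(ConfusionCounts(1, 1, 0, 9, k=2)) == pytest.approx(0.9)
        assert specificity(ConfusionCounts(1, 0, 0, 9, k=1)) == 1.0
        with pytest.raises(ValidationError):
            specificity(ConfusionCounts(1, 0, 3, 0, k=1))

    def test_confusion_partitions_toy_golden(self):
        # 3 drugs x 4 diseases; target "a" with positives {d1, d2}
        golden = make_golden(
            ["a", "b", "c"], ["d1", "d2", "d3", "d4"],
            [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1]],
        )
        positives = set(golden.indications("a"))
        c = confusion_at_k(["d1", "d3"], positives, n_diseases=4, k=2)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.tp + c.fp + c.fn + c.tn == 4

    def test_counts_must_fit_cap(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=2, fp=2, fn=0, tn=0, k=3)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 20), st.integers(0, 20), st.integers(0, 20))
    def test_f1_between_min_and_max(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn, tn=5, k=tp + fp)
        p, r, f1 = precision_recall_f1(c)
        if p > 0 and r > 0:
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestAUC:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0, 0])
        assert auc_pr(scores, labels) == pytest.approx(1.0)
        assert auc_roc(scores, labels) == pytest.approx(1.0)

    def test_constant_scores(self):
        scores = np.ones(10)
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert auc_pr(scores, labels) == pytest.approx(0.2)  # prevalence
        assert auc_roc(scores, labels) == pytest.approx(0.5)  # all ties

    def test_reversed_ranking_matches_threshold_sweep(self):
        scores = np.arange(10, dtype=float)  # positives score lowest
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        expected = threshold_sweep_auc_pr(list(scores), list(labels))
        assert auc_pr(scores, labels) == pytest.approx(expected)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValidationError):
            auc_pr(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValidationError):
            auc_roc(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_roc_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc_roc(list(scores), list(labels))
            )

    def test_pr_matches_threshold_sweep_random(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc_pr(scores, labels) == pytest.approx(
                threshold_sweep_auc_pr(list(scores), list(labels))
            )

    def test_curve_points_monotone_recall(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        pts = pr_curve_points(scores, labels)
        assert (pts["recall"].diff().dropna() >= 0).all()


class TestUpperBounds:
    def test_no_guess_precision_is_always_one(self):
        golden = make_golden(
            ["a", "b", "c"], [f"d{i}" for i in range(8)],
            [[1, 0, 0, 0, 0, 0, 0, 0],
             [1, 1, 0, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 0, 0, 0]],
        )
        ub = upper_bounds(golden, [1, 4, 8, 12, 16, 20], allow_guess=False)
        assert (ub["precision"] == 1.0).all()

    def test_guess_mode_hand_computed(self):
        # positives per drug: 1, 2, 5; k = 2
        golden = make_golden(
            ["a", "b", "c"], [f"d{i}" for i in range(8)],
            [[1, 0, 0, 0, 0, 0, 0, 0],
             [1, 1, 0, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 0, 0, 0]],
        )
        ub = upper_bounds(golden, [2], allow_guess=True).loc[2]
        # tp = (1,2,2), fp = (1,0,0): precision (0.5,1,1); recall (1,1,0.4)
        assert ub["precision"] == pytest.approx((0.5 + 1 + 1) / 3)
        assert ub["recall"] == pytest.approx((1 + 1 + 0.4) / 3)
        f1s = (2 * 0.5 * 1 / 1.5, 1.0, 2 * 1 * 0.4 / 1.4)
        assert ub["f1"] == pytest.approx(sum(f1s) / 3)

    def test_recall_one_when_k_covers_all_positives(self):
        golden = make_golden(["a", "b"], ["d1", "d2", "d3"], [[1, 1, 0], [1, 0, 0]])
        for guess in (False, True):
            ub = upper_bounds(golden, [3], allow_guess=guess)
            assert ub.loc[3, "recall"] == 1.0

    def test_zero_positive_rows_excluded(self):
        golden = make_golden(["a", "b"], ["d1", "d2"], [[1, 1], [0, 0]])
        ub = upper_bounds(golden, [2], allow_guess=False)
        assert ub.loc[2, "recall"] == 1.0  # only drug "a" counts


def _duplicate_pair_dataset():
    """Two identical drug pairs: each drug's twin shares features and diseases."""
    chem = make_matrix(
        "chemical", ["a1", "a2", "b1", "b2"],
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
    )
    golden = make_golden(
        ["a1", "a2", "b1", "b2"],
        ["d1", "d2", "d3", "d4"],
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
    )
    return Dataset({"chemical": chem}, golden)


def _cfg(**kw):
    from paretodr.similarity import SimilarityConfig

    base = dict(mot="ND", ist="WSUM", n=1, k=2)
    base.update(kw)
    return MethodConfig(similarity=SimilarityConfig(measures={"chemical": "jaccard"}), **base)


class TestLeaveOneOut:
    def test_identity_clusters_score_perfectly(self):
        ds = _duplicate_pair_dataset()
        rep = leave_one_out(ds, _cfg())
        assert rep.means["precision"] == 1.0
        assert rep.means["recall"] == 1.0

    def test_single_target_equals_aggregate(self):
        ds = _duplicate_pair_dataset()
        full = leave_one_out(ds, _cfg())
        solo = leave_one_out(ds, _cfg(), targets=["a1"])
        assert len(solo.per_target) == 1
        pd.testing.assert_series_equal(
            solo.per_target.loc["a1"], full.per_target.loc["a1"]
        )

    def test_zero_positive_targets_skipped(self):
        chem = make_matrix("chemical", ["a", "b", "c"], [[1, 1], [1, 1], [1, 0]])
        golden = make_golden(["a", "b", "c"], ["d1"], [[1], [1], [0]])
        ds = Dataset({"chemical": chem}, golden)
        rep = leave_one_out(ds, _cfg())
        assert rep.skipped == ["c"]
        assert set(rep.per_target.index) == {"a", "b"}

    def test_withheld_row_never_influences_prediction(self):
        """Poison the target's own golden row; predictions must not change."""
        ds = _duplicate_pair_dataset()
        cfg = _cfg()
        withheld = ds.golden.drop_drug("a1")
        baseline = predict("a1", ds, cfg, golden=withheld)

        poisoned = ds.golden.values.copy()
        poisoned.loc["a1"] = 1 - poisoned.loc["a1"]
        ds2 = Dataset(ds.feature_matrices, GoldenAssociations(poisoned))
        flipped = predict("a1", ds2, cfg, golden=ds2.golden.drop_drug("a1"))
        assert baseline.entries == flipped.entries

    def test_method_never_beats_upper_bound(self, noisy_data):
        dataset, _ = noisy_data
        for k in (1, 4):
            cfg = MethodConfig.from_shorthand(sim="JJJ", mot="ND", ist="WSUM", n=8, k=k)
            rep = leave_one_out(dataset, cfg)
            ub = upper_bounds(dataset.golden, [k], allow_guess=False).loc[k]
            assert rep.means["precision"] <= 1.0
            assert rep.means["recall"] <= ub["recall"] + 1e-12
            assert rep.means["f1"] <= ub["f1"] + 1e-12

    def test_pooled_auc_mode(self):
        ds = _duplicate_pair_dataset()
        rep = leave_one_out(ds, _cfg(), pooled_auc=True)
        assert rep.per_target["auc_roc"].nunique() == 1
        assert 0.0 <= rep.means["auc_pr"] <= 1.0

    def test_precision_at_1_beats_no_skill_on_planted_clusters(self, noisy_data):
        dataset, truth = noisy_data
        cfg = MethodConfig.from_shorthand(sim="JJJ", mot="ND", ist="WSUM", n=8, k=1)
        rep = leave_one_out(dataset, cfg)
        no_skill = 1.0 - expected_sparsity(truth.spec, "golden")
        assert rep.means["precision"] > no_skill
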