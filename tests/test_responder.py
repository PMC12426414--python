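import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmsreact import (label_responder, nested_cv_classify, roc_report,
                      updrs_subscores, extract_features,
                      group_difference_tests)
from tmsreact.responder import SubjectRecord, _fold_zscore


class TestResponderRule:
    @pytest.mark.parametrize("t0,t10,expected", [
        (20, 13, "responder"),       # 35% and 7 points: both clauses
        (20, 15, "non-responder"),   # 25% and exactly 5 points: neither
        (10, 7, "responder"),        # exactly 30%: rate clause inclusive
        (40, 34, "responder"),       # 15% but 6 points: absolute clause
        (40, 35, "non-responder"),   # 12.5% and exactly 5 points
        (10, 11, "non-responder"),   # worsening
    ])
    def test_rule_boundaries(self, t0, t10, expected):
        assert label_responder(t0, t10) == expected

    def test_zero_baseline_undefined(self):
        with pytest.raises(ZeroDivisionError):
            label_responder(0, 0)

    def test_exhaustive_grid_matches_bruteforce(self):
        """Decision table over t0 in 5..60, t10 in 0..t0 vs a restatement."""
        for t0 in range(5, 61):
            for t10 in range(0, t0 + 1):
                drop = t0 - t10
                brute = ("responder" if (drop * 10 >= 3 * t0) or (drop >= 6)
                         else "non-responder")  # integer restatement
                assert label_responder(t0, t10) == brute, (t0, t10)

    @settings(max_examples=200, derandomize=True)
    @given(t0=st.integers(1, 100), t10=st.integers(0, 100))
    def test_rule_matches_float_restatement(self, t0, t10):
        got = label_responder(t0, t10)
        want = ("responder"
                if ((t0 - t10) / t0 >= 0.30 or (t0 - t10) > 5)
                else "non-responder")
        assert got == want

    def test_record_label_and_missing_t10(self):
        s = SubjectRecord(id="x", group="iTBS", affected_side="left",
                          updrs_t0=20.0, updrs_t10=13.0)
        assert s.responder is True
        assert s.improvement_rate == pytest.approx(0.35)
        s2 = SubjectRecord(id="y", group="iTBS", affected_side="left",
                           updrs_t0=20.0)
        assert s2.responder is None


class TestSubscores:
    def test_tremor_is_items_20_21(self):
        items = {k: 1.0 for k in range(18, 32)}
        items[20], items[21] = 3.0, 2.0
        sub = updrs_subscores(items)
        assert sub["tremor"] == 5.0
        assert sub["rigidity"] == items[22]
        assert sub["bradykinesia"] == items[31]

    def test_missing_items_reported(self):
        with pytest.raises(KeyError, match="missing items"):
            updrs_subscores({20: 1.0})


class TestFeatures:
    def test_feature_vector_order_and_unlabeled_drop(self):
        subs = [
            SubjectRecord(id="a", group="iTBS", affected_side="left",
                          updrs_t0=20, updrs_t10=10,
                          frontal_delta_rel=0.355, f2f7_delta_pli=0.2),
            SubjectRecord(id="b", group="iTBS", affected_side="left",
                          updrs_t0=20, updrs_t10=19,
                          frontal_delta_rel=0.44, f2f7_delta_pli=0.3),
            SubjectRecord(id="c", group="iTBS", affected_side="left",
                          updrs_t0=20,  # no T10: unlabeled, dropped
                          frontal_delta_rel=0.5, f2f7_delta_pli=0.1),
        ]
        X, y = extract_features(subs)
        assert X.shape == (2, 2)
        assert np.allclose(X[0], [0.355, 0.2])
        assert list(y) == [1, 0]

    def test_fold_zscore_normalizes_training_fold(self):
        rng = np.random.default_rng(0)
        tr = rng.normal(5, 2, (30, 2))
        te = rng.normal(5, 2, (10, 2))
        ztr, zte = _fold_zscore(tr, te)
        assert np.allclose(ztr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(ztr.std(axis=0), 1, atol=1e-12)
        assert zte.shape == te.shape

    def test_constant_column_zscored_to_zero_with_warning(self):
        tr = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant feature"):
            ztr, _ = _fold_zscore(tr, tr)
        assert np.allclose(ztr[:, 0], 0.0)


class TestNestedCv:
    def test_separable_features_classified_nearly_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(5, 1, (15, 2))])
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        rep = nested_cv_classify(X, y, repetitions=5, seed=1)
        assert rep.balanced_accuracy >= 0.95
        assert rep.auc >= 0.98

    def test_seeding_contract(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (24, 2))
        y = np.r_[np.zeros(12, int), np.ones(12, int)]
        a = nested_cv_classify(X, y, repetitions=1, seed=7)
        b = nested_cv_classify(X, y, repetitions=2, seed=7)
        assert a.per_repetition_auc[0] == b.per_repetition_auc[0]
        assert a.per_repetition_bal_acc[0] == b.per_repetition_bal_acc[0]

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(3, 1, (15, 2))])
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        aucs = []
        for pseed in range(5):
            yp = np.random.default_rng(pseed).permutation(y)
            rep = nested_cv_classify(X, yp, repetitions=4, seed=3)
            aucs.append(rep.auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="two classes"):
            nested_cv_classify(X, np.zeros(10, int), repetitions=1)


class TestRoc:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        rep = roc_report(y.astype(float), y)
        assert rep["auc"] == 1.0
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 1.0

    def test_constant_scores_are_chance(self):
        rep = roc_report(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert rep["auc"] == pytest.approx(0.5)

    def test_auc_matches_pairwise_bruteforce(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        rep = roc_report(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep["auc"] == pytest.approx(wins / (len(pos) * len(neg)))
        assert rep["auc"] == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_report(np.arange(4.0), np.zeros(4, int))


class TestGroupDifferences:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        out = group_difference_tests({"f": (a, a.copy())})
        assert out["f"]["p"] > 0.9

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 26)
        b = rng.normal(1.5, 1, 26)
        out = group_difference_tests({"f": (a, b)})
        assert out["f"]["p"] < 0.05

    def test_fdr_adjustment_matches_hand_applied_bh_stepup(self):
        # four feature comparisons with very different separations; the
        # BH-adjusted output must agree with a hand-applied step-up on the
        # raw p-values the tests produced
        rng = np.random.default_rng(6)
        table = {}
        for i, shift in enumerate((3.0, 1.5, 1.0, 0.0)):
            table[f"f{i}"] = (rng.normal(0, 1, 20), rng.normal(shift, 1, 20))
        names = tuple(table)
        out = group_difference_tests(table, fdr_features=names)
        raw = np.array([out[n]["p"] for n in names])
        m = len(raw)
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):  # step-up from the largest p
            i = order[rank]
            running = min(running, raw[i] * m / (rank + 1))
            adj[i] = running
        for i, n in enumerate(names):
            assert out[n]["p_fdr"] == pytest.approx(adj[i])
            assert out[n]["reject_fdr"] == (adj[i] <= 0.05)

    def test_zero_variance_skipped_with_note(self):
        out = group_difference_tests({"f": (np.ones(5), np.ones(5))})
        assert out["f"]["test"] == "skipped"
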