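"""AUC statistics, DeLong, bootstrap CIs, reports, calibration, attributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import pair_counting_auc
from kineticrad.evaluation import (
    UndefinedAUCError,
    UnstableCIError,
    attribution_summary,
    attributions,
    bootstrap_ci,
    calibration_curve,
    class_ovr_auc,
    classification_report,
    delong_test,
    delong_variance,
    evaluate_probs,
    micro_macro_auc,
    ovr_auc,
)
from kineticrad.io import SUBTYPES
from kineticrad.models import SubtypeModel


class TestAUC:
    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            s = rng.integers(0, 8, size=60).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            assert ovr_auc(s, y) == pytest.approx(pair_counting_auc(s, y), abs=1e-12)

    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 0, 1, 1])
        assert ovr_auc(np.array([1, 2, 3, 4, 5.0]), y) == 1.0
        assert ovr_auc(np.array([5, 4, 3, 2, 1.0]), y) == 0.0
        assert ovr_auc(np.ones(5), y) == 0.5

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        aucs = [
            ovr_auc(rng.standard_normal(400), rng.integers(0, 2, 400))
            for _ in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            ovr_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_micro_equals_macro_when_balanced_and_symmetric(self):
        """With balanced classes and per-class scores drawn from the same
        generating law, micro and macro estimate the same quantity."""
        rng = np.random.default_rng(2)
        n = 600
        labels = np.array(SUBTYPES)[np.repeat([0, 1, 2], n // 3)]
        probs = rng.uniform(size=(n, 3))
        for k, c in enumerate(SUBTYPES):
            probs[labels == c, k] += 0.8
        micro, macro = micro_macro_auc(probs, labels)
        assert micro == pytest.approx(macro, abs=0.02)
        for c in SUBTYPES:
            assert class_ovr_auc(probs, labels, c) > 0.7

    def test_micro_is_flattened_auc(self):
        rng = np.random.default_rng(3)
        labels = np.array(SUBTYPES)[rng.integers(0, 3, 90)]
        probs = rng.uniform(size=(90, 3))
        onehot = np.column_stack([(labels == c).astype(int) for c in SUBTYPES])
        micro, _ = micro_macro_auc(probs, labels)
        assert micro == pytest.approx(
            pair_counting_auc(probs.ravel(), onehot.ravel()), abs=1e-12
        )


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(80)
        y = rng.integers(0, 2, 80)
        z, p = delong_test(s, s.copy(), y)
        assert z == 0.0 and p == 1.0

    def test_variance_matches_mann_whitney_null_closed_form(self):
        """Under exchangeable continuous scores the MW AUC variance is
        (m + n + 1) / (12 m n); the DeLong estimate must track it on average."""
        rng = np.random.default_rng(5)
        m, n = 40, 60
        closed = (m + n + 1) / (12 * m * n)
        ests = []
        for _ in range(300):
            s = rng.standard_normal(m + n)
            y = np.concatenate([np.ones(m), np.zeros(n)]).astype(int)
            ests.append(delong_variance(s, y)[1])
        assert np.mean(ests) == pytest.approx(closed, rel=0.1)

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(6)
        n = 300
        y = rng.integers(0, 2, n)
        good = y + 0.5 * rng.standard_normal(n)
        bad = rng.standard_normal(n)
        z, p = delong_test(good, bad, y)
        assert p < 1e-6 and z > 0

    def test_auc_component_matches_rank_estimate(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(100)
        y = rng.integers(0, 2, 100)
        auc, _ = delong_variance(s, y)
        assert auc == pytest.approx(ovr_auc(s, y), abs=1e-12)


class TestBootstrap:
    def test_degenerate_point_mass(self):
        # perfect scores: every resample has AUC 1 -> zero-width CI at 1
        y = np.repeat([0, 1], 20)
        probs = np.column_stack([1 - y, y]).astype(float)
        lo, hi = bootstrap_ci(
            lambda p, yy: ovr_auc(p[:, 1], yy), probs, y, reps=200, seed=0
        )
        assert lo == hi == 1.0

    def test_unstable_when_class_nearly_absent(self):
        y = np.array([1] + [0] * 60)
        probs = np.random.default_rng(8).uniform(size=(61, 2))
        with pytest.raises(UnstableCIError):
            bootstrap_ci(lambda p, yy: ovr_auc(p[:, 1], yy), probs, y, reps=200, seed=8)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(9)
        n = 150
        y = rng.integers(0, 2, n)
        probs = 0.3 * np.column_stack([1 - y, y]) + 0.7 * rng.uniform(size=(n, 2))
        point = ovr_auc(probs[:, 1], y)
        lo, hi = bootstrap_ci(
            lambda p, yy: ovr_auc(p[:, 1], yy), probs, y, reps=500, seed=9
        )
        assert lo <= point <= hi
        assert 0.0 < lo < hi <= 1.0


class TestReports:
    def test_classification_report_hand_arithmetic(self):
        """Toy: 3 patients per class, argmax correct for 2 of 3 in each class,
        errors forming a cycle -> precision = recall = F1 = 2/3 everywhere."""
        labels = np.repeat(list(SUBTYPES), 3)
        probs = np.zeros((9, 3))
        for i, c in enumerate(labels):
            k = list(SUBTYPES).index(c)
            probs[i, k] = 1.0
        # one error per class, cycling: class k -> class (k+1) % 3
        for k, i in enumerate([2, 5, 8]):
            probs[i] = 0.0
            probs[i, (k + 1) % 3] = 1.0
        cm, metrics = classification_report(probs, labels)
        assert np.trace(cm.to_numpy()) == 6
        for c in SUBTYPES:
            assert metrics.loc[c, "precision"] == pytest.approx(2 / 3)
            assert metrics.loc[c, "recall"] == pytest.approx(2 / 3)
            assert metrics.loc[c, "f1"] == pytest.approx(2 / 3)
            assert metrics.loc[c, "support"] == 3

    def test_calibration_curve_simulated(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=20000)
        y = rng.uniform(size=20000) < p
        curve = calibration_curve(p, y, n_bins=10)
        assert len(curve) == 10
        np.testing.assert_allclose(
            curve["mean_predicted"], curve["observed_frequency"], atol=0.03
        )
        assert not curve["low_count"].any()

    def test_calibration_single_occupied_bin(self):
        curve = calibration_curve(np.full(3, 0.55), np.array([0, 1, 1]))
        assert len(curve) == 1
        assert curve.iloc[0]["low_count"]
        assert curve.iloc[0]["observed_frequency"] == pytest.approx(2 / 3)

    def test_evaluate_probs_assembles(self):
        rng = np.random.default_rng(11)
        n = 120
        labels = np.array(SUBTYPES)[np.repeat([0, 1, 2], n // 3)]
        probs = rng.uniform(size=(n, 3))
        for k, c in enumerate(SUBTYPES):
            probs[labels == c, k] += 0.7
        rep = evaluate_probs(probs, labels, dataset="toy", bootstrap_reps=200, seed=11)
        assert rep.micro_auc_ci[0] <= rep.micro_auc <= rep.micro_auc_ci[1]
        assert set(rep.ovr_aucs) == set(SUBTYPES)
        assert rep.confusion.to_numpy().sum() == n
        d = rep.to_json()
        assert d["dataset"] == "toy" and "micro_auc" in d


class TestAttributions:
    @staticmethod
    def _fitted(seed=12, dup=False):
        rng = np.random.default_rng(seed)
        n = 180
        y = pd.Series(np.array(SUBTYPES)[np.repeat([0, 1, 2], n // 3)])
        centers = {"HR+/HER2-": (0, 0), "HER2+": (3, 0), "TNBC": (0, 3)}
        X = np.array([centers[c] for c in y]) + 0.6 * rng.standard_normal((n, 2))
        cols = {"u": X[:, 0], "v": X[:, 1], "null_player": rng.standard_normal(n)}
        if dup:
            cols["u_dup"] = cols["u"].copy()
        Xdf = pd.DataFrame(cols)
        return SubtypeModel(Xdf, y).fit(seed=seed), Xdf

    def test_local_accuracy_in_log_odds(self):
        res, X = self._fitted()
        attr = attributions(res, X)
        raw = {
            c: res.boosters[c].booster_.predict(X.to_numpy(dtype=float), raw_score=True)
            for c in res.class_order
        }
        for c in res.class_order:
            np.testing.assert_allclose(attr[c].sum(axis=1), raw[c], atol=1e-4)

    def test_null_player_gets_no_credit(self):
        res, X = self._fitted()
        summ = attribution_summary(res, X)
        for c in res.class_order:
            assert summ.loc["null_player", c] < 0.15 * max(
                summ.loc["u", c], summ.loc["v", c]
            )

    def test_summary_shape_and_nonnegativity(self):
        res, X = self._fitted()
        summ = attribution_summary(res, X)
        assert list(summ.index) == list(X.columns)
        assert set(summ.columns) == set(SUBTYPES)
        assert (summ.to_numpy() >= 0).all()
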