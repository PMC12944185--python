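"""One-vs-all boosted models, sqrt-balanced weights, isotonic calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.isotonic import IsotonicRegression

from kineticrad.io import SUBTYPES
from kineticrad.models import (
    AlignmentError,
    BoostingParams,
    DegenerateTrainingError,
    FusionModel,
    StratificationError,
    SubtypeModel,
    split_cohort,
    sqrt_balanced_weights,
)
from _oracles import isotonic_minmax, pair_counting_auc


def _separable_cohort(seed=0, n=180):
    rng = np.random.default_rng(seed)
    y = np.array(SUBTYPES)[np.repeat([0, 1, 2], n // 3)]
    centers = {"HR+/HER2-": (0, 0), "HER2+": (4, 0), "TNBC": (0, 4)}
    X = np.array([centers[c] for c in y]) + 0.5 * rng.standard_normal((n, 2))
    return pd.DataFrame(X, columns=["u", "v"]), pd.Series(y)


class TestWeights:
    def test_sqrt_balanced_ratio(self):
        labels = np.concatenate(
            [np.repeat("HR+/HER2-", 299), np.repeat("HER2+", 235), np.repeat("TNBC", 142)]
        )
        w = sqrt_balanced_weights(labels)
        assert w["HR+/HER2-"] == pytest.approx(1.0)
        assert w["TNBC"] == pytest.approx(np.sqrt(299 / 142))
        assert w["TNBC"] == pytest.approx(1.451, abs=0.001)
        assert w["HER2+"] == pytest.approx(np.sqrt(299 / 235))

    def test_balanced_labels_unit_weights(self):
        w = sqrt_balanced_weights(np.repeat(["a", "b"], 10))
        assert w == {"a": 1.0, "b": 1.0}


class TestSplit:
    def test_8_to_2_arithmetic(self):
        # 845 patients split 8:2 -> 676 train / 169 validation
        labels = pd.Series(
            np.repeat(["HR+/HER2-", "HER2+", "TNBC"], [425, 280, 140]),
            index=[f"P{i}" for i in range(845)],
        )
        train, val = split_cohort(labels, test_fraction=0.2, seed=0)
        assert len(train) == 676 and len(val) == 169
        # stratification: per-class validation counts within 1 of n*0.2
        for cls, n in [("HR+/HER2-", 425), ("HER2+", 280), ("TNBC", 140)]:
            n_val = sum(labels[i] == cls for i in val)
            assert abs(n_val - 0.2 * n) <= 1.0

    def test_disjoint_and_deterministic(self):
        labels = pd.Series(
            np.repeat(["HR+/HER2-", "HER2+", "TNBC"], [15, 12, 7]),
            index=[f"P{i}" for i in range(34)],
        )
        t1, v1 = split_cohort(labels, seed=3)
        t2, v2 = split_cohort(labels, seed=3)
        assert t1 == t2 and v1 == v2
        assert set(t1).isdisjoint(v1)
        assert set(t1) | set(v1) == set(labels.index)

    def test_tiny_class_rejected(self):
        labels = pd.Series(
            ["HR+/HER2-"] * 20 + ["HER2+"] * 20 + ["TNBC"] * 4,
            index=[f"P{i}" for i in range(44)],
        )
        with pytest.raises(StratificationError):
            split_cohort(labels)


class TestSubtypeModel:
    def test_separable_data_learned(self):
        X, y = _separable_cohort(seed=1)
        res = SubtypeModel(X, y, source="TIC-WIR").fit(seed=1)
        probs = res.predict_proba(X)
        for k, cls in enumerate(res.class_order):
            auc = pair_counting_auc(probs[:, k], (y == cls).to_numpy())
            assert auc > 0.99, cls

    def test_predict_proba_rows_sum_to_one(self):
        X, y = _separable_cohort(seed=2)
        res = SubtypeModel(X, y).fit(seed=2)
        probs = res.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_calibrated_probs_not_renormalized(self):
        """predict_calibrated is exactly the per-class calibrator applied to
        the raw one-vs-all scores — no renormalization step in between."""
        X, y = _separable_cohort(seed=3)
        res = SubtypeModel(X, y).fit(seed=3)
        raw = res.predict_raw(X)
        manual = np.column_stack(
            [res.calibrators[c].predict(raw[:, k]) for k, c in enumerate(res.class_order)]
        )
        np.testing.assert_array_equal(res.predict_calibrated(X), manual)

    def test_deterministic_given_seed(self):
        X, y = _separable_cohort(seed=4)
        a = SubtypeModel(X, y).fit(seed=4).predict_proba(X)
        b = SubtypeModel(X, y).fit(seed=4).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_summary_contents(self):
        X, y = _separable_cohort(seed=5)
        res = SubtypeModel(X, y, source="TIC-Area").fit(seed=5)
        summ = res.summary()
        assert list(summ["class"]) == list(SUBTYPES)
        assert (summ["source"] == "TIC-Area").all()
        assert (summ["n_positive"] == 60).all()

    def test_single_class_rejected(self):
        X, _ = _separable_cohort()
        with pytest.raises(DegenerateTrainingError):
            SubtypeModel(X, pd.Series(["TNBC"] * len(X)))

    def test_misaligned_labels_rejected(self):
        X, y = _separable_cohort()
        with pytest.raises(AlignmentError):
            SubtypeModel(X, y.iloc[:-3])


class TestIsotonicCalibration:
    def test_sklearn_matches_minmax_closed_form(self):
        """The per-class calibrator is plain isotonic regression; its fit on
        <=6 points must equal the exact min-max monotone least-squares
        solution, including the non-monotone hand case."""
        cases = [
            [0.0, 1.0, 0.0, 1.0],  # x = 0.1, 0.2, 0.3, 0.4 -> pooled 0.5s
            [1.0, 0.0],
            [0.2, 0.8, 0.4, 0.9, 0.1, 1.0],
            [0.5, 0.5, 0.5],
        ]
        for y in cases:
            x = 0.1 * (1 + np.arange(len(y)))
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(x, y)
            np.testing.assert_allclose(
                iso.predict(x), np.clip(isotonic_minmax(y), 0, 1), atol=1e-12
            )

    def test_hand_case_pools_middle_violation(self):
        # y = 0, 1, 0, 1: only the violating middle pair (1, 0) pools to 0.5
        iso = IsotonicRegression(out_of_bounds="clip")
        iso.fit([0.1, 0.2, 0.3, 0.4], [0.0, 1.0, 0.0, 1.0])
        np.testing.assert_allclose(
            iso.predict([0.1, 0.2, 0.3, 0.4]), [0.0, 0.5, 0.5, 1.0]
        )

    def test_calibrator_improves_monotone_grouping(self):
        X, y = _separable_cohort(seed=6)
        res = SubtypeModel(X, y).fit(seed=6)
        # calibrated map must be monotone in the raw score
        raw = np.linspace(0, 1, 101)
        for cls in res.class_order:
            out = res.calibrators[cls].predict(raw)
            assert np.all(np.diff(out) >= -1e-12)


class TestFusion:
    def test_fusion_input_layout_and_fit(self):
        X, y = _separable_cohort(seed=7)
        res_a = SubtypeModel(X, y, source="TIC-WIR").fit(seed=7)
        res_b = SubtypeModel(X, y, source="TIC-Area").fit(seed=8)
        cal_a, cal_b = res_a.predict_calibrated(X), res_b.predict_calibrated(X)
        fusion = FusionModel(cal_a, cal_b, y).fit(seed=9)
        assert fusion.feature_names == [
            "TICWIR_p_HR+/HER2-", "TICWIR_p_HER2+", "TICWIR_p_TNBC",
            "TICArea_p_HR+/HER2-", "TICArea_p_HER2+", "TICArea_p_TNBC",
        ]
        from kineticrad.models import fusion_inputs

        probs = fusion.predict_proba(fusion_inputs(cal_a, cal_b))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs.argmax(axis=1) == [list(SUBTYPES).index(c) for c in y]).mean() > 0.95

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            FusionModel(np.zeros((10, 3)), np.zeros((9, 3)), pd.Series(["a"] * 10))

    def test_fusion_dominance_over_noise_channel(self):
        """One informative base model, one pure-noise base model: fusion
        trained on cross-fitted calibrated probabilities stays within 0.03
        macro AUC of the informative base on held-out data, on average over
        20 seeds (with a looser per-seed guard, since a 120-sample
        meta-learner admits small single-seed excursions)."""
        from kineticrad.evaluation import micro_macro_auc
        from kineticrad.models import cross_fitted_calibrated_probs, fusion_inputs

        params = BoostingParams(n_estimators=100)
        margins = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 360  # large held-out set so AUC sampling noise stays small
            y = pd.Series(np.array(SUBTYPES)[np.repeat([0, 1, 2], n // 3)])
            centers = {"HR+/HER2-": (0, 0), "HER2+": (2.5, 0), "TNBC": (0, 2.5)}
            info = pd.DataFrame(
                np.array([centers[c] for c in y]) + 0.8 * rng.standard_normal((n, 2)),
                columns=["u", "v"],
            )
            noise = pd.DataFrame(
                rng.standard_normal((n, 2)), columns=["a", "b"]
            )
            tr = np.concatenate([np.arange(k * 120, k * 120 + 40) for k in range(3)])
            te = np.setdiff1d(np.arange(n), tr)
            y_tr, y_te = y.iloc[tr], y.iloc[te]

            res_info = SubtypeModel(info.iloc[tr], y_tr, params=params).fit(seed)
            res_noise = SubtypeModel(noise.iloc[tr], y_tr, params=params).fit(seed)
            oof_info = cross_fitted_calibrated_probs(
                info.iloc[tr], y_tr, params=params, seed=seed
            )
            oof_noise = cross_fitted_calibrated_probs(
                noise.iloc[tr], y_tr, params=params, seed=seed
            )
            fusion = FusionModel(oof_info, oof_noise, y_tr, params=params).fit(seed)

            val_X = fusion_inputs(
                res_info.predict_calibrated(info.iloc[te]),
                res_noise.predict_calibrated(noise.iloc[te]),
            )
            _, macro_fusion = micro_macro_auc(fusion.predict_proba(val_X), y_te)
            _, macro_info = micro_macro_auc(res_info.predict_proba(info.iloc[te]), y_te)
            margins.append(macro_fusion - macro_info)
        assert float(np.mean(margins)) >= -0.03, margins
        assert min(margins) >= -0.06, margins
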