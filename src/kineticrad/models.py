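"""Boosted one-vs-all subtype models, isotonic calibration, decision fusion.

The modelling surface follows the Model/Results convention: a
:class:`SubtypeModel` is built from a feature table and labels, its
``fit()`` returns a :class:`SubtypeModelResults` that carries the fitted
one-vs-all gradient-boosted trees, the per-class isotonic calibrators and
a ``summary()``. A :class:`FusionModel` stacks the calibrated per-class
probabilities of two base results into a combined decision-level model.

One-vs-all semantics are realised as K independent binary boosted models
(no softmax coupling); each sample is weighted by the square-root-balanced
weight of its true class, w_c = sqrt(max_k n_k / n_c), which damps class
imbalance without fully inverting it.

Calibrated per-class probabilities are deliberately NOT renormalized
before entering the fusion model — they are features there, and
renormalization would destroy the marginal calibration the isotonic maps
just learned. Only ``predict_proba`` outputs, which are meant to be class
distributions, are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import train_test_split

from .io import SUBTYPES


class DegenerateTrainingError(ValueError):
    """Training labels contain fewer than 2 classes."""


class AlignmentError(ValueError):
    """Row misalignment between probability matrices and labels."""


class StratificationError(ValueError):
    """A class is too small to stratify."""


@dataclass
class BoostingParams:
    """Gradient-boosting hyperparameters (unexposed settings use library
    defaults). Modest depth/iterations suit the few-hundred-patient
    cohorts this method targets."""

    n_estimators: int = 300
    learning_rate: float = 0.05
    max_depth: int = 6
    num_leaves: int = 31
    min_child_samples: int = 5
    early_stopping_fraction: float | None = None  # e.g. 0.1 for a 10% holdout

    def to_lgbm(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "num_leaves": self.num_leaves,
            "min_child_samples": self.min_child_samples,
            "verbose": -1,
        }


def sqrt_balanced_weights(labels: np.ndarray) -> dict[str, float]:
    """Per-class weights w_c = sqrt(max_k n_k / n_c)."""
    classes, counts = np.unique(labels, return_counts=True)
    n_max = counts.max()
    return {c: float(np.sqrt(n_max / n)) for c, n in zip(classes, counts)}


def split_cohort(
    labels: pd.Series, test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train / internal-validation split of patient ids (8:2
    by default). Requires >= 5 patients per class."""
    y = labels.to_numpy()
    ids = labels.index.to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise StratificationError(
            f"smallest class has {counts.min()} patients; need >= 5 to stratify"
        )
    train_ids, val_ids = train_test_split(
        ids, test_size=test_fraction, stratify=y, random_state=seed
    )
    return list(train_ids), list(val_ids)


class SubtypeModel:
    """One-vs-all boosted multiclass model over a radiomics feature table.

    Parameters
    ----------
    features : patients x selected-features table (training rows).
    labels : subtype per patient, aligned with ``features``.
    source : image type the features came from ("TIC-WIR", "TIC-Area",
        "MR-ORI", ...), recorded as metadata.
    class_order : fixed output class order.
    params : boosting hyperparameters.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series | np.ndarray,
        source: str = "unknown",
        class_order: tuple[str, ...] = SUBTYPES,
        params: BoostingParams | None = None,
    ) -> None:
        self.features = features
        self.labels = np.asarray(labels)
        if len(self.labels) != len(features):
            raise AlignmentError("labels and features row counts differ")
        present = set(np.unique(self.labels))
        if len(present) < 2:
            raise DegenerateTrainingError("training labels contain a single class")
        if not present <= set(class_order):
            raise ValueError(f"labels {present - set(class_order)} not in class order")
        self.source = source
        self.class_order = tuple(class_order)
        self.params = params or BoostingParams()

    def fit(self, seed: int = 0) -> "SubtypeModelResults":
        weights_by_class = sqrt_balanced_weights(self.labels)
        sample_w = np.array([weights_by_class[c] for c in self.labels])
        X = self.features.to_numpy(dtype=float)

        boosters: dict[str, lgb.LGBMClassifier] = {}
        for cls in self.class_order:
            y_bin = (self.labels == cls).astype(int)
            clf = lgb.LGBMClassifier(
                objective="binary", random_state=seed, **self.params.to_lgbm()
            )
            fit_kwargs: dict = {"sample_weight": sample_w}
            if self.params.early_stopping_fraction:
                Xt, Xv, yt, yv, wt, _ = train_test_split(
                    X,
                    y_bin,
                    sample_w,
                    test_size=self.params.early_stopping_fraction,
                    stratify=y_bin,
                    random_state=seed,
                )
                clf.fit(
                    Xt,
                    yt,
                    sample_weight=wt,
                    eval_set=[(Xv, yv)],
                    callbacks=[lgb.early_stopping(25, verbose=False)],
                )
            else:
                clf.fit(X, y_bin, **fit_kwargs)
            boosters[cls] = clf

        results = SubtypeModelResults(
            model=self,
            boosters=boosters,
            feature_names=list(self.features.columns),
            seed=seed,
            class_weights=weights_by_class,
        )
        results._fit_calibrators(self.features, self.labels)
        return results


@dataclass
class SubtypeModelResults:
    """Fitted one-vs-all model + per-class isotonic calibrators."""

    model: SubtypeModel
    boosters: dict[str, lgb.LGBMClassifier]
    feature_names: list[str]
    seed: int
    class_weights: dict[str, float]
    calibrators: dict[str, IsotonicRegression] = field(default_factory=dict)

    @property
    def class_order(self) -> tuple[str, ...]:
        return self.model.class_order

    def _check(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            features = features[self.feature_names]
        return features.to_numpy(dtype=float)

    def predict_raw(self, features: pd.DataFrame) -> np.ndarray:
        """Uncalibrated per-class one-vs-all probabilities (n x K).
        Columns follow ``class_order``; rows need not sum to 1."""
        X = self._check(features)
        return np.column_stack(
            [self.boosters[c].predict_proba(X)[:, 1] for c in self.class_order]
        )

    def _fit_calibrators(self, features: pd.DataFrame, labels: np.ndarray) -> None:
        raw = self.predict_raw(features)
        for k, cls in enumerate(self.class_order):
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(raw[:, k], (labels == cls).astype(float))
            self.calibrators[cls] = iso

    def predict_calibrated(self, features: pd.DataFrame) -> np.ndarray:
        """Isotonically calibrated per-class probabilities (n x K, not
        renormalized — see module docstring)."""
        raw = self.predict_raw(features)
        return np.column_stack(
            [self.calibrators[c].predict(raw[:, k]) for k, c in enumerate(self.class_order)]
        )

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Calibrated probabilities renormalized to a distribution."""
        cal = self.predict_calibrated(features)
        return _normalize_rows(cal)

    def summary(self) -> pd.DataFrame:
        """Per-class training metadata table."""
        rows = []
        for cls in self.class_order:
            clf = self.boosters[cls]
            rows.append(
                {
                    "class": cls,
                    "source": self.model.source,
                    "n_train": len(self.model.labels),
                    "n_positive": int((self.model.labels == cls).sum()),
                    "class_weight": self.class_weights.get(cls, np.nan),
                    "n_trees": clf.booster_.num_trees(),
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _normalize_rows(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    s = p.sum(axis=1, keepdims=True)
    uniform = np.full_like(p, 1.0 / p.shape[1])
    return np.where(s > 1e-12, p / np.where(s > 1e-12, s, 1.0), uniform)


def cross_fitted_calibrated_probs(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    source: str = "unknown",
    class_order: tuple[str, ...] = SUBTYPES,
    params: BoostingParams | None = None,
    seed: int = 0,
    folds: int = 5,
) -> np.ndarray:
    """Out-of-fold calibrated probabilities of a base model (n x K).

    Boosted trees can memorize a small training set, in which case the
    in-sample calibrated probabilities collapse to the one-hot labels for
    every source regardless of its real signal — blinding any stacked
    model trained on them. Cross-fitting (fit on K-1 folds, predict the
    held-out fold) restores honest training-time inputs for fusion.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise StratificationError("need >= 2 samples per class for cross-fitting")
    out = np.zeros((len(y), len(class_order)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(features, y):
        res = SubtypeModel(
            features.iloc[tr], y[tr], source=source,
            class_order=class_order, params=params,
        ).fit(seed=seed)
        out[te] = res.predict_calibrated(features.iloc[te])
    return out


def fusion_inputs(
    wir_cal_probs: np.ndarray, area_cal_probs: np.ndarray,
    class_order: tuple[str, ...] = SUBTYPES,
) -> pd.DataFrame:
    """Assemble the 6-column stacked input with a fixed, recorded order."""
    if wir_cal_probs.shape != area_cal_probs.shape:
        raise AlignmentError("base-model probability matrices differ in shape")
    cols = [f"TICWIR_p_{c}" for c in class_order] + [
        f"TICArea_p_{c}" for c in class_order
    ]
    return pd.DataFrame(np.column_stack([wir_cal_probs, area_cal_probs]), columns=cols)


class FusionModel(SubtypeModel):
    """Decision-level fusion: a boosted model over the 6 calibrated
    per-class probabilities of the TIC-WIR and TIC-Area base models."""

    def __init__(
        self,
        wir_cal_probs: np.ndarray,
        area_cal_probs: np.ndarray,
        labels: pd.Series | np.ndarray,
        class_order: tuple[str, ...] = SUBTYPES,
        params: BoostingParams | None = None,
    ) -> None:
        X = fusion_inputs(wir_cal_probs, area_cal_probs, class_order)
        if len(X) != len(np.asarray(labels)):
            raise AlignmentError("probability rows and labels differ in length")
        super().__init__(X, labels, source="TIC-Combined", class_order=class_order, params=params)
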