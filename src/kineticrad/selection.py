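"""Three-step feature selection, fitted on the training split and frozen.

1. variance filter: drop columns whose raw sample variance is below a
   threshold (default 0.01) — applied before any standardization, since a
   variance threshold on z-scored data would be vacuous;
2. correlation pruning: while any pair of surviving features has
   |Pearson r| > 0.8, take the worst pair (largest |r|) and drop the
   member with the higher mean absolute correlation to all remaining
   features (ties drop the later column);
3. LASSO: multinomial L1-penalized logistic regression on z-scored
   features, penalty chosen by stratified 10-fold cross-validated mean
   deviance; kept features are those with any nonzero coefficient across
   the classes.

The result is a frozen, ordered list of column names; applying it to new
data touches nothing but those names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler


class SelectionCollapseError(ValueError):
    """Every feature was eliminated."""


class StratificationError(ValueError):
    """Too few samples per class for the requested CV folds."""


@dataclass
class SelectionResult:
    """Frozen outcome of the three-step selection."""

    kept_features: list[str]
    variance_removed: list[str] = field(default_factory=list)
    correlation_removed: list[str] = field(default_factory=list)
    lasso_removed: list[str] = field(default_factory=list)
    lasso_lambda: float | None = None

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project any feature table onto the frozen selection."""
        return table[self.kept_features]

    def to_json(self) -> dict:
        return {
            "kept_features": self.kept_features,
            "variance_removed": self.variance_removed,
            "correlation_removed": self.correlation_removed,
            "lasso_removed": self.lasso_removed,
            "lasso_lambda": self.lasso_lambda,
        }

    @classmethod
    def from_json(cls, d: dict) -> "SelectionResult":
        return cls(**d)


def variance_filter(table: pd.DataFrame, threshold: float = 0.01) -> SelectionResult:
    """Drop columns whose sample variance (ddof=1) is below ``threshold``."""
    if len(table) < 2:
        raise ValueError("variance filter needs at least 2 rows")
    variances = table.var(axis=0, ddof=1)
    kept = [c for c in table.columns if variances[c] >= threshold]
    removed = [c for c in table.columns if c not in kept]
    if not kept:
        raise SelectionCollapseError("variance filter removed every feature")
    return SelectionResult(kept_features=kept, variance_removed=removed)


def correlation_prune(table: pd.DataFrame, r_max: float = 0.8) -> SelectionResult:
    """Iteratively break up highly correlated pairs.

    At each step the pair with the largest |r| > r_max loses its member
    with the higher mean absolute correlation to all current features.
    Deterministic given column order.
    """
    cols = list(table.columns)
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(cols), dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        if sub.max() <= r_max:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if i > j:
            i, j = j, i
        mean_i = sub[i, alive].sum() / (alive.sum() - 1)
        mean_j = sub[j, alive].sum() / (alive.sum() - 1)
        drop = j if mean_j >= mean_i else i  # tie -> later column
        alive[drop] = False
        removed.append(cols[drop])
    kept = [c for c, a in zip(cols, alive) if a]
    return SelectionResult(kept_features=kept, correlation_removed=removed)


def lasso_select(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
    lambda_override: float | None = None,
) -> SelectionResult:
    """Multinomial L1 logistic selection with stratified K-fold CV.

    Features are z-scored (training statistics) before fitting; the
    penalty minimising mean CV deviance is used and features with any
    nonzero coefficient across classes are kept. ``lambda_override``
    skips the CV and fits at a fixed penalty.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if lambda_override is None and counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; {folds}-fold "
            "stratified CV needs at least one sample per class per fold"
        )
    X = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    if lambda_override is not None:
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(
            C=1.0 / lambda_override,
            penalty="l1",
            solver="saga",
            max_iter=5000,
            random_state=seed,
            tol=1e-4,
        )
        model.fit(X, y)
        lam = float(lambda_override)
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LogisticRegressionCV(
            Cs=n_lambdas,
            cv=cv,
            penalty="l1",
            solver="saga",
            scoring="neg_log_loss",
            max_iter=5000,
            random_state=seed,
            tol=1e-4,
        )
        model.fit(X, y)
        lam = 1.0 / float(np.atleast_1d(model.C_)[0])
    support = np.any(np.abs(model.coef_) > 1e-10, axis=0)
    kept = [c for c, s in zip(table.columns, support) if s]
    removed = [c for c, s in zip(table.columns, support) if not s]
    if not kept:
        raise SelectionCollapseError("LASSO shrank every coefficient to zero")
    return SelectionResult(kept_features=kept, lasso_removed=removed, lasso_lambda=lam)


def select_features(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    variance_threshold: float = 0.01,
    r_max: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Run the full three-step pipeline on the training table."""
    step1 = variance_filter(table, variance_threshold)
    step2 = correlation_prune(table[step1.kept_features], r_max)
    step3 = lasso_select(table[step2.kept_features], labels, folds=folds, seed=seed)
    return SelectionResult(
        kept_features=step3.kept_features,
        variance_removed=step1.variance_removed,
        correlation_removed=step2.correlation_removed,
        lasso_removed=step3.lasso_removed,
        lasso_lambda=step3.lasso_lambda,
    )
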