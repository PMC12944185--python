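"""ROC/AUC statistics, DeLong comparisons, bootstrap CIs, calibration and
tree-ensemble attributions.

AUCs are empirical Mann-Whitney statistics (ties count 1/2). The
multiclass summary follows the one-vs-rest family: per-class OvR AUCs,
their mean (macro average) and the AUC of the flattened (sample, class)
binary problem (micro average). DeLong variances/covariances use the
placement-value (structural component) formulation; comparisons of
micro-average AUCs treat the flattened scores as the paired units, which
ignores within-patient correlation across classes — a documented caveat.
Bootstrap CIs are percentile intervals over patient-level resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .io import SUBTYPES


class UndefinedAUCError(ValueError):
    """Both classes must be present to define an AUC."""


class UnstableCIError(RuntimeError):
    """Too many bootstrap resamples were degenerate."""


# ---------------------------------------------------------------------------
# AUC family
# ---------------------------------------------------------------------------


def ovr_auc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` against binary labels (ties = 1/2)."""
    y = np.asarray(binary_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("need both positive and negative samples")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def class_ovr_auc(
    probs: np.ndarray, labels: np.ndarray, cls: str,
    class_order: Sequence[str] = SUBTYPES,
) -> float:
    """One-vs-rest AUC of class ``cls`` from an (n, K) probability matrix."""
    k = list(class_order).index(cls)
    return ovr_auc(probs[:, k], np.asarray(labels) == cls)


def micro_macro_auc(
    probs: np.ndarray, labels: np.ndarray, class_order: Sequence[str] = SUBTYPES
) -> tuple[float, float]:
    """(micro, macro) average AUC of a multiclass probability matrix."""
    labels = np.asarray(labels)
    per_class = [class_ovr_auc(probs, labels, c, class_order) for c in class_order]
    onehot = np.column_stack([(labels == c).astype(int) for c in class_order])
    micro = ovr_auc(probs.ravel(), onehot.ravel())
    return micro, float(np.mean(per_class))


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus placement values V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_s)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores: np.ndarray, binary_labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single model."""
    y = np.asarray(binary_labels).astype(bool)
    auc, v10, v01 = _placements(np.asarray(scores, float)[y], np.asarray(scores, float)[~y])
    m, n = int(y.sum()), int((~y).sum())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, binary_labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test of two correlated empirical AUCs.

    Returns (z, two-sided p). Identical score vectors (or zero variance of
    the difference with equal AUCs) give z = 0, p = 1 by convention.
    """
    y = np.asarray(binary_labels).astype(bool)
    if y.all() or (~y).all():
        raise UndefinedAUCError("need both classes for a DeLong test")
    a_pos, a_neg = np.asarray(scores_a, float)[y], np.asarray(scores_a, float)[~y]
    b_pos, b_neg = np.asarray(scores_b, float)[y], np.asarray(scores_b, float)[~y]
    auc_a, v10_a, v01_a = _placements(a_pos, a_neg)
    auc_b, v10_b, v01_b = _placements(b_pos, b_neg)
    m, n = len(a_pos), len(a_neg)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (np.inf * np.sign(diff), 0.0)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def delong_test_micro(
    probs_a: np.ndarray, probs_b: np.ndarray, labels: np.ndarray,
    class_order: Sequence[str] = SUBTYPES,
) -> tuple[float, float]:
    """DeLong comparison of micro-average AUCs on the flattened problem."""
    labels = np.asarray(labels)
    onehot = np.column_stack([(labels == c).astype(int) for c in class_order])
    return delong_test(probs_a.ravel(), probs_b.ravel(), onehot.ravel())


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    probs: np.ndarray,
    labels: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn(probs, labels)``.

    Resampling is at patient level (all class probabilities of a patient
    move together). Resamples on which the metric is undefined (a missing
    class) are skipped; more than 10% skips raises UnstableCIError.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals: list[float] = []
    skipped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(float(metric_fn(probs[idx], labels[idx])))
        except (UndefinedAUCError, ValueError):
            skipped += 1
    if skipped > 0.1 * reps:
        raise UnstableCIError(f"{skipped}/{reps} bootstrap resamples were degenerate")
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# classification report / calibration
# ---------------------------------------------------------------------------


def classification_report(
    probs: np.ndarray, labels: np.ndarray, class_order: Sequence[str] = SUBTYPES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(confusion matrix, per-class precision/recall/F1) under argmax."""
    labels = np.asarray(labels)
    order = list(class_order)
    pred = np.asarray(order)[np.argmax(probs, axis=1)]
    cm = _sk_confusion(labels, pred, labels=order)
    cm_df = pd.DataFrame(cm, index=order, columns=order)
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, pred, labels=order, zero_division=0
    )
    metrics = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support}, index=order
    )
    return cm_df, metrics


def calibration_curve(
    probs_class: np.ndarray, labels_class: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-width reliability curve for one class.

    Returns one row per occupied bin: mean predicted probability, observed
    event frequency, count, and a low-count flag (< 5 samples)."""
    p = np.asarray(probs_class, dtype=float)
    y = np.asarray(labels_class).astype(int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(p[sel].mean()),
                "observed_frequency": float(y[sel].mean()),
                "count": int(sel.sum()),
                "low_count": bool(sel.sum() < 5),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# attributions
# ---------------------------------------------------------------------------


def attributions(results, features: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-class additive feature attributions (TreeSHAP) on the raw
    (log-odds) score scale.

    For each class's one-vs-all booster, returns an (n, p+1) array whose
    first p columns are feature attributions and whose last column is the
    base value; each row sums to the booster's raw prediction exactly
    (local accuracy)."""
    X = features[results.feature_names].to_numpy(dtype=float)
    out = {}
    for cls in results.class_order:
        contrib = results.boosters[cls].booster_.predict(X, pred_contrib=True)
        out[cls] = np.asarray(contrib)
    return out


def attribution_summary(results, features: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute attribution per input feature per class."""
    attr = attributions(results, features)
    data = {
        cls: np.abs(mat[:, :-1]).mean(axis=0) for cls, mat in attr.items()
    }
    return pd.DataFrame(data, index=results.feature_names)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Full statistics battery for one model on one dataset."""

    dataset: str
    micro_auc: float
    macro_auc: float
    ovr_aucs: dict[str, float]
    micro_auc_ci: tuple[float, float]
    macro_auc_ci: tuple[float, float]
    ovr_auc_cis: dict[str, tuple[float, float]]
    confusion: pd.DataFrame
    class_metrics: pd.DataFrame
    calibration: dict[str, pd.DataFrame]
    attribution: pd.DataFrame | None = None
    delong_vs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "dataset": self.dataset,
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
            "ovr_aucs": self.ovr_aucs,
            "micro_auc_ci": list(self.micro_auc_ci),
            "macro_auc_ci": list(self.macro_auc_ci),
            "ovr_auc_cis": {k: list(v) for k, v in self.ovr_auc_cis.items()},
            "confusion": self.confusion.to_dict(),
            "class_metrics": self.class_metrics.to_dict(),
            "delong_vs": {k: list(v) for k, v in self.delong_vs.items()},
        }


def evaluate_probs(
    probs: np.ndarray,
    labels: np.ndarray,
    dataset: str = "dataset",
    class_order: Sequence[str] = SUBTYPES,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the evaluation battery from a probability matrix."""
    labels = np.asarray(labels)
    micro, macro = micro_macro_auc(probs, labels, class_order)
    ovr = {c: class_ovr_auc(probs, labels, c, class_order) for c in class_order}

    def _safe_ci(metric_fn, ci_seed, what):
        # small validation sets can make too many resamples degenerate;
        # report an undefined interval instead of aborting the whole report
        try:
            return bootstrap_ci(metric_fn, probs, labels, reps=bootstrap_reps, seed=ci_seed)
        except UnstableCIError:
            logging.getLogger("kineticrad").warning(
                "bootstrap CI for %s on %r unstable (too many degenerate "
                "resamples); reporting NaN interval", what, dataset,
            )
            return (float("nan"), float("nan"))

    micro_ci = _safe_ci(
        lambda p, y: micro_macro_auc(p, y, class_order)[0], seed, "micro AUC"
    )
    macro_ci = _safe_ci(
        lambda p, y: micro_macro_auc(p, y, class_order)[1], seed + 1, "macro AUC"
    )
    ovr_cis = {
        c: _safe_ci(
            lambda p, y, c=c: class_ovr_auc(p, y, c, class_order),
            seed + 2 + i, f"OvR AUC of {c}",
        )
        for i, c in enumerate(class_order)
    }
    cm, metrics = classification_report(probs, labels, class_order)
    calib = {
        c: calibration_curve(probs[:, k], labels == c)
        for k, c in enumerate(class_order)
    }
    return EvaluationReport(
        dataset=dataset,
        micro_auc=micro,
        macro_auc=macro,
        ovr_aucs=ovr,
        micro_auc_ci=micro_ci,
        macro_auc_ci=macro_ci,
        ovr_auc_cis=ovr_cis,
        confusion=cm,
        class_metrics=metrics,
        calibration=calib,
    )
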