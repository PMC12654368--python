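"""Metric suite: classification, regression, calibration, conformal bands,
and tertile-stratified error.

Classification metrics cover the imbalance-sensitive set (macro-F1 next to
weighted-F1 and accuracy), threshold-free discrimination (ROC AUC, average
precision), probabilistic accuracy (Brier score, calibration bins), and
row-normalized confusion matrices. Regression adds R², RMSE, error
stratified by target tertiles, and a split-conformal prediction band whose
half-width is an empirical quantile of calibration absolute residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    brier_score_loss,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)


@dataclass
class EvalReport:
    """Bundle of metric values; classification and regression share the type."""

    task: str  # "classification" | "regression"
    metrics: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None
    calibration: dict | None = None

    def to_dict(self) -> dict:
        out = {"task": self.task, "metrics": dict(self.metrics)}
        if self.confusion is not None:
            out["confusion_normalized"] = self.confusion.tolist()
        if self.calibration is not None:
            out["calibration"] = self.calibration
        return out


def order_quantile(values: np.ndarray, level: float, side: str = "higher") -> float:
    """Empirical quantile as an order statistic.

    ``higher`` returns the ceil(level·n)-th smallest value (conservative;
    with |residuals| = 1..100 and level 0.95 this is 95), ``lower`` the
    floor-based counterpart used for bootstrap CI endpoints on discrete
    grids.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    if side == "higher":
        k = max(1, math.ceil(level * n))
    elif side == "lower":
        k = min(n, max(1, math.ceil(level * n)))
    else:
        raise ValueError(f"side must be 'higher' or 'lower', got {side!r}")
    return float(v[k - 1])


def classification_report(
    y_true, p_pos, labels=None, threshold: float = 0.5, n_bins: int = 10
) -> EvalReport:
    """Full classification metric bundle from true labels and P(positive).

    *y_true* may be any binary labeling; the positive class is the larger
    label under sorting unless *labels* gives the order (negative first).
    Macro metrics average classes unweighted; weighted-F1 weights by
    support. With a single class present, AUC and AP are reported as NaN
    markers rather than raising.
    """
    y_true = np.asarray(y_true)
    p_pos = np.asarray(p_pos, dtype=np.float64)
    if labels is None:
        labels = np.unique(y_true)
        if len(labels) == 1:
            labels = list(labels)
        else:
            labels = list(labels)
    neg, pos = (labels[0], labels[-1]) if len(labels) > 1 else (labels[0], labels[0])
    y_pred = np.where(p_pos >= threshold, pos, neg)
    y_bin = (y_true == pos).astype(int)

    metrics = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        "weighted_f1": float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        "macro_precision": float(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        ),
        "macro_recall": float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        "brier": float(brier_score_loss(y_bin, p_pos)),
    }
    if len(np.unique(y_true)) > 1:
        metrics["auc"] = float(roc_auc_score(y_bin, p_pos))
        metrics["ap"] = float(average_precision_score(y_bin, p_pos))
    else:
        metrics["auc"] = float("nan")
        metrics["ap"] = float("nan")

    cm = confusion_matrix(y_true, y_pred, labels=[neg, pos]).astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cm_norm = cm / cm.sum(axis=1, keepdims=True)

    # 10 equal-width probability bins; empty bins omitted.
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p_pos, edges[1:-1]), 0, n_bins - 1)
    cal = {"bin_mid": [], "mean_predicted": [], "observed_fraction": [], "count": []}
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        cal["bin_mid"].append(float((edges[b] + edges[b + 1]) / 2))
        cal["mean_predicted"].append(float(p_pos[mask].mean()))
        cal["observed_fraction"].append(float(y_bin[mask].mean()))
        cal["count"].append(int(mask.sum()))

    return EvalReport(
        task="classification", metrics=metrics, confusion=cm_norm, calibration=cal
    )


def multiclass_report(y_true, y_pred) -> EvalReport:
    """Macro/weighted metrics for the multi-class category head."""
    labels = sorted(set(y_true) | set(y_pred))
    metrics = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        "weighted_f1": float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        "macro_precision": float(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        ),
        "macro_recall": float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
    }
    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cm_norm = cm / cm.sum(axis=1, keepdims=True)
    return EvalReport(task="classification", metrics=metrics, confusion=cm_norm)


def regression_report(y_true, y_hat) -> EvalReport:
    """R², RMSE, and tertile-stratified RMSE on -log10(mg/L) targets."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_true.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if not (np.isfinite(y_true).all() and np.isfinite(y_hat).all()):
        raise ValueError("non-finite values")
    ss_res = float(np.sum((y_true - y_hat) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_true - y_hat) ** 2)))
    metrics = {"r2": r2, "rmse": rmse}
    if y_true.size >= 3:
        low, mid, high = tertile_rmse(y_true, y_hat)
        metrics.update({"rmse_low": low, "rmse_mid": mid, "rmse_high": high})
    return EvalReport(task="regression", metrics=metrics)


def tertile_rmse(y_true, y_hat) -> tuple[float, float, float]:
    """RMSE within Low (≤ q1), Mid (q1, q2], High (> q2) target strata.

    q1 and q2 are the 1/3 and 2/3 quantiles of *y_true* ('higher' order
    statistic, so boundary points fall in the lower stratum). An empty
    stratum — possible with heavy ties at a quantile — reports NaN.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_true.size < 3:
        raise ValueError("need at least 3 points for tertiles")
    q1 = order_quantile(y_true, 1 / 3)
    q2 = order_quantile(y_true, 2 / 3)
    masks = (y_true <= q1, (y_true > q1) & (y_true <= q2), y_true > q2)
    out = []
    for m in masks:
        if not m.any():
            out.append(float("nan"))
        else:
            out.append(float(np.sqrt(np.mean((y_true[m] - y_hat[m]) ** 2))))
    return tuple(out)


@dataclass(frozen=True)
class ConformalBand:
    """Residual-based conformal prediction band on the -log10(mg/L) scale."""

    level: float
    q: float
    n_calibration: int


def conformal_band(calibration_residuals, level: float = 0.95) -> ConformalBand:
    """Half-width q = the ceil(level·n) order statistic of |residuals|.

    The empirical coverage of the band on the calibration residuals
    themselves is then at least level − 1/n. For honest coverage claims,
    evaluate :func:`coverage` on points disjoint from calibration (the
    in-sample variant is an emulation mode, not the default workflow).
    """
    r = np.abs(np.asarray(calibration_residuals, dtype=np.float64))
    if not np.isfinite(r).all():
        raise ValueError("non-finite residuals")
    if r.size < 20:
        warnings.warn(
            f"only {r.size} calibration residuals; the {level:.0%} quantile is unstable",
            stacklevel=2,
        )
    return ConformalBand(level=level, q=order_quantile(r, level), n_calibration=int(r.size))


def coverage(y_true, y_hat, q: float) -> float:
    """Fraction of points with |y − ŷ| ≤ q."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    return float(np.mean(np.abs(y_true - y_hat) <= q))
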