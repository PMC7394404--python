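"""Benchmark metrics and evaluation scenarios for variant classifiers.

All metrics derive from the confusion matrix with *deleterious* as the
positive class: a true positive is a deleterious variant called
deleterious, a true negative a benign variant called benign.  The panel
reports twelve quantities: sensitivity, specificity, precision, NPV,
accuracy, F1, MCC, ROC AUC, Log Loss, diagnostic odds ratio (DOR), FPR and
FNR.

AUC uses the rank (Mann-Whitney) statistic with tied scores receiving
averaged ranks.  DOR is (TP*TN)/(FP*FN) and is reported as +inf when the
denominator vanishes with a positive numerator.  Log Loss has two modes:
``"probability"`` evaluates the cross-entropy of the continuous scores
(clipped to [eps, 1-eps]); ``"hard"`` evaluates it on the 0/1 predicted
classes, which makes the loss proportional to the misclassification rate —
the convention under which published loss values of order 3-5 arise for
classifiers with ~90 % accuracy.

Zero-denominator metrics other than DOR are reported as NaN (an explicit
"undefined" marker), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "auc_score",
    "metric_panel",
    "repeated_balanced_eval",
    "handle_missing_scores",
    "model_concordance",
    "score_distribution_export",
    "LOG_LOSS_EPS",
]

LOG_LOSS_EPS = 1e-15


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f1: float
    mcc: float
    auc: float
    log_loss: float
    dor: float
    fpr: float
    fnr: float
    log_loss_mode: str = "probability"

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "log_loss_mode"
        }


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=int)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if arr.size and not np.isin(arr, [0, 1]).all():
        raise ValueError(f"{name} must contain only 0/1")
    return arr


def confusion(labels, classes) -> ConfusionCounts:
    """Count TP/FP/TN/FN with deleterious (1) as the positive class."""
    y = _as_binary(labels, "labels")
    c = _as_binary(classes, "classes")
    if len(y) != len(c):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(c)} classes")
    return ConfusionCounts(
        TP=int(((y == 1) & (c == 1)).sum()),
        FP=int(((y == 0) & (c == 1)).sum()),
        TN=int(((y == 0) & (c == 0)).sum()),
        FN=int(((y == 1) & (c == 0)).sum()),
    )


def auc_score(labels, scores) -> float:
    """ROC AUC via the rank statistic; tied scores get averaged ranks."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores length mismatch")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def _log_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    # clip each term's probability directly (not 1-p of a clipped p), so the
    # loss is symmetric in the two classes to full float precision
    p = np.asarray(probs, dtype=float)
    y = labels.astype(float)
    term_pos = np.log(np.clip(p, LOG_LOSS_EPS, 1.0))
    term_neg = np.log(np.clip(1 - p, LOG_LOSS_EPS, 1.0))
    return float(-np.mean(y * term_pos + (1 - y) * term_neg))


def metric_panel(
    counts: ConfusionCounts,
    scores=None,
    labels=None,
    log_loss_mode: str = "probability",
) -> MetricsReport:
    """The twelve-metric performance panel.

    ``scores`` and ``labels`` feed the AUC and the probability-mode Log
    Loss; hard-mode Log Loss is derived from the counts alone.  With
    ``scores=None`` the AUC (and probability Log Loss) are NaN.
    """
    if counts.total == 0:
        raise ValueError("empty input: confusion counts sum to zero")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = (tp + tn) / counts.total
    f1 = (
        _safe_div(2 * prec * sens, prec + sens)
        if np.isfinite(prec) and np.isfinite(sens)
        else float("nan")
    )
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den != 0 else float("nan")
    if fp * fn == 0:
        dor = float("inf") if tp * tn > 0 else float("nan")
    else:
        dor = (tp * tn) / (fp * fn)

    auc = float("nan")
    if scores is not None and labels is not None:
        y = _as_binary(labels, "labels")
        if len(y) != counts.total:
            raise ValueError("labels inconsistent with confusion-count total")
        auc = auc_score(y, scores)

    if log_loss_mode == "probability":
        if scores is not None and labels is not None:
            ll = _log_loss(_as_binary(labels, "labels"), np.asarray(scores, float))
        else:
            ll = float("nan")
    elif log_loss_mode == "hard":
        # predicted class 1 contributes -log(eps) when wrong, -log(1-eps)~0 when
        # right, so the loss reduces to misclassification_rate * -log(eps)
        ll = ((fp + fn) / counts.total) * -np.log(LOG_LOSS_EPS) + (
            (tp + tn) / counts.total
        ) * -np.log(1 - LOG_LOSS_EPS)
    else:
        raise ValueError(f"unknown log_loss_mode {log_loss_mode!r}")

    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        accuracy=acc,
        f1=f1,
        mcc=float(mcc),
        auc=auc,
        log_loss=float(ll),
        dor=float(dor),
        fpr=1 - spec if np.isfinite(spec) else float("nan"),
        fnr=1 - sens if np.isfinite(sens) else float("nan"),
        log_loss_mode=log_loss_mode,
    )


def dor_from_rates(sensitivity: float, specificity: float) -> float:
    """DOR expressed through the rates: (sens/(1-sens)) * (spec/(1-spec))."""
    return (sensitivity / (1 - sensitivity)) * (specificity / (1 - specificity))


def repeated_balanced_eval(
    del_scores: Sequence[float],
    benign_pools: Mapping[str, Sequence[float]],
    n_rep: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    log_loss_mode: str = "probability",
) -> pd.DataFrame:
    """Repeated balanced evaluation against per-bin benign score pools.

    For each bin, ``n_rep`` random draws of ``len(del_scores)`` benign
    scores are taken without replacement, the metric panel is computed per
    draw, and the per-metric mean and sample standard deviation (ddof=1;
    0 when ``n_rep == 1``) are reported.  Reproducible under ``seed``.
    """
    del_scores = np.asarray(del_scores, dtype=float)
    n_del = len(del_scores)
    rows = []
    rng = np.random.default_rng(seed)
    for bin_name, pool in benign_pools.items():
        pool = np.asarray(pool, dtype=float)
        if len(pool) < n_del:
            raise ValueError(
                f"bin {bin_name!r}: benign pool of {len(pool)} smaller than "
                f"deleterious set of {n_del}"
            )
        per_rep: list[dict] = []
        for _ in range(n_rep):
            draw = pool[rng.choice(len(pool), size=n_del, replace=False)]
            scores = np.concatenate([del_scores, draw])
            labels = np.concatenate([np.ones(n_del, int), np.zeros(n_del, int)])
            classes = (scores > threshold).astype(int)
            report = metric_panel(
                confusion(labels, classes), scores, labels, log_loss_mode
            )
            per_rep.append(report.as_dict())
        rep_df = pd.DataFrame(per_rep)
        for metric in rep_df.columns:
            vals = rep_df[metric].to_numpy()
            with np.errstate(invalid="ignore"):  # sd of +-inf metrics (DOR) is NaN
                sd = float(np.std(vals, ddof=1)) if n_rep > 1 else 0.0
            rows.append(
                {"bin": bin_name, "metric": metric, "mean": float(np.mean(vals)), "sd": sd}
            )
    return pd.DataFrame(rows)


def handle_missing_scores(
    score_table: pd.DataFrame, tool_columns: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Keep rows scored by every requested tool; report per-tool missingness.

    Cross-tool comparisons are only fair on the variants every tool could
    score, so rows missing any requested column are dropped.  The report
    gives each tool's missingness as a percentage of the input rows.
    """
    report: dict[str, float] = {}
    n = len(score_table)
    mask = np.ones(n, dtype=bool)
    for col in tool_columns:
        present = score_table[col].notna().to_numpy()
        report[col] = 100.0 * (1 - present.mean()) if n else 0.0
        mask &= present
    return score_table.loc[mask].reset_index(drop=True), report


def model_concordance(classesA, classesB, labels) -> dict[str, float]:
    """Percent agreement between two classifiers' calls.

    Reported overall and stratified by the true label (concordance on
    deleterious variants, concordance on benign variants).  Strata with no
    members report NaN.
    """
    a = _as_binary(classesA, "classesA")
    b = _as_binary(classesB, "classesB")
    y = _as_binary(labels, "labels")
    if not (len(a) == len(b) == len(y)):
        raise ValueError("length mismatch among class vectors and labels")
    agree = a == b

    def _pct(mask: np.ndarray) -> float:
        return 100.0 * agree[mask].mean() if mask.any() else float("nan")

    return {
        "overall": _pct(np.ones(len(a), dtype=bool)),
        "positives": _pct(y == 1),
        "negatives": _pct(y == 0),
    }


def score_distribution_export(scores, labels, threshold: float, path) -> pd.DataFrame:
    """Long-format export (score, true class, predicted class, threshold)
    for violin/ROC plotting in external tools."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, "labels") if len(scores) else np.zeros(0, int)
    df = pd.DataFrame(
        {
            "score": scores,
            "true_class": ["deleterious" if v else "benign" for v in y],
            "predicted_class": [
                "deleterious" if s > threshold else "benign" for s in scores
            ],
            "threshold": threshold,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
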