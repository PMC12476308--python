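"""Threshold classifier on the septal RV-endocardial-third z-score.

Each patient is reduced to one scalar feature — the mean z-score over the
septal segments at depths 0.7–0.9 (the endocardial third of the RV side
of the septum) — and classified as CS when the feature is at or above a
threshold.  The threshold is chosen to maximize Youden's J
(sensitivity + specificity - 1) on the ROC curve, and its out-of-sample
performance is estimated by stratified k-fold cross-validation: the
threshold is fit on the training folds and evaluated on the held-out
fold; fold ROC curves are vertically averaged on a common FPR grid.

Predictive values translate an operating point (sensitivity, specificity)
into post-test probabilities at a given disease prevalence via Bayes'
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import StratificationError, UndefinedValueError

logger = logging.getLogger("lge_zmap")

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ROCResult:
    """Step-function ROC over all observed thresholds.

    ``thresholds`` are sorted descending from +inf to -inf; a case is
    called positive when its feature is >= the threshold, so (fpr, tpr)
    runs from (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class PredictiveValues:
    ppv: float
    npv: float
    prevalence: float


@dataclass
class CVReport:
    """Cross-validated performance of the Youden-threshold classifier."""

    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    threshold: float
    mean_sensitivity: float
    mean_specificity: float
    seed: int
    k: int
    threshold_mode: str
    fold_thresholds: list[float] = field(default_factory=list)
    mean_roc_fpr: np.ndarray | None = None
    mean_roc_tpr: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "threshold": float(self.threshold),
            "mean_sensitivity": float(self.mean_sensitivity),
            "mean_specificity": float(self.mean_specificity),
            "seed": int(self.seed),
            "k": int(self.k),
            "threshold_mode": self.threshold_mode,
            "fold_thresholds": [float(t) for t in self.fold_thresholds],
            "mean_roc": {
                "fpr": [float(v) for v in (self.mean_roc_fpr if self.mean_roc_fpr is not None else [])],
                "tpr": [float(v) for v in (self.mean_roc_tpr if self.mean_roc_tpr is not None else [])],
            },
        }


def roc_curve(features, labels) -> ROCResult:
    """ROC curve for the rule 'positive if feature >= threshold'.

    Thresholds are the sorted unique feature values plus +/- infinity;
    tied features step the curve simultaneously.  AUC is the trapezoidal
    integral of TPR over FPR, which equals the Mann-Whitney concordance
    probability (ties counted half).
    """
    f = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("features and labels must be 1-D arrays of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")
    thresholds = np.concatenate(
        [[np.inf], np.unique(f)[::-1], [-np.inf]]
    )
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pos = f >= t
        tpr[i] = (pos & (y == 1)).sum() / n_pos
        fpr[i] = (pos & (y == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def youden_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher threshold (the more specific
    operating point).  Returns (threshold, sensitivity, specificity).
    """
    j = roc.tpr - roc.fpr
    # thresholds are sorted descending, so the first maximum is the highest
    best = int(np.argmax(j))
    thr = float(roc.thresholds[best])
    if np.isinf(thr):
        # J maximized only at an endpoint (degenerate/anti-correlated data):
        # fall back to the highest finite threshold
        finite = np.isfinite(roc.thresholds)
        best = int(np.argmax(np.where(finite, j, -np.inf)))
        thr = float(roc.thresholds[best])
    jmax = float(j[best])
    if jmax <= 0:
        logger.warning(
            "Youden's J <= 0 at every threshold: feature orientation may be inverted"
        )
    return thr, float(roc.tpr[best]), float(1.0 - roc.fpr[best])


def _operating_point(features, labels, threshold: float) -> tuple[float, float]:
    f = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = f >= threshold
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    sens = float((pos & (y == 1)).sum() / n_pos) if n_pos else np.nan
    spec = float((~pos & (y == 0)).sum() / n_neg) if n_neg else np.nan
    return sens, spec


def _interp_roc(roc: ROCResult, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(roc.fpr, kind="stable")
    return np.interp(grid, roc.fpr[order], roc.tpr[order])


def cv_evaluate(
    features,
    labels,
    k: int = 5,
    seed: int = 0,
    threshold_mode: str = "full",
) -> CVReport:
    """Stratified k-fold cross-validation of the Youden-threshold rule.

    Per fold, the threshold is fit (Youden) on the training folds and the
    held-out fold provides the fold AUC and the sensitivity/specificity at
    that threshold.  The reported ``threshold`` is the full-data Youden
    threshold (``threshold_mode='full'``) or the mean of the per-fold
    thresholds (``'per-fold'``).  The mean ROC is the vertical average of
    fold ROCs on a 101-point FPR grid.

    ``k = n`` (leave-one-out) is accepted as a degenerate check: folds
    whose held-out set contains a single class contribute no fold AUC, and
    the pooled held-out AUC is used for the aggregate instead.
    """
    f = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if threshold_mode not in ("full", "per-fold"):
        raise ValueError(f"threshold_mode must be 'full' or 'per-fold', got {threshold_mode!r}")
    if k < 2 or k > n:
        raise StratificationError(f"k must be in 2..{n}, got {k}")
    loo = k == n
    if not loo and (counts < k).any():
        raise StratificationError(
            f"each class needs >= {k} members for stratified {k}-fold CV; got {counts.tolist()}"
        )

    if loo:
        splits = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(f.reshape(-1, 1), y))

    fold_aucs: list[float] = []
    fold_thresholds: list[float] = []
    senss: list[float] = []
    specs: list[float] = []
    tprs: list[np.ndarray] = []
    held_f: list[float] = []
    held_y: list[int] = []
    for train, test in splits:
        roc_tr = roc_curve(f[train], y[train])
        thr, _, _ = youden_threshold(roc_tr)
        fold_thresholds.append(thr)
        held_f.extend(f[test])
        held_y.extend(y[test])
        yt = y[test]
        if (yt == 1).any() and (yt == 0).any():
            roc_te = roc_curve(f[test], yt)
            fold_aucs.append(roc_te.auc)
            tprs.append(_interp_roc(roc_te, FPR_GRID))
        sens, spec = _operating_point(f[test], yt, thr)
        if np.isfinite(sens):
            senss.append(sens)
        if np.isfinite(spec):
            specs.append(spec)

    if fold_aucs:
        mean_auc = float(np.mean(fold_aucs))
        sd_auc = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    else:  # degenerate folds everywhere (e.g. LOO): pool held-out predictions
        mean_auc = roc_curve(np.array(held_f), np.array(held_y)).auc
        sd_auc = 0.0

    if threshold_mode == "full":
        threshold = youden_threshold(roc_curve(f, y))[0]
    else:
        threshold = float(np.mean(fold_thresholds))

    mean_tpr = np.mean(tprs, axis=0) if tprs else None
    return CVReport(
        fold_aucs=fold_aucs,
        mean_auc=mean_auc,
        sd_auc=sd_auc,
        threshold=threshold,
        mean_sensitivity=float(np.mean(senss)) if senss else np.nan,
        mean_specificity=float(np.mean(specs)) if specs else np.nan,
        seed=seed,
        k=k,
        threshold_mode=threshold_mode,
        fold_thresholds=fold_thresholds,
        mean_roc_fpr=FPR_GRID.copy() if mean_tpr is not None else None,
        mean_roc_tpr=mean_tpr,
    )


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> PredictiveValues:
    """PPV and NPV at a given prevalence, by Bayes' rule.

    PPV = se*p / (se*p + (1-sp)(1-p));
    NPV = sp*(1-p) / (sp*(1-p) + (1-se)*p).
    """
    se, sp, p = float(sensitivity), float(specificity), float(prevalence)
    for name, v in (("sensitivity", se), ("specificity", sp), ("prevalence", p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    ppv_den = se * p + (1.0 - sp) * (1.0 - p)
    npv_den = sp * (1.0 - p) + (1.0 - se) * p
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedValueError(
            "predictive value undefined: no test-positive (or test-negative) mass"
        )
    return PredictiveValues(
        ppv=se * p / ppv_den, npv=sp * (1.0 - p) / npv_den, prevalence=p
    )
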