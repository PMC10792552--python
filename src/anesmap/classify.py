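"""IES-sensitivity prediction from event delays.

A recording is *IES sensitive* when its cumulative iso-electric-suppression
duration exceeds 30 s (the regime in which a gamma rebound follows
recovery).  Event delays are mapped through the decreasing transform

    tau* = ln(1 + 100 / (delay_s + 0.1))

so that early events produce large features and the "never happened" limit
is 0, and fed to an l2-regularized logistic regression (C = 1) evaluated by
stratified group k-fold cross-validation: recordings of one subject never
split across train and validation folds, and every validation fold keeps
the cohort's class balance.  Performance is reported as ROC-AUC, pooled
over out-of-fold predictions (primary) and per fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from .params import ClassifyParams

__all__ = [
    "FEATURE_COLUMNS",
    "CVResult",
    "FoldDegeneracyError",
    "label_sensitivity",
    "normalize_feature",
    "build_feature_matrix",
    "fit_evaluate",
]


# Event-delay columns of a cohort table usable as predictors (seconds from
# induction; NaN = event absent).
FEATURE_COLUMNS = (
    "tau_theta_decay_s",
    "tau_delta_app_s",
    "tau_theta_disp_s",
    "tau_delta_disp_s",
    "tau_ies1_s",
)


class FoldDegeneracyError(ValueError):
    """A cross-validation training fold contains a single class."""


@dataclass(frozen=True)
class CVResult:
    """Cross-validated classification result."""

    features: Sequence[str]
    fold_assignments: np.ndarray
    auc_pooled: float
    auc_per_fold: List[float]
    coefficients: np.ndarray  # (n_folds, n_features)
    intercepts: np.ndarray


def label_sensitivity(delta_ies_s: float, threshold_s: float = 30.0) -> bool:
    """IES-sensitive label: cumulative IES duration strictly above 30 s."""
    if delta_ies_s < 0:
        raise ValueError("cumulative IES duration must be >= 0")
    return delta_ies_s > threshold_s


def normalize_feature(
    tau_s: Optional[float],
    tau_iso_start: float = 0.0,
    params: ClassifyParams = ClassifyParams(),
) -> float:
    """Map an event time to the dimensionless feature
    ``ln(1 + 100 / (delay + 0.1))``.

    ``tau_s`` may be an absolute event time (with ``tau_iso_start`` the
    induction time) or already a delay (with the default induction 0).
    An absent event (None/NaN) maps to 0, the infinite-delay limit of the
    transform.
    """
    if tau_s is None or (isinstance(tau_s, float) and np.isnan(tau_s)):
        return 0.0
    delay = float(tau_s) - float(tau_iso_start)
    if delay < 0:
        raise ValueError("event time precedes isoflurane onset")
    return float(np.log1p(params.norm_scale_s / (delay + params.norm_offset_s)))


def build_feature_matrix(
    cohort: pd.DataFrame,
    features: Sequence[str],
    params: ClassifyParams = ClassifyParams(),
) -> np.ndarray:
    """Normalized feature matrix from the delay columns of a cohort table."""
    unknown = [f for f in features if f not in cohort.columns]
    if unknown:
        raise ValueError(f"cohort table lacks feature columns {unknown}")
    X = np.empty((len(cohort), len(features)))
    for j, name in enumerate(features):
        col = cohort[name].to_numpy(dtype=float)
        X[:, j] = [normalize_feature(v, 0.0, params) for v in col]
    return X


def fit_evaluate(
    cohort: pd.DataFrame,
    features: Sequence[str],
    k: Optional[int] = None,
    seed: int = 0,
    params: ClassifyParams = ClassifyParams(),
) -> CVResult:
    """Stratified group k-fold logistic regression on a cohort table.

    The table needs ``subject_id`` and ``delta_ies_s`` columns plus the
    requested delay columns.  Folds group by subject and stratify by the
    sensitivity label; a training fold with a single class raises
    :class:`FoldDegeneracyError`.  Deterministic for a fixed seed.
    """
    k = params.n_folds if k is None else k
    y = np.array([label_sensitivity(v, params.ies_sensitive_thr_s) for v in cohort["delta_ies_s"]])
    if y.all() or not y.any():
        raise FoldDegeneracyError("cohort contains a single class")
    X = build_feature_matrix(cohort, features, params)
    groups = cohort["subject_id"].to_numpy()

    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.full(len(cohort), -1, dtype=int)
    oof = np.full(len(cohort), np.nan)
    aucs: List[float] = []
    coefs = np.zeros((k, len(features)))
    intercepts = np.zeros(k)
    for fold, (tr, va) in enumerate(cv.split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise FoldDegeneracyError(f"training split of fold {fold} has a single class")
        # l2 penalty (the solver default) with regularization constant C
        model = LogisticRegression(
            C=params.C,
            solver="lbfgs",
            tol=params.tol,
            max_iter=params.max_iter,
        )
        model.fit(X[tr], y[tr])
        prob = model.predict_proba(X[va])[:, 1]
        oof[va] = prob
        fold_of[va] = fold
        coefs[fold] = model.coef_[0]
        intercepts[fold] = model.intercept_[0]
        if len(np.unique(y[va])) == 2:
            aucs.append(float(roc_auc_score(y[va], prob)))
        else:
            aucs.append(float("nan"))
    pooled = float(roc_auc_score(y, oof))
    return CVResult(
        features=tuple(features),
        fold_assignments=fold_of,
        auc_pooled=pooled,
        auc_per_fold=aucs,
        coefficients=coefs,
        intercepts=intercepts,
    )
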