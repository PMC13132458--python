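"""Random-forest association scoring and Youden-index thresholding.

Association probability for a candidate pair is the forest's soft vote: the
average over trees of the per-tree positive-class probability, so scores live
in [0, 1] and support ranking metrics.  Scores become binary calls at the
threshold maximizing Youden's J = TPR - FPR, selected on training-fold scores
only and applied unchanged to test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ddacl.errors import ConfigurationError, InputError, ThresholdError


@dataclass
class ForestConfig:
    """Forest hyperparameters; defaults are the tuned benchmark values."""

    n_estimators: int = 250
    max_depth: int = 25
    min_samples_split: int = 5
    min_samples_leaf: int = 2
    max_features: str | float = "sqrt"
    class_weight: str | None = "balanced"
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigurationError("max_depth must be positive")
        if self.min_samples_split < 2 or self.min_samples_leaf < 1:
            raise ConfigurationError("min-sample settings must be positive")


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    feature_dim: int
    config: ForestConfig


def fit_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> ForestModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("X must be 2-D with one row per label")
    bad = np.where(~np.all(np.isfinite(X), axis=1))[0]
    if bad.size:
        raise InputError(f"non-finite features in rows {bad[:10].tolist()}")
    if len(np.unique(y)) < 2:
        raise InputError("forest fitting requires samples of both classes")
    max_features = cfg.max_features if cfg.max_features != "all" else None
    est = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        min_samples_split=cfg.min_samples_split,
        min_samples_leaf=cfg.min_samples_leaf,
        max_features=max_features,
        class_weight=cfg.class_weight if cfg.class_weight != "none" else None,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return ForestModel(estimator=est, feature_dim=X.shape[1], config=cfg)


def predict_scores(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Soft-vote scores in [0, 1]: mean positive-class probability over trees."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise InputError(
            f"probe features must have {model.feature_dim} columns, got shape {X.shape}")
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    return model.estimator.predict_proba(X)[:, pos_col]


@dataclass
class ThresholdResult:
    theta_star: float
    J_star: float
    tpr_at: float
    fpr_at: float


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus +/-inf sentinels."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> ThresholdResult:
    """Threshold maximizing J = TPR - FPR under the 'score >= theta' rule.

    Candidates are all midpoints of adjacent distinct scores plus sentinels;
    ties in J are broken toward the smallest threshold (favors sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ThresholdError("threshold selection requires both classes present")
    thetas = _candidate_thresholds(scores)
    pred = scores[None, :] >= thetas[:, None]  # (T, n)
    tpr = (pred & (labels == 1)).sum(axis=1) / n_pos
    fpr = (pred & (labels == 0)).sum(axis=1) / n_neg
    J = tpr - fpr
    best = int(np.argmax(J))  # argmax takes the first max; thetas ascend
    return ThresholdResult(theta_star=float(thetas[best]), J_star=float(J[best]),
                           tpr_at=float(tpr[best]), fpr_at=float(fpr[best]))


def binarize(scores: np.ndarray, theta: float) -> np.ndarray:
    """Binary calls: 1 iff score >= theta (closed at theta)."""
    return (np.asarray(scores, dtype=float) >= theta).astype(int)
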