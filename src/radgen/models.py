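"""Model fitting and the four evaluation metrics.

Two model families are supported — penalized logistic regression and
gradient-boosted trees — both returning probabilities.  Standardization
statistics always come from the training fold only.  Metrics: AUC
(Mann-Whitney with half-credit ties), Brier score, Nagelkerke pseudo-R²,
and Youden's J maximized over thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ModelSpec:
    family: str = "logistic_regression"  # or "gradient_boosted_trees"
    C: float = 1.0  # LR inverse penalty strength
    penalty: str = "l2"
    n_estimators: int = 100
    max_depth: int = 2
    learning_rate: float = 0.1
    subsample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("logistic_regression", "gradient_boosted_trees"):
            raise ValueError(f"unknown family {self.family!r}")
        if not np.isfinite([self.C, self.learning_rate, self.subsample]).all():
            raise ValueError("non-finite hyperparameters")


@dataclass
class MetricSet:
    auc: float
    brier: float
    nagelkerke_r2: float
    youden_j: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0 <= self.auc <= 1 and 0 <= self.brier <= 1):
            raise ValueError("auc and brier must be in [0,1]")
        if not (0 <= self.nagelkerke_r2 <= 1):
            raise ValueError("nagelkerke_r2 must be in [0,1]")
        if not (-1 <= self.youden_j <= 1):
            raise ValueError("youden_j must be in [-1,1]")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    estimator: object = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean_) / self.scale_
        p = self.estimator.predict_proba(Xs)[:, 1]
        return np.clip(p, 1e-12, 1 - 1e-12)


def fit_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
              feature_names: list[str] | None = None) -> FittedModel:
    """Fit on training data; standardization uses these rows only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if X.shape[0] < 20:
        raise ValueError("need >= 20 training samples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    if spec.family == "logistic_regression":
        kwargs = {}
        if spec.penalty == "l1":
            kwargs = {"penalty": "l1", "solver": "liblinear"}
        est = LogisticRegression(
            C=spec.C, max_iter=2000, random_state=spec.seed, **kwargs
        )
    else:
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=spec.n_estimators,
            max_depth=spec.max_depth,
            learning_rate=spec.learning_rate,
            subsample=spec.subsample,
            random_state=spec.seed,
            tree_method="hist",
            n_jobs=1,
            eval_metric="logloss",
        )
    est.fit(Xs, y)
    names = feature_names if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    return FittedModel(spec=spec, feature_names=list(names), mean_=mean,
                       scale_=scale, estimator=est)


# ------------------------------------------------------------------ metrics


def auc_score(y: np.ndarray, p: np.ndarray) -> float:
    """AUC = Mann-Whitney pair counting with half credit for ties."""
    return float(roc_auc_score(y, p))


def brier_score(y: np.ndarray, p: np.ndarray) -> float:
    return float(np.mean((np.asarray(p, float) - np.asarray(y, float)) ** 2))


def nagelkerke_r2(y: np.ndarray, p: np.ndarray) -> float:
    """(1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)) with the prevalence-only null."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    n = len(y)
    prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll1 = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    ll0 = np.sum(y * np.log(prev) + (1 - y) * np.log(1 - prev))
    cs = 1.0 - np.exp(2.0 / n * (ll0 - ll1))
    max_cs = 1.0 - np.exp(2.0 / n * ll0)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cs / max_cs, 0.0, 1.0))


def youden_j(y: np.ndarray, p: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(y, p)
    return float(np.max(tpr - fpr))


def compute_metrics(p: np.ndarray, y: np.ndarray) -> MetricSet:
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0,1]")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    return MetricSet(
        auc=auc_score(y, p),
        brier=brier_score(y, p),
        nagelkerke_r2=nagelkerke_r2(y, p),
        youden_j=youden_j(y, p),
        n_samples=len(y),
    )
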