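"""RBF-SVM classification, hyperparameter search and evaluation metrics.

The metric set (Sn, Sp, Acc, MCC) is expressed in terms of the four counts
N+ (real positives), N- (real negatives), N-+ (positives predicted
negative) and N+- (negatives predicted positive):

    Sn  = 1 - N-+ / N+
    Sp  = 1 - N+- / N-
    Acc = 1 - (N-+ + N+-) / (N+ + N-)
    MCC = (1 - (N-+/N+ + N+-/N-))
          / sqrt((1 + (N+- - N-+)/N+) * (1 + (N-+ - N+-)/N-))

This MCC form is algebraically identical to the textbook
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) wherever both are
defined; when a square-root factor vanishes (all samples predicted into
one class) the MCC is flagged undefined rather than extrapolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from pressc.features import FeatureVector, PsesscParams

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "SvmConfig",
    "ConfusionCounts",
    "MetricsResult",
    "ModelBundle",
    "CvResult",
    "EvaluationError",
    "metrics_from_counts",
    "train",
    "predict",
    "grid_search",
    "cross_validate",
    "default_param_grid",
    "default_svm_grid",
    "PRESETS",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Human-readable prediction labels, matching the published service output.
POSITIVE_LABEL = "Real Pre-miRNA"
NEGATIVE_LABEL = "False Pre-miRNA"


class EvaluationError(ValueError):
    """Invalid classification or evaluation input."""


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters."""

    C: float = 8.0
    gamma: float = 2.0 ** -5

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise EvaluationError(f"C and gamma must be > 0, got C={self.C} gamma={self.gamma}")


#: Published optimal configurations for the two predictor variants.
PRESETS: dict[str, tuple[PsesscParams, SvmConfig]] = {
    "pressc": (PsesscParams(n=2, lam=13, w=0.5), SvmConfig(C=8.0, gamma=2.0 ** -5)),
    "expressc": (PsesscParams(n=1, lam=17, w=0.2), SvmConfig(C=128.0, gamma=2.0 ** -7)),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """The four counts behind the metric formulas."""

    n_pos: int
    n_neg: int
    fn: int  # positives predicted negative (N-+)
    fp: int  # negatives predicted positive (N+-)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise EvaluationError(
                f"need at least one sample per class, got N+={self.n_pos} N-={self.n_neg}"
            )
        if not 0 <= self.fn <= self.n_pos:
            raise EvaluationError(f"fn={self.fn} out of range [0, {self.n_pos}]")
        if not 0 <= self.fp <= self.n_neg:
            raise EvaluationError(f"fp={self.fp} out of range [0, {self.n_neg}]")


@dataclass(frozen=True)
class MetricsResult:
    sn: float
    sp: float
    acc: float
    mcc: Optional[float]  # None when undefined (a sqrt factor is zero)


def metrics_from_counts(c: ConfusionCounts) -> MetricsResult:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)
    factor_pos = 1.0 + (c.fp - c.fn) / c.n_pos
    factor_neg = 1.0 + (c.fn - c.fp) / c.n_neg
    if factor_pos <= 0 or factor_neg <= 0 or factor_pos * factor_neg == 0:
        logger.warning("MCC undefined for counts %s (zero factor under the root)", c)
        mcc: Optional[float] = None
    else:
        mcc = (1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)) / math.sqrt(factor_pos * factor_neg)
    return MetricsResult(sn=sn, sp=sp, acc=acc, mcc=mcc)


class _MinMaxColumns:
    """Per-column linear scaling to [-1, 1] fitted on training data.

    Constant columns map to 0 so unseen data cannot blow up.
    """

    def fit(self, X: np.ndarray) -> "_MinMaxColumns":
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        span = self.hi_ - self.lo_
        self.span_ = np.where(span == 0, 1.0, span)
        self.constant_ = span == 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        scaled = 2.0 * (X - self.lo_) / self.span_ - 1.0
        scaled[:, self.constant_] = 0.0
        return scaled


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: SVM, scaling, parameters."""

    svm: SVC
    scaler: _MinMaxColumns
    config: SvmConfig
    feature_kind: str
    params: PsesscParams
    n_features: int
    status_convention: str = "own-first"
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def _stack(features: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    if not features:
        raise EvaluationError("no feature vectors supplied")
    dim = len(features[0].values)
    for v in features[1:]:
        if len(v.values) != dim:
            raise EvaluationError(
                f"feature dimension mismatch: {v.record_id!r} has {len(v.values)}, "
                f"expected {dim}"
            )
    X = np.vstack([v.values for v in features])
    y = np.array([1 if v.label == "positive" else 0 for v in features])
    return X, y


def train(features: Sequence[FeatureVector], cfg: SvmConfig, seed: int = 0) -> ModelBundle:
    """Fit the [-1,1] column scaling and an RBF-SVM on labeled vectors."""
    X, y = _stack(features)
    if len(np.unique(y)) < 2:
        raise EvaluationError("training data must contain both classes")
    scaler = _MinMaxColumns().fit(X)
    svm = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf", random_state=seed)
    svm.fit(scaler.transform(X), y)
    first = features[0]
    return ModelBundle(
        svm=svm,
        scaler=scaler,
        config=cfg,
        feature_kind=first.kind,
        params=first.params,
        n_features=X.shape[1],
        seed=seed,
    )


def predict(
    model: ModelBundle, features: Sequence[FeatureVector]
) -> tuple[list[str], np.ndarray]:
    """Label records and return signed decision values (positive => real)."""
    if not features:
        return [], np.empty(0)
    X, _ = _stack(features)
    if X.shape[1] != model.n_features:
        raise EvaluationError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}"
        )
    Xs = model.scaler.transform(X)
    scores = model.svm.decision_function(Xs)
    raw = model.svm.predict(Xs)
    labels = [POSITIVE_LABEL if p == 1 else NEGATIVE_LABEL for p in raw]
    return labels, scores


def save_model(model: ModelBundle, path: str) -> None:
    joblib.dump(model, path)


def load_model(path: str) -> ModelBundle:
    bundle = joblib.load(path)
    if not isinstance(bundle, ModelBundle):
        raise EvaluationError(f"{path!r} does not contain a model bundle")
    return bundle


def _roc_and_auc(y: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC polygon from sorted decision values; AUC by the rank statistic.

    Tied scores receive half credit, which makes the rank AUC equal the
    trapezoidal area under the tie-aware ROC polygon.
    """
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if y[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j

    pos_scores = scores[y == 1]
    neg_scores = scores[y == 0]
    wins = (pos_scores[:, None] > neg_scores[None, :]).sum()
    ties = (pos_scores[:, None] == neg_scores[None, :]).sum()
    auc = (wins + 0.5 * ties) / (n_pos * n_neg)
    return points, float(auc)


@dataclass
class CvResult:
    counts: ConfusionCounts
    metrics: MetricsResult
    roc_points: list[tuple[float, float]]
    auc: float
    decision_values: dict[str, float]


def _fold_indices(y: np.ndarray, scheme: str, k: Optional[int], seed: int):
    n = len(y)
    if scheme == "jackknife":
        return LeaveOneOut().split(np.zeros(n))
    if scheme == "kfold":
        if k is None or k < 2 or k > n:
            raise EvaluationError(f"k must lie in [2, {n}], got {k}")
        if k == n:
            return LeaveOneOut().split(np.zeros(n))
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros(n), y
        )
    raise EvaluationError(f"unknown cross-validation scheme {scheme!r}")


def cross_validate(
    features: Sequence[FeatureVector],
    cfg: SvmConfig,
    scheme: str = "jackknife",
    k: Optional[int] = None,
    seed: int = 0,
) -> CvResult:
    """Score every sample with a model trained without it.

    Column scaling is refitted inside each training split so no held-out
    information leaks into the scaler. Confusion counts are aggregated over
    all held-out predictions; ROC/AUC come from the pooled decision values.
    """
    X, y = _stack(features)
    if len(np.unique(y)) < 2:
        raise EvaluationError("cross-validation requires both classes")
    ids = [v.record_id for v in features]

    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    for train_idx, test_idx in _fold_indices(y, scheme, k, seed):
        if len(np.unique(y[train_idx])) < 2:
            raise EvaluationError("a training split lost one class entirely")
        scaler = _MinMaxColumns().fit(X[train_idx])
        svm = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf")
        svm.fit(scaler.transform(X[train_idx]), y[train_idx])
        Xt = scaler.transform(X[test_idx])
        scores[test_idx] = svm.decision_function(Xt)
        preds[test_idx] = svm.predict(Xt)

    counts = ConfusionCounts(
        n_pos=int(y.sum()),
        n_neg=int((y == 0).sum()),
        fn=int(((y == 1) & (preds == 0)).sum()),
        fp=int(((y == 0) & (preds == 1)).sum()),
    )
    roc, auc = _roc_and_auc(y, scores)
    return CvResult(
        counts=counts,
        metrics=metrics_from_counts(counts),
        roc_points=roc,
        auc=auc,
        decision_values=dict(zip(ids, scores.tolist())),
    )


def default_param_grid() -> list[PsesscParams]:
    """The published tuning grid: n in 1..4, lam in 1..20, w over the
    10-point grid 0.1..1.0 — 800 cells as counted in the source protocol.
    (An 11-point w-grid including 0 is available via ``w_values``.)
    """
    return [
        PsesscParams(n=n, lam=lam, w=round(w * 0.1, 10))
        for n in range(1, 5)
        for lam in range(1, 21)
        for w in range(1, 11)
    ]


def default_svm_grid() -> list[SvmConfig]:
    """Conventional exponential (C, gamma) grid: C = 2^-5..2^15, gamma =
    2^-15..2^3, both stepping by a factor of 4."""
    return [
        SvmConfig(C=2.0 ** ec, gamma=2.0 ** eg)
        for ec in range(-5, 16, 2)
        for eg in range(-15, 4, 2)
    ]


@dataclass(frozen=True)
class GridCell:
    params: PsesscParams
    config: SvmConfig
    accuracy: float


def _cell_key(cell: GridCell):
    # Deterministic tie-breaking: highest accuracy, then smaller lam, n, w, C, gamma.
    p, c = cell.params, cell.config
    return (-cell.accuracy, p.lam, p.n, p.w, c.C, c.gamma)


def grid_search(
    featurize: Callable[[PsesscParams], Sequence[FeatureVector]],
    param_grid: Optional[Iterable[PsesscParams]] = None,
    svm_grid: Optional[Iterable[SvmConfig]] = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[PsesscParams, SvmConfig, list[GridCell]]:
    """Exhaustive (n, lam, w) x (C, gamma) search by stratified k-fold accuracy.

    ``featurize`` regenerates the feature vectors for each parameter cell.
    Cells whose ``lam`` is infeasible for the data (lam >= shortest
    sequence) are skipped with a warning rather than aborting the search.
    """
    param_grid = list(param_grid) if param_grid is not None else default_param_grid()
    svm_grid = list(svm_grid) if svm_grid is not None else default_svm_grid()
    if not param_grid or not svm_grid:
        raise EvaluationError("empty search grid")

    cells: list[GridCell] = []
    for params in param_grid:
        try:
            vectors = list(featurize(params))
        except Exception as exc:  # infeasible cell (e.g. lam >= L)
            logger.warning("skipping grid cell %s: %s", params, exc)
            continue
        X, y = _stack(vectors)
        for cfg in svm_grid:
            correct = 0
            for train_idx, test_idx in _fold_indices(y, "kfold", folds, seed):
                scaler = _MinMaxColumns().fit(X[train_idx])
                svm = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf")
                svm.fit(scaler.transform(X[train_idx]), y[train_idx])
                correct += int(
                    (svm.predict(scaler.transform(X[test_idx])) == y[test_idx]).sum()
                )
            cells.append(GridCell(params=params, config=cfg, accuracy=correct / len(y)))

    if not cells:
        raise EvaluationError("every grid cell was infeasible for the supplied data")
    best = min(cells, key=_cell_key)
    return best.params, best.config, cells


def clone_with_metadata(model: ModelBundle, **meta) -> ModelBundle:
    return replace(model, metadata={**model.metadata, **meta})
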