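"""RBF-SVM model construction and evaluation for MIEC matrices.

The central object is :class:`MIECSVMClassifier`, a scikit-learn compatible
estimator that reproduces the model-construction protocol: an exhaustive
(c, gamma) grid on a base-2 exponent lattice (c exponent in [-2, 10], gamma
exponent in [-10, 2], spacing 0.5, i.e. 25 x 25 = 625 cells), each cell
scored by the mean Matthews correlation coefficient over 5 seeded stratified
cross-validation folds, with the inhibitor class up-weighted by 1.2 to
compensate the ~1:20 class imbalance.  The best cell (ties to smaller cost,
then smaller gamma — the smoother model) is refit on the full training data
with probability calibration.

Evaluation utilities implement the confusion-matrix metrics (sensitivity,
specificity, class prediction accuracies, MCC), ROC/AUC, and the enrichment
"inflection point": the true-positive rate at a 1% false-positive rate,
i.e. at the threshold admitting floor(0.01 * n_negatives) false positives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .miec import MIECMatrix

__all__ = [
    "GridConfig",
    "TrainConfig",
    "MetricsReport",
    "GridSearchResult",
    "ROCCurve",
    "MIECSVMClassifier",
    "stratified_half_split",
    "grid_search",
    "confusion_metrics",
    "metrics_from_predictions",
    "predict_probability",
    "roc_from_scores",
    "inflection_point",
    "allowed_false_positives",
    "default_parameter_model",
    "cv_mean_mcc",
]


def _exponent_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    return np.round(grid, 10)


@dataclass
class GridConfig:
    """Base-2 exponent lattice for the (cost, gamma) search."""

    c_min: float = -2.0
    c_max: float = 10.0
    gamma_min: float = -10.0
    gamma_max: float = 2.0
    step: float = 0.5
    base: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.c_max < self.c_min or self.gamma_max < self.gamma_min:
            raise ValueError("exponent ranges must be non-empty")

    def c_exponents(self) -> np.ndarray:
        return _exponent_grid(self.c_min, self.c_max, self.step)

    def gamma_exponents(self) -> np.ndarray:
        return _exponent_grid(self.gamma_min, self.gamma_max, self.step)

    @classmethod
    def coarse(cls, step: float = 2.0) -> "GridConfig":
        """Same exponent ranges on a coarser lattice (desk-scale runs)."""
        return cls(step=step)


@dataclass
class TrainConfig:
    positive_class_weight: float = 1.2
    cv_folds: int = 5
    selection_metric: str = "mcc"
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class MetricsReport:
    """Confusion-matrix metrics; undefined ratios are None and flagged."""

    TP: int
    FP: int
    TN: int
    FN: int
    SE: float | None = field(init=False)
    SP: float | None = field(init=False)
    Q_plus: float | None = field(init=False)
    Q_minus: float | None = field(init=False)
    MCC: float | None = field(init=False)
    undefined: list[str] = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.TP, self.FP, self.TN, self.FN
        undefined: list[str] = []

        def ratio(num, den, name):
            if den == 0:
                undefined.append(name)
                return None
            return num / den

        self.SE = ratio(tp, tp + fn, "SE")
        self.SP = ratio(tn, tn + fp, "SP")
        self.Q_plus = ratio(tp, tp + fp, "Q_plus")
        self.Q_minus = ratio(tn, tn + fn, "Q_minus")
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            undefined.append("MCC")
            self.MCC = None
        else:
            self.MCC = (tp * tn - fp * fn) / math.sqrt(denom)
        self.undefined = undefined
        if undefined:
            warnings.warn(
                f"zero denominator: metric(s) {undefined} undefined", stacklevel=3
            )


@dataclass
class GridSearchResult:
    c_exponents: np.ndarray
    gamma_exponents: np.ndarray
    cv_mean_mcc: np.ndarray  # len(c) x len(gamma)
    best_c_exp: float
    best_gamma_exp: float
    best_mcc: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"c_exp": c, "gamma_exp": g, "cv_mean_mcc": self.cv_mean_mcc[i, j]}
            for i, c in enumerate(self.c_exponents)
            for j, g in enumerate(self.gamma_exponents)
        ]
        return pd.DataFrame(rows)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _fold_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


class MIECSVMClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched RBF-SVM over MIEC features.

    Parameters
    ----------
    grid : GridConfig or None
        Exponent lattice searched during fit; None means the default
        625-cell grid.
    cv_folds : int
        Stratified cross-validation folds used to score each grid cell.
    positive_class_weight : float
        Misclassification-cost multiplier for the inhibitor (+1) class.
    base : float
        Base of the exponent lattice (cost = base**c_exp etc.).
    probability : bool
        Calibrate class probabilities on the refit model.
    random_state : int or None
        Seeds the CV shuffling and probability calibration; the same seed
        reproduces every cell MCC bit-identically.

    Attributes (after fit)
    ----------------------
    best_c_exp_, best_gamma_exp_, best_mcc_ : selected grid cell.
    grid_result_ : GridSearchResult with the full MCC surface.
    estimator_ : the refit SVC.
    classes_ : array([-1, 1]).
    """

    def __init__(
        self,
        grid: GridConfig | None = None,
        cv_folds: int = 5,
        positive_class_weight: float = 1.2,
        base: float = 2.0,
        probability: bool = True,
        random_state: int | None = 0,
    ):
        self.grid = grid
        self.cv_folds = cv_folds
        self.positive_class_weight = positive_class_weight
        self.base = base
        self.probability = probability
        self.random_state = random_state

    def _make_svc(self, c_exp: float, gamma_exp: float, probability: bool) -> SVC:
        return SVC(
            kernel="rbf",
            C=self.base**c_exp,
            gamma=self.base**gamma_exp,
            class_weight={1: self.positive_class_weight},
            probability=probability,
            random_state=self.random_state,
        )

    @staticmethod
    def _fit_svc(clf: SVC, X, y) -> SVC:
        # libsvm's built-in Platt calibration (probability=True) is the
        # protocol's probability source; newer sklearn deprecates the flag in
        # favour of CalibratedClassifierCV, so silence that advice at fit time.
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            clf.fit(X, y)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +1 (inhibitor) / -1 (non-inhibitor)")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to train")

        grid = self.grid if self.grid is not None else GridConfig()
        c_exps = grid.c_exponents()
        g_exps = grid.gamma_exponents()

        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(X, y))

        surface = np.empty((len(c_exps), len(g_exps)))
        for i, ce in enumerate(c_exps):
            for j, ge in enumerate(g_exps):
                mccs = []
                for tr, va in folds:
                    if len(np.unique(y[tr])) < 2:
                        warnings.warn("degenerate single-class fold; MCC := 0")
                        mccs.append(0.0)
                        continue
                    clf = self._make_svc(ce, ge, probability=False)
                    self._fit_svc(clf, X[tr], y[tr])
                    mccs.append(_fold_mcc(y[va], clf.predict(X[va])))
                surface[i, j] = float(np.mean(mccs))

        best_flat = np.argmax(surface)  # first occurrence = smaller c, then gamma
        bi, bj = np.unravel_index(best_flat, surface.shape)
        self.grid_result_ = GridSearchResult(
            c_exponents=c_exps,
            gamma_exponents=g_exps,
            cv_mean_mcc=surface,
            best_c_exp=float(c_exps[bi]),
            best_gamma_exp=float(g_exps[bj]),
            best_mcc=float(surface[bi, bj]),
        )
        self.best_c_exp_ = self.grid_result_.best_c_exp
        self.best_gamma_exp_ = self.grid_result_.best_gamma_exp
        self.best_mcc_ = self.grid_result_.best_mcc

        self.estimator_ = self._make_svc(
            self.best_c_exp_, self.best_gamma_exp_, probability=self.probability
        )
        self._fit_svc(self.estimator_, X, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature-dimension mismatch: fitted with "
                f"{self.n_features_in_}, got {X.shape[1]}"
            )
        return X

    def predict(self, X):
        return self.estimator_.predict(self._check_X(X))

    def decision_function(self, X):
        return self.estimator_.decision_function(self._check_X(X))

    def predict_proba(self, X):
        if not self.probability:
            raise AttributeError("fit with probability=True for predict_proba")
        return self.estimator_.predict_proba(self._check_X(X))

    def inhibitor_probability(self, X) -> np.ndarray:
        """P(inhibitor), i.e. the +1-class column of predict_proba."""
        proba = self.predict_proba(X)
        col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, col]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def stratified_half_split(
    matrix: MIECMatrix, cfg: TrainConfig
) -> tuple[MIECMatrix, MIECMatrix]:
    """Seeded stratified split into training and test halves.

    Within each class the samples are shuffled and split; odd class counts
    put the extra sample in the training half.  Union is the input, the
    intersection empty, and a fixed seed reproduces the split exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (1, -1):
        idx = np.flatnonzero(matrix.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_train = math.ceil(len(idx) * cfg.split_fraction)
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(test_idx))


def grid_search(
    train: MIECMatrix, grid: GridConfig, cfg: TrainConfig
) -> tuple[GridSearchResult, MIECSVMClassifier]:
    """Run the protocol's grid search; returns the surface and refit model."""
    clf = MIECSVMClassifier(
        grid=grid,
        cv_folds=cfg.cv_folds,
        positive_class_weight=cfg.positive_class_weight,
        random_state=cfg.seed,
    )
    clf.fit(train.features, train.labels)
    return clf.grid_result_, clf


def confusion_metrics(TP: int, FP: int, TN: int, FN: int) -> MetricsReport:
    """SE, SP, Q+, Q- and MCC from raw confusion counts."""
    return MetricsReport(TP=TP, FP=FP, TN=TN, FN=FN)


def metrics_from_predictions(y_true, y_pred) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return confusion_metrics(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def predict_probability(model: MIECSVMClassifier, X) -> np.ndarray:
    """Per-sample inhibitor probability in [0, 1]."""
    return model.inhibitor_probability(X)


def roc_from_scores(scores, labels) -> ROCCurve:
    """ROC curve and trapezoidal AUC from inhibitor scores and +-1 labels."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float), pos_label=1)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def allowed_false_positives(negatives_total: int, fpr: float = 0.01) -> int:
    """False positives admitted at the given FPR: floor(fpr * n_negatives)."""
    if negatives_total <= 0:
        raise ValueError("negatives_total must be positive")
    return int(math.floor(fpr * negatives_total))


def inflection_point(roc: ROCCurve, negatives_total: int, fpr: float = 0.01) -> float:
    """TPR at the threshold admitting floor(fpr * n_negatives) false positives."""
    n_fp = allowed_false_positives(negatives_total, fpr)
    fpr_cut = n_fp / negatives_total
    ok = roc.fpr <= fpr_cut + 1e-12
    if not ok.any():
        return 0.0
    return float(roc.tpr[ok].max())


def default_parameter_model(
    train: MIECMatrix, cfg: TrainConfig
) -> MIECSVMClassifier:
    """Baseline model at the library defaults: cost 2^0 = 1, gamma = 1/n_features.

    Built as a single-cell grid so the fitted object carries the same
    interface (and CV MCC) as the tuned models.
    """
    n_features = train.features.shape[1]
    gamma_exp = math.log2(1.0 / n_features)
    grid = GridConfig(
        c_min=0.0, c_max=0.0, gamma_min=gamma_exp, gamma_max=gamma_exp, step=1.0
    )
    clf = MIECSVMClassifier(
        grid=grid,
        cv_folds=cfg.cv_folds,
        positive_class_weight=cfg.positive_class_weight,
        random_state=cfg.seed,
    )
    clf.fit(train.features, train.labels)
    return clf


def cv_mean_mcc(
    X, y, c_exp: float, gamma_exp: float, cfg: TrainConfig
) -> float:
    """Mean MCC of one (c, gamma) cell over the seeded stratified folds."""
    grid = GridConfig(
        c_min=c_exp, c_max=c_exp, gamma_min=gamma_exp, gamma_max=gamma_exp, step=1.0
    )
    clf = MIECSVMClassifier(
        grid=grid,
        cv_folds=cfg.cv_folds,
        positive_class_weight=cfg.positive_class_weight,
        probability=False,
        random_state=cfg.seed,
    )
    clf.fit(X, y)
    return clf.best_mcc_
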