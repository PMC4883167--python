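"""Max-margin classification of texture feature vectors, with an optional
homogeneous chi-squared feature map, and stratified k-fold evaluation.

Two solver families are supported:

* ``kernel-svm`` — a kernel SVM (linear, polynomial, or histogram
  intersection ``k(x, y) = sum_d min(x_d, y_d)``);
* ``linear-primal`` — a LIBLINEAR-style primal linear SVM with squared-hinge
  loss and either an L2 or L1 penalty.

The homogeneous map turns the additive chi-squared kernel

    k(x, y) = sum_d 2 x_d y_d / (x_d + y_d)

into an explicit finite feature expansion so the fast linear solver emulates
the kernel machine. For the chi-squared kernel the signature has the closed
form ``kappa(lambda) = sech(pi * lambda)``; sampling it at period L up to
order n expands every nonnegative component x into 2n + 1 values

    [ sqrt(x L),
      sqrt(2 x L kappa(jL)) cos(jL log x),
      sqrt(2 x L kappa(jL)) sin(jL log x) ]   for j = 1..n,

with x = 0 mapping to zeros. Evaluation metrics are the usual confusion
ratios, reported in percent: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/(TP+TN+FP+FN). Folds are stratified and shuffled with an
explicit seed; aggregate metrics pool the confusion counts over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from sklearn.svm import SVC, LinearSVC

from .errors import ParameterError, TrainingError

POSITIVE_LABEL = "seizure"
NEGATIVE_LABEL = "normal"


# ---------------------------------------------------------------------------
# homogeneous chi-squared feature map


def _chi2_kappa(lam):
    """Closed-form spectrum of the additive chi-squared kernel."""
    return 1.0 / np.cosh(np.pi * np.asarray(lam, dtype=float))


def _diag_gain(order: int, period: float) -> float:
    """<Psi(x), Psi(x)> / k(x, x); exactly 1 means the map preserves norms."""
    j = np.arange(1, order + 1)
    return period * (1.0 + 2.0 * _chi2_kappa(j * period).sum())


def _auto_period(order: int) -> float:
    """Period making the map exact on the diagonal (k(x, x) preserved)."""
    return brentq(lambda L: _diag_gain(order, L) - 1.0, 1e-3, 3.0)


def chi2_feature_map(x: np.ndarray, order: int = 1, period: float | None = None) -> np.ndarray:
    """Expand nonnegative features so inner products approximate the
    additive chi-squared kernel.

    Each input component becomes ``2 * order + 1`` output components. The
    default period is 0.65 at order 1 (the common choice for this map);
    for higher orders an unspecified period is solved so that ``k(x, x)``
    is reproduced exactly.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ParameterError("order must be >= 1")
    if np.any(x < 0):
        raise ParameterError(
            "chi-squared map needs nonnegative inputs; scale features first"
        )
    if period is None:
        period = 0.65 if order == 1 else _auto_period(order)

    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    n, d = X.shape
    out = np.zeros((n, d, 2 * order + 1))
    nz = X > 0
    Xnz = X[nz]
    out[..., 0][nz] = np.sqrt(Xnz * period)
    log_x = np.log(Xnz)
    for j in range(1, order + 1):
        amp = np.sqrt(2.0 * Xnz * period * _chi2_kappa(j * period))
        out[..., 2 * j - 1][nz] = amp * np.cos(j * period * log_x)
        out[..., 2 * j][nz] = amp * np.sin(j * period * log_x)
    out = out.reshape(n, d * (2 * order + 1))
    return out[0] if squeeze else out


def chi2_kernel_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Additive chi-squared kernel, the quantity the map approximates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, 2.0 * x * y / np.where(s > 0, s, 1.0), 0.0)
    return float(terms.sum())


def intersection_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Histogram intersection Gram matrix, computed row-blockwise."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    K = np.empty((X.shape[0], Y.shape[0]))
    for i, row in enumerate(X):
        K[i] = np.minimum(row, Y).sum(axis=1)
    return K


# ---------------------------------------------------------------------------
# classifier configuration and model


@dataclass
class ClassifierConfig:
    """Solver, kernel and preprocessing choices for one experiment."""

    solver: str = "kernel-svm"  # or "linear-primal"
    kernel: str = "linear"  # linear | polynomial | intersection | none
    C: float = 1.0
    penalty: str = "l2"  # l2 (L2-reg L2-loss) or l1 (L1-reg L2-loss)
    homogeneous_map: tuple | None = None  # (order, period-or-None)
    scaling: str = "minmax01"  # or "none"
    poly_degree: int = 3
    poly_coef0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ParameterError("C must be > 0")
        if self.solver not in ("kernel-svm", "linear-primal"):
            raise ParameterError(f"unknown solver {self.solver!r}")
        if self.penalty not in ("l1", "l2"):
            raise ParameterError(f"unknown penalty {self.penalty!r}")
        if self.scaling not in ("minmax01", "none"):
            raise ParameterError(f"unknown scaling {self.scaling!r}")


#: Named configurations for the three descriptor families.
PRESETS = {
    "glcm-svm": ClassifierConfig(solver="kernel-svm", kernel="linear", C=100.0),
    "glcm-liblinear": ClassifierConfig(solver="linear-primal", penalty="l2", C=0.07),
    "glcm-hm-liblinear": ClassifierConfig(
        solver="linear-primal", penalty="l2", C=0.07, homogeneous_map=(1, None)
    ),
    "tfcm-svm": ClassifierConfig(solver="kernel-svm", kernel="polynomial", C=1.0),
    "tfcm-liblinear": ClassifierConfig(solver="linear-primal", penalty="l1", C=15.0),
    "tfcm-hm-liblinear": ClassifierConfig(
        solver="linear-primal", penalty="l1", C=15.0, homogeneous_map=(1, None)
    ),
    "lbp-svm": ClassifierConfig(solver="kernel-svm", kernel="intersection", C=0.32),
    "lbp-liblinear": ClassifierConfig(solver="linear-primal", penalty="l1", C=100.0),
    "lbp-hm-liblinear": ClassifierConfig(
        solver="linear-primal", penalty="l1", C=100.0, homogeneous_map=(1, None)
    ),
}


class TextureClassifier:
    """A fitted scaling + optional chi2 map + max-margin model."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self._lo = None
        self._span = None
        self._train_X = None
        self._est = None

    # -- preprocessing ------------------------------------------------
    def _fit_scaler(self, X):
        if self.config.scaling == "minmax01":
            self._lo = X.min(axis=0)
            span = X.max(axis=0) - self._lo
            self._span = np.where(span > 0, span, 1.0)

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.config.scaling == "minmax01":
            X = np.clip((X - self._lo) / self._span, 0.0, 1.0)
        if self.config.homogeneous_map is not None:
            order, period = self.config.homogeneous_map
            X = chi2_feature_map(X, order=order, period=period)
        return X

    # -- estimator ----------------------------------------------------
    def _make_estimator(self):
        cfg = self.config
        if cfg.solver == "linear-primal":
            return LinearSVC(
                penalty=cfg.penalty,
                loss="squared_hinge",
                dual=False,
                C=cfg.C,
                max_iter=200000,
                tol=1e-3,  # LIBLINEAR's own default is 1e-2; sklearn's 1e-4 is needlessly strict here
                random_state=cfg.seed,
            )
        if cfg.kernel == "linear":
            return SVC(kernel="linear", C=cfg.C)
        if cfg.kernel == "polynomial":
            return SVC(
                kernel="poly", degree=cfg.poly_degree, coef0=cfg.poly_coef0,
                gamma="scale", C=cfg.C,
            )
        if cfg.kernel == "intersection":
            return SVC(kernel="precomputed", C=cfg.C)
        raise ParameterError(f"unknown kernel {self.config.kernel!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ParameterError("features must be finite")
        if np.unique(y).size < 2:
            raise TrainingError("training needs at least two classes")
        self._fit_scaler(X)
        Xt = self._transform(X)
        self._est = self._make_estimator()
        if self.config.solver == "kernel-svm" and self.config.kernel == "intersection":
            self._train_X = Xt
            self._est.fit(intersection_kernel(Xt, Xt), y)
        else:
            self._est.fit(Xt, y)
        return self

    def _gram_or_features(self, X):
        Xt = self._transform(X)
        if self._train_X is not None:
            return intersection_kernel(Xt, self._train_X)
        return Xt

    def predict(self, X):
        return self._est.predict(self._gram_or_features(X))

    def decision_function(self, X):
        return self._est.decision_function(self._gram_or_features(X))


def train_classifier(X, y, config: ClassifierConfig) -> TextureClassifier:
    """Fit a classifier; deterministic for a fixed config seed."""
    return TextureClassifier(config).fit(X, y)


# ---------------------------------------------------------------------------
# evaluation


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity, specificity and accuracy in percent."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ParameterError("no samples to evaluate")
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": 100.0 * (tp + tn) / total,
    }


@dataclass
class EvalReport:
    """Per-fold and pooled confusion counts with percent metrics."""

    folds: list  # one dict per fold: tp/fn/tn/fp + metrics
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "pooled": {
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def evaluate_cv(X, y, config: ClassifierConfig, k: int = 5, seed: int = 0) -> EvalReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Scaling is fit on the training folds only and applied to the held-out
    fold. The positive class is ``"seizure"``.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ParameterError("k must be >= 2")
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise TrainingError("evaluation needs two classes")
    if counts.min() < k:
        raise TrainingError(
            f"every class needs >= {k} members for {k}-fold CV; got {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    TP = FN = TN = FP = 0
    for train_idx, test_idx in skf.split(X, y):
        model = TextureClassifier(config).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        tp = int(np.sum((truth == POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
        fn = int(np.sum((truth == POSITIVE_LABEL) & (pred != POSITIVE_LABEL)))
        tn = int(np.sum((truth != POSITIVE_LABEL) & (pred != POSITIVE_LABEL)))
        fp = int(np.sum((truth != POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
        folds.append({"tp": tp, "fn": fn, "tn": tn, "fp": fp,
                      **metrics_from_counts(tp, fn, tn, fp)})
        TP += tp; FN += fn; TN += tn; FP += fp
    pooled = metrics_from_counts(TP, FN, TN, FP)
    return EvalReport(
        folds=folds, tp=TP, fn=FN, tn=TN, fp=FP,
        accuracy=pooled["accuracy"], sensitivity=pooled["sensitivity"],
        specificity=pooled["specificity"], n_folds=k, seed=seed,
    )
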