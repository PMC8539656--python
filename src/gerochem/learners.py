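"""Classifiers and evaluation.

The primary model is a four-layer feed-forward network (input, two hidden
layers each as wide as the input, 2-unit softmax output).  The first
hidden layer uses SELU activation and the second ReLU; 50% dropout
follows each hidden layer during training.  Training minimizes the
softmax cross-entropy with the Adam optimizer and stops early when the
validation loss has not improved for ``patience`` epochs, restoring the
best-epoch weights.  Implemented directly on NumPy.

Benchmarks: random forest, Gaussian naive Bayes, and L2-regularized
(ridge) logistic regression, via scikit-learn.

Evaluation reports accuracy, ROC-AUC, precision, recall, and the area
under the precision–recall curve (APR), plus confusion counts at a 0.5
probability threshold:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB

from .datasets import AssembledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DnnConfig",
    "DnnClassifier",
    "TrainedClassifier",
    "EvalReport",
    "build_dnn",
    "train_classifier",
    "predict_proba",
    "evaluate",
    "LEARNER_KINDS",
]

LEARNER_KINDS = ("dnn", "random_forest", "naive_bayes", "ridge_logistic")

# SELU's self-normalizing constants
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


@dataclass(frozen=True)
class DnnConfig:
    """Hyperparameters of the feed-forward network.

    The architecture itself (two equal-to-input hidden layers, SELU then
    ReLU, 50% dropout, softmax output) is fixed by design; the activation
    order is switchable since only the set {SELU, ReLU} is prescribed.
    """

    dropout_rate: float = 0.5
    activations: tuple[str, str] = ("selu", "relu")
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1   # internal early-stopping split when no fold given
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        bad = set(self.activations) - {"selu", "relu"}
        if bad:
            raise ValueError(f"unsupported activation(s): {sorted(bad)}")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0)) - 1))


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DnnClassifier:
    """Four-layer softmax network with widths [w, w, w, 2] for input width w."""

    def __init__(self, input_width: int, config: DnnConfig | None = None):
        if input_width < 1:
            raise ValueError("input_width must be >= 1")
        self.config = config or DnnConfig()
        self.input_width = input_width
        w = input_width
        self.widths = [w, w, w, 2]
        rng = np.random.default_rng(self.config.seed)
        # lecun-normal init for the SELU layer, He for ReLU, Glorot output
        def init(n_in, n_out, scale):
            return rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float64)
        a0, a1 = self.config.activations
        s0 = math.sqrt(1.0 / w) if a0 == "selu" else math.sqrt(2.0 / w)
        s1 = math.sqrt(1.0 / w) if a1 == "selu" else math.sqrt(2.0 / w)
        self.W = [init(w, w, s0), init(w, w, s1), init(w, 2, math.sqrt(2.0 / (w + 2)))]
        self.b = [np.zeros(w), np.zeros(w), np.zeros(2)]
        self._rng = rng
        self.history: dict = {"train_loss": [], "val_loss": [], "best_val_loss": []}
        self.epochs_run = 0

    # -- forward ---------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.W, self.b))

    def _forward(self, X: np.ndarray, train: bool = False):
        a0, a1 = self.config.activations
        p = self.config.dropout_rate
        cache = {"X": X}
        z1 = X @ self.W[0] + self.b[0]
        h1 = _act(a0, z1)
        if train and p > 0:
            m1 = (self._rng.random(h1.shape) >= p) / (1 - p)  # inverted dropout
            h1 = h1 * m1
            cache["m1"] = m1
        z2 = h1 @ self.W[1] + self.b[1]
        h2 = _act(a1, z2)
        if train and p > 0:
            m2 = (self._rng.random(h2.shape) >= p) / (1 - p)
            h2 = h2 * m2
            cache["m2"] = m2
        z3 = h2 @ self.W[2] + self.b[2]
        out = _softmax(z3)
        cache.update(z1=z1, h1=h1, z2=z2, h2=h2)
        return out, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix (n, 2); dropout disabled (inference)."""
        X = self._check_X(X)
        out, _ = self._forward(X, train=False)
        return out

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width mismatch: model expects {self.input_width}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}")
        return X

    # -- training --------------------------------------------------------

    @staticmethod
    def _loss(proba: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(proba[np.arange(len(y)), y] + eps)))

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None) -> "DnnClassifier":
        """Adam + early stopping on validation loss; best weights restored.

        Without an explicit validation set, a stratified ``val_fraction``
        split is carved out internally for the stopping criterion.
        """
        cfg = self.config
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if X_val is None:
            if len(np.unique(y)) < 2:
                raise ValueError("training data must contain both classes")
            sss = StratifiedShuffleSplit(n_splits=1, test_size=max(cfg.val_fraction, 2 / len(y)),
                                         random_state=cfg.seed)
            tr, va = next(sss.split(X, y))
            X, X_val, y, y_val = X[tr], X[va], y[tr], y[va]
        else:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val, dtype=int)

        a0, a1 = cfg.activations
        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best = None
        bad_epochs = 0
        n = len(X)
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                proba, cache = self._forward(xb, train=True)
                ep_loss += self._loss(proba, yb) * len(idx)

                # backprop
                m = len(idx)
                d3 = proba.copy()
                d3[np.arange(m), yb] -= 1.0
                d3 /= m
                gW2 = cache["h2"].T @ d3
                gb2 = d3.sum(axis=0)
                dh2 = d3 @ self.W[2].T
                if "m2" in cache:
                    dh2 = dh2 * cache["m2"]
                d2 = dh2 * _act_grad(a1, cache["z2"])
                gW1 = cache["h1"].T @ d2
                gb1 = d2.sum(axis=0)
                dh1 = d2 @ self.W[1].T
                if "m1" in cache:
                    dh1 = dh1 * cache["m1"]
                d1 = dh1 * _act_grad(a0, cache["z1"])
                gW0 = cache["X"].T @ d1
                gb0 = d1.sum(axis=0)

                t += 1
                for i, (gW, gb) in enumerate(((gW0, gb0), (gW1, gb1), (gW2, gb2))):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW * gW
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb * gb
                    lr_t = cfg.learning_rate * math.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
                    self.W[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                    self.b[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)

            val_proba, _ = self._forward(X_val, train=False)
            val_loss = self._loss(val_proba, y_val)
            self.history["train_loss"].append(ep_loss / n)
            self.history["val_loss"].append(val_loss)
            self.epochs_run = epoch + 1
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best = ([W.copy() for W in self.W], [b.copy() for b in self.b])
                bad_epochs = 0
            else:
                bad_epochs += 1
            self.history["best_val_loss"].append(best_loss)
            if bad_epochs >= cfg.patience:
                break
        if best is not None:
            self.W, self.b = best
        return self


def build_dnn(input_width: int, config: DnnConfig | None = None) -> DnnClassifier:
    """Untrained network with layer widths [w, w, w, 2]."""
    return DnnClassifier(input_width, config)


# ---------------------------------------------------------------------------
# Unified training / prediction surface
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    kind: str
    model: object
    input_width: int
    metadata: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    """Threshold-0.5 confusion counts plus threshold-free rank metrics.

    ``auc_roc``/``apr`` (and precision when nothing is predicted
    positive) are NaN where undefined, e.g. single-class truth.
    """

    accuracy: float
    auc_roc: float
    precision: float
    recall: float
    apr: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "auc_roc", "precision", "recall", "apr",
                 "tp", "fp", "tn", "fn")}


def _make_sklearn(kind: str, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "ridge_logistic":
        # default penalty is L2 (ridge): guards against collinearity in
        # the wide binary/continuous feature vector
        return LogisticRegression(C=1.0, max_iter=2000)
    raise ValueError(f"unknown learner kind {kind!r}; choose from {LEARNER_KINDS}")


def _fit_one(kind: str, X, y, Xv, yv, config: DnnConfig):
    if kind == "dnn":
        net = DnnClassifier(X.shape[1], config)
        net.fit(X, y, Xv, yv)
        return net
    clf = _make_sklearn(kind, config.seed)
    clf.fit(X, y)
    return clf


def _proba_pos(model, X) -> np.ndarray:
    if isinstance(model, DnnClassifier):
        return model.predict_proba(X)[:, 1]
    if X.shape[1] != model.n_features_in_:
        raise ValueError(f"feature width mismatch: model expects "
                         f"{model.n_features_in_}, got {X.shape[1]}")
    return model.predict_proba(X)[:, 1]


def train_classifier(kind: str, dataset: AssembledDataset,
                     folds: list[tuple[np.ndarray, np.ndarray]],
                     config: DnnConfig | None = None
                     ) -> tuple[TrainedClassifier, list[EvalReport]]:
    """Cross-validated training: one fit per fold scored on its validation
    split, then a final refit on all rows.

    Returns the refit classifier plus the per-fold validation reports.
    """
    config = config or DnnConfig()
    if kind not in LEARNER_KINDS:
        raise ValueError(f"unknown learner kind {kind!r}; choose from {LEARNER_KINDS}")
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    classes = np.unique(dataset.y)
    if len(classes) < 2:
        missing = "positive" if 1 not in classes else "negative"
        raise ValueError(f"dataset has no {missing} samples; cannot train a classifier")

    reports = []
    for i, (tr, va) in enumerate(folds):
        fold_cfg = replace(config, seed=config.seed + i) if kind == "dnn" else config
        model = _fit_one(kind, dataset.X[tr], dataset.y[tr],
                         dataset.X[va], dataset.y[va], fold_cfg)
        scores = _proba_pos(model, dataset.X[va])
        reports.append(evaluate(dataset.y[va], scores))

    final = _fit_one(kind, dataset.X, dataset.y, None, None, config)
    meta = {"seed": config.seed, "n_folds": len(folds), "n_samples": dataset.n_samples}
    if isinstance(final, DnnClassifier):
        meta["epochs_run"] = final.epochs_run
    return TrainedClassifier(kind, final, dataset.width, meta), reports


def predict_proba(trained: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class probability per row; rejects width mismatches."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != trained.input_width:
        got = X.shape[1] if X.ndim == 2 else X.shape
        raise ValueError(f"feature width mismatch: model expects "
                         f"{trained.input_width}, got {got}")
    return _proba_pos(trained.model, X)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(y_true, y_score, threshold: float = 0.5) -> EvalReport:
    """Confusion counts at ``threshold`` plus rank-based AUC and
    step-interpolated area under the precision–recall curve.

    With single-class truth the rank metrics are undefined and reported
    as NaN; accuracy and whichever of precision/recall remain defined are
    still computed.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have equal lengths")
    y_pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    n = len(y_true)
    accuracy = (tp + tn) / n if n else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, y_score))
        apr = float(average_precision_score(y_true, y_score))
    else:
        auc = apr = float("nan")
    return EvalReport(accuracy=accuracy, auc_roc=auc, precision=precision,
                      recall=recall, apr=apr, tp=tp, fp=fp, tn=tn, fn=fn)
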