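"""Two-layer fully connected PJK risk model.

One hidden tanh layer plus a sigmoid output unit maps the 18 features
(16 stress deltas, age, gender) to a risk score in (0, 1).  Training
minimizes the mean squared error between scores and binary PJK labels with
full-batch Adam; features are z-scored with statistics captured from the
training set and stored on the model.  Everything is plain numpy, with
analytic gradients both for the weights (training) and for the inputs
(needed by the angle optimizer), and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .features import Standardizer

__all__ = [
    "LoocvResult",
    "RiskModel",
    "TrainConfig",
    "accuracy",
    "loocv",
    "roc_auc",
    "train",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; the seed fixes every random draw."""

    hidden_width: int = 8
    learning_rate: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    epochs: int = 2000
    seed: int = 0
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.hidden_width < 1 or self.epochs < 1:
            raise ValueError("hidden_width and epochs must be positive")
        for name in ("learning_rate", "adam_beta1", "adam_beta2", "adam_epsilon", "init_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RiskModel:
    """g(x; W): sigmoid(w2 . tanh(W1 z + b1) + b2) on standardized features z."""

    def __init__(
        self,
        W1: np.ndarray,
        b1: np.ndarray,
        w2: np.ndarray,
        b2: float,
        standardizer: Standardizer | None = None,
        config: TrainConfig | None = None,
    ) -> None:
        self.W1 = np.asarray(W1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.w2 = np.asarray(w2, dtype=float)
        self.b2 = float(b2)
        H, p = self.W1.shape
        if self.b1.shape != (H,) or self.w2.shape != (H,):
            raise ValueError("inconsistent parameter shapes")
        self.n_features = p
        self.standardizer = standardizer
        self.config = config

    # -- construction -----------------------------------------------------

    @classmethod
    def initialize(cls, n_features: int, config: TrainConfig) -> "RiskModel":
        """Xavier-uniform initialization scaled by ``init_scale``."""
        rng = np.random.default_rng(config.seed)
        H = config.hidden_width
        lim1 = config.init_scale * np.sqrt(6.0 / (n_features + H))
        lim2 = config.init_scale * np.sqrt(6.0 / (H + 1))
        return cls(
            W1=rng.uniform(-lim1, lim1, size=(H, n_features)),
            b1=np.zeros(H),
            w2=rng.uniform(-lim2, lim2, size=H),
            b2=0.0,
            config=config,
        )

    # -- inference ---------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.standardizer is None:
            return np.asarray(X, dtype=float)
        return self.standardizer.transform(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted PJK risk in (0, 1); X is (n, p) or (p,) raw features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        Z = self._standardize(X)
        H = np.tanh(Z @ self.W1.T + self.b1)
        return _sigmoid(H @ self.w2 + self.b2)

    def predict_one(self, x: np.ndarray) -> float:
        return float(self.predict(x)[0])

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """dy/dx of the risk w.r.t. the raw (unstandardized) features."""
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape != (self.n_features,):
            raise ValueError(f"expected {self.n_features} features, got {x.shape}")
        z = self._standardize(x[None, :])[0]
        h = np.tanh(self.W1 @ z + self.b1)
        y = float(_sigmoid(np.array([self.w2 @ h + self.b2]))[0])
        dy_dh = y * (1.0 - y) * self.w2
        dy_dz = self.W1.T @ (dy_dh * (1.0 - h**2))
        if self.standardizer is not None:
            dy_dz = dy_dz / self.standardizer.scale
        return dy_dz

    # -- training internals ------------------------------------------------

    def _loss_and_gradients(
        self, Z: np.ndarray, t: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """MSE loss and its analytic gradients on standardized inputs Z."""
        n = Z.shape[0]
        H = np.tanh(Z @ self.W1.T + self.b1)
        y = _sigmoid(H @ self.w2 + self.b2)
        err = y - t
        loss = float(np.mean(err**2))
        ds = (2.0 / n) * err * y * (1.0 - y)  # dL/d(pre-sigmoid)
        grad_w2 = H.T @ ds
        grad_b2 = float(ds.sum())
        dH = np.outer(ds, self.w2) * (1.0 - H**2)
        grad_W1 = dH.T @ Z
        grad_b1 = dH.sum(axis=0)
        return loss, {"W1": grad_W1, "b1": grad_b1, "w2": grad_w2, "b2": np.array([grad_b2])}

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "standardizer": None
            if self.standardizer is None
            else {"mean": self.standardizer.mean.tolist(),
                  "scale": self.standardizer.scale.tolist()},
            "config": None if self.config is None else dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        doc = json.loads(Path(path).read_text())
        std = doc.get("standardizer")
        return cls(
            W1=np.asarray(doc["W1"]),
            b1=np.asarray(doc["b1"]),
            w2=np.asarray(doc["w2"]),
            b2=doc["b2"],
            standardizer=None
            if std is None
            else Standardizer(np.asarray(std["mean"]), np.asarray(std["scale"])),
            config=None if doc.get("config") is None else TrainConfig(**doc["config"]),
        )


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    standardize: bool = True,
) -> tuple[RiskModel, np.ndarray]:
    """Fit the risk model by full-batch Adam on the MSE objective.

    Returns the trained model and the per-epoch loss trajectory (epochs + 1
    entries; the first is the loss at initialization).  Identical data,
    config and seed give bit-identical results.
    """
    if config is None:
        config = TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        warnings.warn("training set has a single class; the model may be constant",
                      stacklevel=2)

    model = RiskModel.initialize(X.shape[1], config)
    if standardize:
        model.standardizer = Standardizer.fit(X)
        Z = model.standardizer.transform(X)
    else:
        Z = X

    params = ["W1", "b1", "w2", "b2"]
    m = {k: 0.0 for k in params}
    v = {k: 0.0 for k in params}
    b1, b2c, eps, lr = (config.adam_beta1, config.adam_beta2,
                        config.adam_epsilon, config.learning_rate)
    history = np.empty(config.epochs + 1)
    for epoch in range(config.epochs):
        loss, grads = model._loss_and_gradients(Z, y)
        history[epoch] = loss
        for k in params:
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2c * v[k] + (1 - b2c) * g**2
            mhat = m[k] / (1 - b1 ** (epoch + 1))
            vhat = v[k] / (1 - b2c ** (epoch + 1))
            step = lr * mhat / (np.sqrt(vhat) + eps)
            if k == "b2":
                model.b2 -= float(step[0])
            else:
                setattr(model, k, getattr(model, k) - step)
    history[-1], _ = model._loss_and_gradients(Z, y)
    return model, history


def accuracy(risks: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of cases where (risk >= threshold) matches the label."""
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return float(np.mean((risks >= threshold) == (labels == 1.0)))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U normalization.

    Tied scores count one half.  Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclasses.dataclass
class LoocvResult:
    """Held-out predictions from leave-one-out cross-validation."""

    risks: np.ndarray  #: (n,) held-out predicted risks, fold i predicts case i
    labels: np.ndarray
    accuracy: float
    auc: float | None  #: None when only one class is present overall
    single_class_folds: list[int]  #: folds whose training set had one class


def loocv(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> LoocvResult:
    """Leave-one-out cross-validation of the risk model.

    Each fold re-standardizes and re-trains on the n-1 remaining cases
    (with the same hyperparameters and seed) and predicts the held-out
    case, so no test-set statistics ever leak into training.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    risks = np.empty(n)
    degenerate = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if len(np.unique(y[keep])) < 2:
            degenerate.append(i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, _ = train(X[keep], y[keep], config)
        risks[i] = model.predict_one(X[i])
    auc = roc_auc(risks, y) if len(np.unique(y)) == 2 else None
    return LoocvResult(
        risks=risks,
        labels=y.copy(),
        accuracy=accuracy(risks, y),
        auc=auc,
        single_class_folds=degenerate,
    )
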