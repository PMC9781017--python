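"""The integrating multilayer perceptron.

A 6-input, one-hidden-layer (4 tanh units), 3-output softmax network maps
the assembled screening features to class probabilities (inactive,
antagonist, agonist).  Inputs are min-max normalized to [0, 1] with
training-set bounds; training is full-batch gradient descent on the mean
cross-entropy with momentum (defaults: learning rate 0.5, momentum 0.7,
25 epochs), with seed-controlled uniform(-0.5, 0.5) weight
initialization.  All four choices are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the six inputs, in fixed order
FEATURE_NAMES = ["score_ant", "score_ag", "crit_ant", "crit_ag",
                 "deltaG_closed", "lelp_open"]

#: fixed class order for one-hot encoding and output nodes
CLASS_ORDER = ("IN", "ANT", "AG")


@dataclass
class Hyperparams:
    learning_rate: float = 0.5
    momentum: float = 0.7
    max_epochs: int = 25
    n_hidden: int = 4
    seed: int = 0


@dataclass
class MLPModel:
    W1: np.ndarray                   # (6, n_hidden)
    b1: np.ndarray                   # (n_hidden,)
    W2: np.ndarray                   # (n_hidden, 3)
    b2: np.ndarray                   # (3,)
    feature_min: np.ndarray          # per-input normalization bounds
    feature_max: np.ndarray
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    loss_trajectory: list[float] = field(default_factory=list)

    def normalize(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return np.clip((X - self.feature_min) / span, 0.0, 1.0)

    def to_json(self, path: str | Path) -> None:
        data = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "hyperparams": vars(self.hyperparams),
            "loss_trajectory": self.loss_trajectory,
            "feature_names": FEATURE_NAMES,
            "class_order": list(CLASS_ORDER),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        data = json.loads(Path(path).read_text())
        return cls(
            W1=np.array(data["W1"]), b1=np.array(data["b1"]),
            W2=np.array(data["W2"]), b2=np.array(data["b2"]),
            feature_min=np.array(data["feature_min"]),
            feature_max=np.array(data["feature_max"]),
            hyperparams=Hyperparams(**data["hyperparams"]),
            loss_trajectory=list(data["loss_trajectory"]),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(params, X):
    W1, b1, W2, b2 = params
    H = np.tanh(X @ W1 + b1)
    P = _softmax(H @ W2 + b2)
    return H, P


def loss_and_grad(params, X, Y):
    """Mean cross-entropy and its analytic gradient.

    ``params = (W1, b1, W2, b2)``; X normalized features (n, 6), Y one-hot
    labels (n, 3).  Returns (loss, (dW1, db1, dW2, db2)).
    """
    W1, b1, W2, b2 = params
    n = X.shape[0]
    H, P = _forward(params, X)
    loss = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n
    dZ2 = (P - Y) / n
    dW2 = H.T @ dZ2
    db2 = dZ2.sum(axis=0)
    dH = dZ2 @ W2.T
    dZ1 = dH * (1 - H ** 2)
    dW1 = X.T @ dZ1
    db1 = dZ1.sum(axis=0)
    return loss, (dW1, db1, dW2, db2)


def one_hot(labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    Y = np.zeros((len(labels), len(CLASS_ORDER)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def split_train_test(rows: pd.DataFrame, labels, fraction: float = 0.7,
                     seed: int = 0):
    """Stratified-by-class random split; deterministic given seed."""
    import warnings

    labels = np.asarray(labels)
    if len(rows) < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(fraction * len(idx)))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    if len(np.unique(labels[train_idx])) < len(np.unique(labels)) or \
       len(np.unique(labels[test_idx])) < len(np.unique(labels)):
        warnings.warn("a class is absent from one side of the split")
    return (rows.iloc[train_idx], labels[train_idx],
            rows.iloc[test_idx], labels[test_idx])


def train(train_rows: pd.DataFrame, labels,
          hyperparams: Hyperparams | None = None) -> MLPModel:
    """Fit the 6-4-3 network by batch gradient descent with momentum."""
    hp = hyperparams or Hyperparams()
    X_raw = train_rows[FEATURE_NAMES].to_numpy(dtype=float)
    fmin, fmax = X_raw.min(axis=0), X_raw.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    X = (X_raw - fmin) / span
    Y = one_hot(labels)

    rng = np.random.default_rng(hp.seed)
    n_in, n_out = len(FEATURE_NAMES), len(CLASS_ORDER)
    params = [rng.uniform(-0.5, 0.5, s) for s in
              [(n_in, hp.n_hidden), (hp.n_hidden,), (hp.n_hidden, n_out), (n_out,)]]
    velocity = [np.zeros_like(p) for p in params]

    trajectory = []
    for epoch in range(hp.max_epochs):
        loss, grads = loss_and_grad(params, X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        trajectory.append(float(loss))
        for i in range(4):
            velocity[i] = hp.momentum * velocity[i] - hp.learning_rate * grads[i]
            params[i] = params[i] + velocity[i]

    return MLPModel(W1=params[0], b1=params[1], W2=params[2], b2=params[3],
                    feature_min=fmin, feature_max=fmax,
                    hyperparams=hp, loss_trajectory=trajectory)


def predict_proba(model: MLPModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities (columns p_inactive, p_antagonist, p_agonist)."""
    X = model.normalize(rows[FEATURE_NAMES].to_numpy(dtype=float))
    _, P = _forward((model.W1, model.b1, model.W2, model.b2), X)
    return pd.DataFrame(P, index=rows.index,
                        columns=["p_inactive", "p_antagonist", "p_agonist"])


def classify_with_threshold(probs: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """ANT or AG when its probability exceeds the threshold, otherwise the
    argmax class; ties broken by class order (IN, ANT, AG)."""
    out = []
    for _, row in probs.iterrows():
        p = row[["p_inactive", "p_antagonist", "p_agonist"]].to_numpy()
        if p[1] > threshold and p[1] >= p[2]:
            out.append("ANT")
        elif p[2] > threshold:
            out.append("AG")
        else:
            out.append(CLASS_ORDER[int(np.argmax(p))])
    return out


def variable_importance(model: MLPModel, rows: pd.DataFrame, labels,
                        n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance: mean cross-entropy increase when one input
    is shuffled, normalized to sum to 1 over the six inputs."""
    rng = np.random.default_rng(seed)
    Y = one_hot(labels)
    X = model.normalize(rows[FEATURE_NAMES].to_numpy(dtype=float))
    params = (model.W1, model.b1, model.W2, model.b2)
    base, _ = loss_and_grad(params, X, Y)
    increases = np.zeros(len(FEATURE_NAMES))
    for j in range(len(FEATURE_NAMES)):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            loss, _ = loss_and_grad(params, Xp, Y)
            increases[j] += max(loss - base, 0.0)
    increases /= n_repeats
    total = increases.sum()
    if total > 0:
        increases /= total
    return pd.Series(increases, index=FEATURE_NAMES)


def assemble_features(score_table: pd.DataFrame,
                      crit_ant: pd.Series, crit_ag: pd.Series,
                      deltaG_closed: pd.Series, lelp_open: pd.Series
                      ) -> pd.DataFrame:
    """Join the six model inputs on compound_id, dropping compounds with
    any missing feature (e.g. undefined LELP)."""
    df = pd.DataFrame({
        "score_ant": score_table["Score-ANT"],
        "score_ag": score_table["Score-AG"],
        "crit_ant": crit_ant,
        "crit_ag": crit_ag,
        "deltaG_closed": deltaG_closed,
        "lelp_open": lelp_open,
    })
    return df.dropna()
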