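"""Distribution-fed recurrent classifier of interaction partners.

The whole (energy, iRMS, TM-family) distribution of a docking ensemble is
fed, one decoy per timestep, into a single Elman-style recurrent block; the
final hidden state passes through a small dense stack ending in a 2-way
softmax ("interacting" vs "non-interacting"), trained with cross-entropy.
The network and its backpropagation-through-time training are implemented
directly on numpy, with the classic optimizer update rules (Adam, SGD,
RMSprop, Adadelta, Adamax, Adagrad, Nadam, Ftrl) selectable by name.

Input representation: per-decoy rows sorted by ascending interaction energy
(ties by decoy id), truncated or zero-padded to a fixed sequence length,
and standardized per column with training-set statistics. Sorting
canonicalizes the arbitrary decoy order of a docking run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .scores import MetricsTable

#: Feature-name -> metrics-table column.
FEATURE_COLUMNS = {
    "energy": "energy_kcal_mol",
    "irms": "irms_A",
    "rtm": "rtm",
    "itm": "itm_complex",
    "ritm": "ritm",
}

#: Candidate layer structures (first width = recurrent units, rest dense,
#: final 2-way output).
LAYER_CANDIDATES = (
    (1024, 2),
    (1024, 64, 2),
    (1024, 128, 2),
    (2048, 128, 2),
    (2048, 512, 128, 32, 8, 2),
)

OPTIMIZERS = ("adam", "sgd", "rmsprop", "adadelta", "adamax", "adagrad", "nadam", "ftrl")


def build_features(
    metrics: MetricsTable,
    columns: Sequence[str] = ("energy", "irms"),
    length: int = 1000,
) -> np.ndarray:
    """Raw (unnormalized) feature sequence of one ensemble, shape (length, n_cols).

    Rows are sorted by ascending energy (strongest decoy first), truncated
    or zero-padded to ``length``.
    """
    unknown = [c for c in columns if c not in FEATURE_COLUMNS]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    df = metrics.df.sort_values(
        ["energy_kcal_mol", "decoy_id"], kind="mergesort"
    )
    cols = [FEATURE_COLUMNS[c] for c in columns]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    values = df[cols].to_numpy(dtype=float)[:length]
    out = np.zeros((length, len(cols)), dtype=float)
    out[: len(values)] = values
    return out


def features_from_tables(
    tables: Sequence[MetricsTable],
    columns: Sequence[str] = ("energy", "irms"),
    length: int = 1000,
) -> np.ndarray:
    return np.stack([build_features(t, columns, length) for t in tables])


# ---------------------------------------------------------------------------
# Optimizer update rules
# ---------------------------------------------------------------------------

class _Optimizer:
    """Stateful parameter updater; one slot dict per parameter array."""

    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.slots: dict[str, dict[str, np.ndarray]] = {}

    def _slot(self, key: str, like: np.ndarray, names: Sequence[str], init=0.0):
        if key not in self.slots:
            self.slots[key] = {n: np.full_like(like, init) for n in names}
        return self.slots[key]

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self._update(key, params[key], g)

    def _update(self, key: str, w: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr=0.01, momentum=0.0):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, key, w, g):
        s = self._slot(key, w, ["v"])
        s["v"] = self.momentum * s["v"] - self.lr * g
        w += s["v"]


class Adam(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, w, g):
        s = self._slot(key, w, ["m", "v"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        mhat = s["m"] / (1 - self.beta1**self.t)
        vhat = s["v"] / (1 - self.beta2**self.t)
        w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    def _update(self, key, w, g):
        s = self._slot(key, w, ["m", "v"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        mhat = s["m"] / (1 - self.beta1**self.t)
        vhat = s["v"] / (1 - self.beta2**self.t)
        nesterov = self.beta1 * mhat + (1 - self.beta1) * g / (1 - self.beta1**self.t)
        w -= self.lr * nesterov / (np.sqrt(vhat) + self.eps)


class Adamax(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, w, g):
        s = self._slot(key, w, ["m", "u"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["u"] = np.maximum(self.beta2 * s["u"], np.abs(g))
        w -= self.lr / (1 - self.beta1**self.t) * s["m"] / (s["u"] + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, w, g):
        s = self._slot(key, w, ["v"])
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        w -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adagrad(_Optimizer):
    def __init__(self, lr=0.001, initial_accumulator=0.1, eps=1e-7):
        super().__init__(lr)
        self.initial_accumulator, self.eps = initial_accumulator, eps

    def _update(self, key, w, g):
        s = self._slot(key, w, ["v"], init=self.initial_accumulator)
        s["v"] += g * g
        w -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, lr=0.001, rho=0.95, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, w, g):
        s = self._slot(key, w, ["v", "u"])
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        dx = np.sqrt(s["u"] + self.eps) / np.sqrt(s["v"] + self.eps) * g
        s["u"] = self.rho * s["u"] + (1 - self.rho) * dx * dx
        w -= self.lr * dx


class Ftrl(_Optimizer):
    """FTRL-proximal with power -0.5 learning-rate schedule (no regularization)."""

    def __init__(self, lr=0.001, initial_accumulator=0.1, beta=0.0):
        super().__init__(lr)
        self.initial_accumulator, self.beta = initial_accumulator, beta

    def _update(self, key, w, g):
        s = self._slot(key, w, ["z"])
        n = self._slot(key + "/n", w, ["n"], init=self.initial_accumulator)
        new_n = n["n"] + g * g
        sigma = (np.sqrt(new_n) - np.sqrt(n["n"])) / self.lr
        s["z"] += g - sigma * w
        n["n"] = new_n
        w[...] = -s["z"] * self.lr / (self.beta + np.sqrt(new_n))


def make_optimizer(name: str, learning_rate: float | None = None) -> _Optimizer:
    table = {
        "sgd": SGD,
        "adam": Adam,
        "nadam": Nadam,
        "adamax": Adamax,
        "rmsprop": RMSprop,
        "adagrad": Adagrad,
        "adadelta": Adadelta,
        "ftrl": Ftrl,
    }
    key = name.lower()
    if key not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {OPTIMIZERS}")
    return table[key]() if learning_rate is None else table[key](lr=learning_rate)


# ---------------------------------------------------------------------------
# Elman network forward/backward
# ---------------------------------------------------------------------------

def _init_params(n_features: int, layers: Sequence[int], rng: np.random.Generator):
    """Glorot-uniform initialization; ``layers[0]`` is the recurrent width."""
    hidden, dense = layers[0], list(layers[1:])

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    params = {
        "Wx": glorot(n_features, hidden),
        "Wh": glorot(hidden, hidden),
        "bh": np.zeros(hidden),
    }
    widths = [hidden, *dense]
    for i in range(len(dense)):
        params[f"Wd{i}"] = glorot(widths[i], widths[i + 1])
        params[f"bd{i}"] = np.zeros(widths[i + 1])
    return params


def _forward(x: np.ndarray, params: dict[str, np.ndarray], n_dense: int):
    """Forward pass. x: (batch, T, F). Returns probs and a cache for BPTT."""
    batch, T, _ = x.shape
    hidden = params["bh"].shape[0]
    hs = np.empty((T + 1, batch, hidden))
    hs[0] = 0.0
    for t in range(T):
        hs[t + 1] = np.tanh(x[:, t] @ params["Wx"] + hs[t] @ params["Wh"] + params["bh"])
    a = hs[T]
    activations = [a]
    for i in range(n_dense):
        z = a @ params[f"Wd{i}"] + params[f"bd{i}"]
        a = z if i == n_dense - 1 else np.maximum(z, 0.0)
        activations.append(a)
    logits = activations[-1]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    return probs, (hs, activations)


def _backward(x, y_idx, probs, cache, params, n_dense):
    """Cross-entropy gradients via backpropagation through time."""
    hs, activations = cache
    batch, T, _ = x.shape
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    delta = probs.copy()
    delta[np.arange(batch), y_idx] -= 1.0
    delta /= batch
    for i in range(n_dense - 1, -1, -1):
        grads[f"Wd{i}"] = activations[i].T @ delta
        grads[f"bd{i}"] = delta.sum(axis=0)
        delta = delta @ params[f"Wd{i}"].T
        if i > 0:
            delta *= activations[i] > 0  # relu mask
    dh = delta
    for t in range(T - 1, -1, -1):
        dz = dh * (1.0 - hs[t + 1] ** 2)
        grads["Wx"] += x[:, t].T @ dz
        grads["Wh"] += hs[t].T @ dz
        grads["bh"] += dz.sum(axis=0)
        dh = dz @ params["Wh"].T
    return grads


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class RecurrentPairClassifier(BaseEstimator, ClassifierMixin):
    """Recurrent binary classifier of interaction-energy distributions.

    Parameters
    ----------
    feature_columns : sequence of str
        Metric names from {"energy", "irms", "rtm", "itm", "ritm"}; used
        when ``fit``/``predict`` receive metrics tables rather than arrays.
    sequence_length : int
        Decoys per input sequence (pad/truncate target).
    recurrent_units : int
        Width of the single recurrent block.
    dense_layers : sequence of int
        Widths of the dense stack after the recurrent block; must end in 2.
    optimizer : str
        One of {"adam", "sgd", "rmsprop", "adadelta", "adamax", "adagrad",
        "nadam", "ftrl"} (family-default learning rates unless overridden).
    reverse_sequence : bool
        Read the sequence weakest-decoy-first (backwards), so the
        informative low-energy head — and not the zero padding — sits next
        to the final hidden state the dense stack reads. Feature order on
        disk stays ascending-energy either way.
    epochs, batch_size, learning_rate, clip_norm, seed
        Training-loop controls; identical seeds give identical weights and
        predictions.
    """

    def __init__(
        self,
        feature_columns=("energy", "irms"),
        sequence_length=1000,
        recurrent_units=32,
        dense_layers=(2,),
        optimizer="adam",
        learning_rate=None,
        epochs=30,
        batch_size=16,
        clip_norm=5.0,
        reverse_sequence=True,
        seed=0,
    ):
        self.feature_columns = feature_columns
        self.sequence_length = sequence_length
        self.recurrent_units = recurrent_units
        self.dense_layers = dense_layers
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.clip_norm = clip_norm
        self.reverse_sequence = reverse_sequence
        self.seed = seed

    # -- data preparation ---------------------------------------------------

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], MetricsTable):
            X = features_from_tables(X, self.feature_columns, self.sequence_length)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_items, sequence_length, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        return X

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        xn = (X - self.norm_mean_) / self.norm_std_
        # Feed the sequence weakest-first so the low-energy head is read last.
        return xn[:, ::-1, :] if self.reverse_sequence else xn

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = self._as_array(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain exactly two classes")
        if int(self.dense_layers[-1]) != 2:
            raise ValueError("dense_layers must end in the 2-way output")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        y_idx = np.searchsorted(self.classes_, y)

        self.norm_mean_ = X.reshape(-1, X.shape[2]).mean(axis=0)
        self.norm_std_ = X.reshape(-1, X.shape[2]).std(axis=0)
        self.norm_std_ = np.where(self.norm_std_ < 1e-8, 1.0, self.norm_std_)
        xn = self._normalize(X)

        rng = np.random.default_rng(self.seed)
        layers = (int(self.recurrent_units), *(int(w) for w in self.dense_layers))
        self.n_features_in_ = X.shape[2]
        params = _init_params(self.n_features_in_, layers, rng)
        n_dense = len(layers) - 1
        opt = make_optimizer(self.optimizer, self.learning_rate)

        n = len(xn)
        batch = min(int(self.batch_size), n)
        self.loss_curve_ = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                sel = order[start : start + batch]
                probs, cache = _forward(xn[sel], params, n_dense)
                p_true = np.clip(probs[np.arange(len(sel)), y_idx[sel]], 1e-12, None)
                epoch_loss += float(-np.log(p_true).sum())
                grads = _backward(xn[sel], y_idx[sel], probs, cache, params, n_dense)
                _clip_global_norm(grads, self.clip_norm)
                opt.step(params, grads)
            self.loss_curve_.append(epoch_loss / n)
        self.params_ = params
        self.n_dense_ = n_dense
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._as_array(X)
        if X.shape[2] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[2]}"
            )
        xn = self._normalize(X)
        probs, _ = _forward(xn, self.params_, self.n_dense_)
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (second) class."""
        return self.predict_proba(X)[:, 1]

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "params_")
        spec = {"format_version": 1, "params": self.get_params()}
        np.savez(
            path,
            spec_json=json.dumps(spec),
            classes=self.classes_,
            norm_mean=self.norm_mean_,
            norm_std=self.norm_std_,
            n_features_in=self.n_features_in_,
            n_dense=self.n_dense_,
            **{f"weight_{k}": v for k, v in self.params_.items()},
        )

    @classmethod
    def load(cls, path) -> "RecurrentPairClassifier":
        with np.load(path, allow_pickle=False) as data:
            spec = json.loads(str(data["spec_json"]))
            params = {k: tuple(v) if isinstance(v, list) else v for k, v in spec["params"].items()}
            model = cls(**params)
            model.classes_ = data["classes"]
            model.norm_mean_ = data["norm_mean"]
            model.norm_std_ = data["norm_std"]
            model.n_features_in_ = int(data["n_features_in"])
            model.n_dense_ = int(data["n_dense"])
            model.params_ = {
                k.removeprefix("weight_"): data[k]
                for k in data.files
                if k.startswith("weight_")
            }
        return model


# ---------------------------------------------------------------------------
# Cross-validation and model search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldROC:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ROCResult:
    folds: tuple[FoldROC, ...]
    mean_auc: float
    accuracy: float

    @property
    def aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.folds])


def _roc_auc(y_true: np.ndarray, scores: np.ndarray) -> FoldROC:
    if np.allclose(scores, scores[0]):
        # Degenerate constant scores: chance-level curve by convention.
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        return FoldROC(fpr, tpr, 0.5)
    fpr, tpr, _ = roc_curve(y_true, scores)
    return FoldROC(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def cross_validate(
    X,
    y,
    estimator: RecurrentPairClassifier | None = None,
    folds: int = 10,
    shuffle_seed: int = 0,
) -> ROCResult:
    """Stratified k-fold ROC analysis with seeded data shuffling.

    Per fold, the ROC curve sweeps the predicted interaction probability;
    AUC is the trapezoidal area. Also reports the pooled accuracy at the
    0.5 threshold.
    """
    estimator = estimator if estimator is not None else RecurrentPairClassifier()
    X = estimator._as_array(X)
    y = np.asarray(y)
    if folds > len(y):
        raise ValueError("more folds than items")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=shuffle_seed)
    fold_rocs, correct, total = [], 0, 0
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = clone(estimator)
        model.set_params(seed=estimator.seed + k)
        model.fit(X[train_idx], y[train_idx])
        positive = model.classes_[1]
        scores = model.decision_scores(X[test_idx])
        fold_rocs.append(_roc_auc(y[test_idx] == positive, scores))
        pred = np.where(scores >= 0.5, model.classes_[1], model.classes_[0])
        correct += int(np.sum(pred == y[test_idx]))
        total += len(test_idx)
    mean_auc = float(np.mean([f.auc for f in fold_rocs]))
    return ROCResult(tuple(fold_rocs), mean_auc, correct / total)


def model_search(
    X,
    y,
    optimizers: Sequence[str] = OPTIMIZERS,
    layer_candidates: Sequence[Sequence[int]] = LAYER_CANDIDATES,
    epoch_grid: Sequence[int] = tuple(range(10, 201, 10)),
    base: RecurrentPairClassifier | None = None,
    seed: int = 0,
    validation_fraction: float = 0.25,
):
    """Grid search over optimizer x layer structure x epochs on a fixed split.

    Returns the results table (one row per candidate, ranked by validation
    accuracy; stable sort, so grid order breaks ties) and the best
    parameter dict.
    """
    if not optimizers or not layer_candidates or not epoch_grid:
        raise ValueError("grids must be non-empty")
    base = base if base is not None else RecurrentPairClassifier()
    X = base._as_array(X)
    y = np.asarray(y)
    X_train, X_val, y_train, y_val = train_test_split(
        X, y, test_size=validation_fraction, stratify=y, random_state=seed
    )
    rows = []
    for opt in optimizers:
        for layers in layer_candidates:
            layers = tuple(int(w) for w in layers)
            for epochs in epoch_grid:
                model = clone(base)
                model.set_params(
                    optimizer=opt,
                    recurrent_units=layers[0],
                    dense_layers=layers[1:],
                    epochs=int(epochs),
                    seed=seed,
                )
                model.fit(X_train, y_train)
                acc = float(np.mean(model.predict(X_val) == y_val))
                rows.append(
                    {
                        "optimizer": opt,
                        "layers": "-".join(str(w) for w in layers),
                        "epochs": int(epochs),
                        "accuracy": acc,
                    }
                )
    table = pd.DataFrame(rows)
    best_row = table.iloc[int(np.argmax(table["accuracy"].to_numpy()))]
    best = {
        "optimizer": best_row["optimizer"],
        "layers": tuple(int(w) for w in best_row["layers"].split("-")),
        "epochs": int(best_row["epochs"]),
        "accuracy": float(best_row["accuracy"]),
    }
    table = table.sort_values("accuracy", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    return table, best
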