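"""The ontology-constrained multilayer perceptron.

The network is a plain fully-connected MLP whose hidden layers are sized by
the layer schema (one neuron per ontology term).  All connections exist; the
structured penalty

    L_GO = sum_l || W^(l) * (1 - C^(l)) ||_F^2

pushes the weights that do not correspond to ontology links ("noGO"
connections) toward zero, weighted by a hyperparameter alpha in the loss

    L = sum_i sum_k ( -y_ik log yhat_ik ) + alpha * L_GO .

L1/L2 penalties over the same hidden-layer weights are provided for
comparison.  Everything is implemented on numpy arrays with explicit
backpropagation; gradients are validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import train_test_split

from .ontology import LayerSchema

PROB_FLOOR = 1e-12  # floor inside log() of the cross-entropy


@dataclass
class NetworkParameters:
    """Per-layer weights and biases; the last entry is the output layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    def copy(self) -> "NetworkParameters":
        return NetworkParameters([w.copy() for w in self.weights],
                                 [b.copy() for b in self.biases])


@dataclass
class TrainingConfig:
    alpha: float = 0.0
    regularizer: str = "go"          # go | l1 | l2 | none
    optimizer: str = "adam"          # adam | sgd
    learning_rate: float = 0.001
    momentum: float = 0.9
    dropout_rate: float = 0.6
    epochs: int = 600
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularizer not in {"go", "l1", "l2", "none"}:
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.optimizer not in {"adam", "sgd"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.regularizer == "none":
            self.alpha = 0.0


@dataclass
class ExpressionDataset:
    """Samples x probes expression with integer class labels.

    ``mean``/``std`` hold the standardization statistics (per probe); they
    are fitted on the training split and reused on held-out data.
    """

    X: np.ndarray
    y: np.ndarray
    probe_ids: tuple[str, ...]
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    class_names: tuple[str, ...] | None = None

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.y.size else 0

    def standardized(self, stats_from: "ExpressionDataset | None" = None) -> "ExpressionDataset":
        """Return a column-standardized copy (zero mean, unit sd).

        When ``stats_from`` is given its statistics are applied instead of
        refitting — the leak-free path for a test split.
        """
        if stats_from is not None and stats_from.mean is not None:
            mean, std = stats_from.mean, stats_from.std
        else:
            mean = self.X.mean(axis=0)
            std = self.X.std(axis=0)
            std = np.where(std == 0, 1.0, std)
        return ExpressionDataset((self.X - mean) / std, self.y, self.probe_ids,
                                 mean=mean, std=std, class_names=self.class_names)

    def split(self, test_fraction: float = 0.2, seed: int = 0,
              standardize: str = "train") -> tuple["ExpressionDataset", "ExpressionDataset"]:
        """Stratified train/test split preserving class frequencies.

        ``standardize`` is ``"train"`` (fit on the training split, apply to
        both — the default, leak-free), ``"global"`` (fit on everything
        before splitting) or ``"none"``.
        """
        idx = np.arange(len(self.y))
        tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                                  stratify=self.y)
        tr.sort(); te.sort()
        src = self.standardized() if standardize == "global" else self
        a = ExpressionDataset(src.X[tr], src.y[tr], self.probe_ids,
                              mean=src.mean, std=src.std, class_names=self.class_names)
        b = ExpressionDataset(src.X[te], src.y[te], self.probe_ids,
                              mean=src.mean, std=src.std, class_names=self.class_names)
        if standardize == "train":
            a = a.standardized()
            b = b.standardized(stats_from=a)
        return a, b


def init_network(schema: LayerSchema, seed: int = 0) -> NetworkParameters:
    """He-initialized weights (variance 2 / fan_in), zero biases."""
    rng = np.random.default_rng(seed)
    sizes = [len(schema.probe_order), *schema.layer_sizes, schema.n_outputs]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkParameters(weights, biases)


def _output_activation(z: np.ndarray) -> np.ndarray:
    if z.shape[1] == 1:  # binary head: single logistic unit
        return 1.0 / (1.0 + np.exp(-z))
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: NetworkParameters,
    X: np.ndarray,
    train_mode: bool = False,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass.

    Returns ``(activations, probs)`` where ``activations[0]`` is the input
    and ``activations[l]`` the ReLU output of hidden layer l; ``probs`` are
    logistic (binary) or softmax (multiclass) class probabilities.  Inverted
    dropout is applied after each hidden layer only in train mode.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.weights[0].shape[0]}")
    acts = [X]
    drop_masks = []
    a = X
    for l in range(params.n_hidden):
        z = a @ params.weights[l] + params.biases[l]
        a = np.maximum(z, 0.0)
        if train_mode and dropout_rate > 0:
            if rng is None:
                raise ValueError("dropout in train mode needs an rng")
            m = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
            a = a * m
            drop_masks.append(m)
        acts.append(a)
    z_out = a @ params.weights[-1] + params.biases[-1]
    probs = _output_activation(z_out)
    if train_mode:
        return acts, probs, z_out, drop_masks
    return acts, probs


def predict_proba(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix of shape (n, K)."""
    _, p = forward(params, X)
    if p.shape[1] == 1:
        return np.hstack([1.0 - p, p])
    return p


def predict(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    return predict_proba(params, X).argmax(axis=1)


def output_logits(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    acts, _ = forward(params, X)
    return acts[-1] @ params.weights[-1] + params.biases[-1]


# ---------------------------------------------------------------------------
# regularizers

def regularizer_go(params: NetworkParameters, masks: Sequence[np.ndarray]) -> float:
    """L_GO: squared Frobenius norm of hidden-layer weights restricted to
    noGO entries.  The output layer's mask is all ones, so it contributes 0;
    biases are excluded."""
    if len(masks) != params.n_hidden:
        raise ValueError(f"{len(masks)} masks for {params.n_hidden} hidden layers")
    total = 0.0
    for w, c in zip(params.weights[:-1], masks):
        if w.shape != c.shape:
            raise ValueError(f"mask shape {c.shape} != weight shape {w.shape}")
        total += float(((w * (1.0 - c)) ** 2).sum())
    return total


def regularizer_l2(params: NetworkParameters) -> float:
    return float(sum((w ** 2).sum() for w in params.weights[:-1]))


def regularizer_l1(params: NetworkParameters) -> float:
    return float(sum(np.abs(w).sum() for w in params.weights[:-1]))


def _penalty(params, masks, config) -> float:
    if config.regularizer == "go":
        return regularizer_go(params, masks)
    if config.regularizer == "l2":
        return regularizer_l2(params)
    if config.regularizer == "l1":
        return regularizer_l1(params)
    return 0.0


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Summed cross-entropy; binary probs may be a single column."""
    p = np.clip(probs, PROB_FLOOR, 1.0)
    if probs.shape[1] == 1:
        p1 = np.clip(probs[:, 0], PROB_FLOOR, 1 - PROB_FLOOR)
        return float(-(y * np.log(p1) + (1 - y) * np.log(1 - p1)).sum())
    return float(-np.log(p[np.arange(len(y)), y]).sum())


def total_loss(params: NetworkParameters, X: np.ndarray, y: np.ndarray,
               masks: Sequence[np.ndarray], config: TrainingConfig) -> float:
    """Summed cross-entropy over the batch plus alpha times the penalty."""
    _, probs = forward(params, X)
    ce = cross_entropy(probs, y)
    if config.alpha == 0.0:
        return ce
    return ce + config.alpha * _penalty(params, masks, config)


# ---------------------------------------------------------------------------
# training

def _loss_gradients(params, X, y, masks, config, rng):
    """Backprop of (batch CE mean + alpha*penalty) w.r.t. all parameters.

    The per-step objective averages the cross-entropy over the batch — the
    convention of the major deep-learning frameworks — so that alpha
    calibrates the penalty against the per-sample loss independently of the
    batch size.
    """
    acts, probs, z_out, drop_masks = forward(
        params, X, train_mode=True, dropout_rate=config.dropout_rate, rng=rng)
    n_out = params.weights[-1].shape[1]
    if n_out == 1:
        delta = (probs - y.reshape(-1, 1)) / len(y)
    else:
        delta = (probs - _one_hot(y, n_out)) / len(y)

    gw = [np.empty_like(w) for w in params.weights]
    gb = [np.empty_like(b) for b in params.biases]
    for l in range(params.n_hidden, -1, -1):
        gw[l] = acts[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ params.weights[l].T
            if config.dropout_rate > 0:
                delta = delta * drop_masks[l - 1]
            delta = delta * (acts[l] > 0)  # ReLU' on the pre-dropout sign

    a = config.alpha
    if a > 0:
        for l in range(params.n_hidden):
            w = params.weights[l]
            if config.regularizer == "go":
                gw[l] += 2.0 * a * w * (1.0 - masks[l])
            elif config.regularizer == "l2":
                gw[l] += 2.0 * a * w
            elif config.regularizer == "l1":
                gw[l] += a * np.sign(w)
    ce = cross_entropy(probs, y)
    return gw, gb, ce


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mw = [np.zeros_like(w) for w in params.weights]
        self.vw = [np.zeros_like(w) for w in params.weights]
        self.mb = [np.zeros_like(b) for b in params.biases]
        self.vb = [np.zeros_like(b) for b in params.biases]

    def step(self, params, gw, gb):
        self.t += 1
        corr = np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for l in range(len(params.weights)):
            for g, m, v, x in ((gw[l], self.mw[l], self.vw[l], params.weights[l]),
                               (gb[l], self.mb[l], self.vb[l], params.biases[l])):
                m *= self.b1; m += (1 - self.b1) * g
                v *= self.b2; v += (1 - self.b2) * g * g
                x -= self.lr * corr * m / (np.sqrt(v) + self.eps)


class _SGDMomentum:
    def __init__(self, params, lr, momentum):
        self.lr, self.mu = lr, momentum
        self.vw = [np.zeros_like(w) for w in params.weights]
        self.vb = [np.zeros_like(b) for b in params.biases]

    def step(self, params, gw, gb):
        for l in range(len(params.weights)):
            self.vw[l] = self.mu * self.vw[l] - self.lr * gw[l]
            self.vb[l] = self.mu * self.vb[l] - self.lr * gb[l]
            params.weights[l] += self.vw[l]
            params.biases[l] += self.vb[l]


def train(
    train_set: ExpressionDataset,
    schema: LayerSchema,
    masks: Sequence[np.ndarray],
    config: TrainingConfig,
) -> tuple[NetworkParameters, list[dict]]:
    """Mini-batch training of the penalized cross-entropy.

    Each step optimizes (CE summed over the batch) + alpha * penalty.  Fully
    reproducible given ``config.seed``, which drives initialization, batch
    shuffling and dropout.  Raises on a non-finite loss.
    """
    params = init_network(schema, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1_000_003)
    opt = (_Adam(params, config.learning_rate) if config.optimizer == "adam"
           else _SGDMomentum(params, config.learning_rate, config.momentum))

    X, y = train_set.X, train_set.y
    n = len(y)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_ce = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            gw, gb, ce = _loss_gradients(params, X[batch], y[batch], masks, config, rng)
            epoch_ce += ce
            opt.step(params, gw, gb)
        pen = config.alpha * _penalty(params, masks, config)
        loss = epoch_ce + pen
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss!r}")
        acc = float((predict(params, X) == y).mean())
        log.append({"epoch": epoch, "cross_entropy": epoch_ce,
                    "penalty": pen, "loss": loss, "train_accuracy": acc})
    return params, log


# ---------------------------------------------------------------------------
# evaluation

def evaluate(params: NetworkParameters, X: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy, precision, recall, F1, MCC and AUC on a held-out split.

    Multiclass metrics are macro-averaged; AUC is one-vs-rest.  AUC is None
    when the split contains a single class.
    """
    proba = predict_proba(params, X)
    pred = proba.argmax(axis=1)
    k = proba.shape[1]
    avg = "binary" if k == 2 else "macro"
    out = {
        "accuracy": float(skmetrics.accuracy_score(y, pred)),
        "precision": float(skmetrics.precision_score(y, pred, average=avg, zero_division=0)),
        "recall": float(skmetrics.recall_score(y, pred, average=avg, zero_division=0)),
        "f1": float(skmetrics.f1_score(y, pred, average=avg, zero_division=0)),
        "mcc": float(skmetrics.matthews_corrcoef(y, pred)),
    }
    if len(np.unique(y)) < 2:
        out["auc"] = None
    elif k == 2:
        out["auc"] = float(skmetrics.roc_auc_score(y, proba[:, 1]))
    else:
        out["auc"] = float(skmetrics.roc_auc_score(y, proba, multi_class="ovr", average="macro"))
    return out
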