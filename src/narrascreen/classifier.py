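"""Feedforward pair-similarity network and reference-vote narrative classifier.

The network maps a Hadamard pair feature to a similarity probability:
input -> 400 (ReLU) -> 50 (ReLU) -> 1 (sigmoid), trained with Adam
(lr 1e-4), batch size 32, binary cross-entropy, at most 50 epochs, and early
stopping after 3 epochs without validation-loss improvement on a stratified
20% validation split. Implemented directly on numpy so training is exactly
reproducible from the spec seed.

A single narrative is classified by pairing its embedding with every train
reference of each class, averaging the predicted pair similarities per
class, and taking the argmax (ties go to class 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .pairs import PairExample, hadamard_feature, pairs_as_arrays

_SIGMOID_EPS = 1e-12


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training recipe for the pair classifier."""

    input_dim: int = 1536
    hidden_dims: tuple[int, ...] = (400, 50)
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_dims or any(h <= 0 for h in self.hidden_dims):
            raise ValidationError("hidden_dims must be non-empty positive ints")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError("validation_fraction must be in (0, 1)")
        if self.input_dim <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValidationError("dimensions, batch size and epochs must be > 0")


@dataclass
class TrainedModel:
    """Fitted network: spec, layer parameters, and the training trace."""

    spec: ClassifierSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_log: list[dict[str, float]] = field(default_factory=list)
    stopped_epoch: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _SIGMOID_EPS, 1.0 - _SIGMOID_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _init_params(
    spec: ClassifierSpec, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    dims = [spec.input_dim, *spec.hidden_dims, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        # He initialization, suited to the ReLU hidden layers
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(
    X: np.ndarray, weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return (probabilities, per-layer activations incl. input)."""
    activations = [X]
    h = X
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        activations.append(h)
    logits = h @ weights[-1] + biases[-1]
    return _sigmoid(logits).ravel(), activations


def _stratified_split(
    y: np.ndarray, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, val); validation stratified by pair label."""
    train_idx, val_idx = [], []
    for label in (0.0, 1.0):
        members = np.flatnonzero(y == label)
        members = rng.permutation(members)
        n_val = max(1, int(round(len(members) * validation_fraction)))
        if n_val >= len(members):
            raise ValidationError(
                "not enough examples of one label to hold out validation data"
            )
        val_idx.append(members[:n_val])
        train_idx.append(members[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_pair_classifier(
    pairs: Sequence[PairExample] | tuple[np.ndarray, np.ndarray],
    spec: ClassifierSpec,
) -> TrainedModel:
    """Fit the pair-similarity network with the spec's training recipe.

    ``pairs`` may be PairExample objects or a pre-stacked ``(X, y)`` tuple.
    Training stops at ``max_epochs`` or when validation loss has not strictly
    improved for ``early_stop_patience`` consecutive epochs; final-epoch
    weights are kept.
    """
    if isinstance(pairs, tuple):
        X, y = pairs
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
    else:
        X, y = pairs_as_arrays(pairs)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValidationError(
            f"feature dimension {X.shape[-1] if X.ndim == 2 else '?'} does "
            f"not match spec input_dim {spec.input_dim}"
        )
    labels = np.unique(y)
    if not np.array_equal(labels, [0.0, 1.0]):
        raise ValidationError(
            f"training requires both pair labels, got {labels.tolist()}"
        )

    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx = _stratified_split(y, spec.validation_fraction, rng)
    X_train, y_train = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    weights, biases = _init_params(spec, rng)
    params = weights + biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    adam_t = 0

    n_layers = len(weights)
    best_val = np.inf
    epochs_since_improve = 0
    log: list[dict[str, float]] = []
    stopped_epoch = 0

    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        for start in range(0, len(order), spec.batch_size):
            batch = order[start : start + spec.batch_size]
            xb, yb = X_train[batch], y_train[batch]
            p, activations = _forward(xb, weights, biases)
            epoch_loss += _bce(p, yb) * len(batch)

            # backprop: d(BCE)/d(logit) = p - y
            delta = ((p - yb) / len(batch))[:, None]
            grads_w = [np.empty(0)] * n_layers
            grads_b = [np.empty(0)] * n_layers
            for layer in range(n_layers - 1, -1, -1):
                grads_w[layer] = activations[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (
                        activations[layer] > 0.0
                    )

            adam_t += 1
            grads = grads_w + grads_b
            for i, (p_arr, g) in enumerate(zip(params, grads)):
                m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
                v_state[i] = beta2 * v_state[i] + (1 - beta2) * g * g
                m_hat = m_state[i] / (1 - beta1**adam_t)
                v_hat = v_state[i] / (1 - beta2**adam_t)
                p_arr -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        train_loss = epoch_loss / len(X_train)
        val_p, _ = _forward(X_val, weights, biases)
        val_loss = _bce(val_p, y_val)
        log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        stopped_epoch = epoch

        if val_loss < best_val:  # any strict decrease counts (min_delta = 0)
            best_val = val_loss
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= spec.early_stop_patience:
                break

    return TrainedModel(
        spec=spec,
        weights=weights,
        biases=biases,
        training_log=log,
        stopped_epoch=stopped_epoch,
    )


def pair_similarities(model: TrainedModel, Z: np.ndarray) -> np.ndarray:
    """Similarity probabilities for a batch of pair features."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    if Z.shape[1] != model.spec.input_dim:
        raise ValidationError(
            f"feature dimension {Z.shape[1]} does not match model input_dim "
            f"{model.spec.input_dim}"
        )
    p, _ = _forward(Z, model.weights, model.biases)
    return np.clip(p, _SIGMOID_EPS, 1.0 - _SIGMOID_EPS)


def pair_similarity(model: TrainedModel, z: np.ndarray) -> float:
    """Similarity probability in (0, 1) for one pair feature."""
    z = np.asarray(z)
    if z.ndim != 1:
        raise ValidationError("pair_similarity expects a single 1-D feature")
    return float(pair_similarities(model, z[None, :])[0])


@dataclass(frozen=True)
class Prediction:
    label: int
    margin: float
    class_scores: tuple[float, float]  # (score_0, score_1)


def classify_narrative(
    model: TrainedModel,
    test_vec: np.ndarray,
    references: Mapping[int, np.ndarray],
) -> Prediction:
    """Reference-vote classification of a single narrative embedding.

    score_c = mean pair similarity of the test vector against class c's
    reference embeddings; predict 1 iff score_1 >= score_0.
    """
    test_vec = np.asarray(test_vec, dtype=np.float64)
    scores = {}
    for cls_label in (0, 1):
        refs = np.atleast_2d(np.asarray(references.get(cls_label, ()),
                                        dtype=np.float64))
        if refs.size == 0:
            raise ValidationError(f"reference class {cls_label} is empty")
        if refs.shape[1] != test_vec.shape[0]:
            raise ValidationError(
                f"reference class {cls_label}: dimension {refs.shape[1]} "
                f"does not match test vector {test_vec.shape[0]}"
            )
        features = refs * test_vec  # row-wise Hadamard products
        scores[cls_label] = float(np.mean(pair_similarities(model, features)))
    margin = scores[1] - scores[0]
    return Prediction(
        label=1 if margin >= 0.0 else 0,
        margin=margin,
        class_scores=(scores[0], scores[1]),
    )


# ---------------------------------------------------------------------------
# Persistence: one .npz container with an embedded JSON header
# ---------------------------------------------------------------------------

_ARTIFACT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    header = {
        "artifact_version": _ARTIFACT_VERSION,
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden_dims": list(model.spec.hidden_dims),
            "learning_rate": model.spec.learning_rate,
            "batch_size": model.spec.batch_size,
            "max_epochs": model.spec.max_epochs,
            "early_stop_patience": model.spec.early_stop_patience,
            "validation_fraction": model.spec.validation_fraction,
            "seed": model.spec.seed,
        },
        "stopped_epoch": model.stopped_epoch,
        "training_log": model.training_log,
    }
    arrays = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(Path(path), **arrays)


def load_model(path: str | Path, expected_input_dim: int | None = None) -> TrainedModel:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("artifact_version") != _ARTIFACT_VERSION:
            raise ValidationError("unsupported model artifact version")
        spec_dict = dict(header["spec"])
        spec_dict["hidden_dims"] = tuple(spec_dict["hidden_dims"])
        spec = ClassifierSpec(**spec_dict)
        if expected_input_dim is not None and spec.input_dim != expected_input_dim:
            raise ValidationError(
                f"model input_dim {spec.input_dim} does not match expected "
                f"{expected_input_dim}"
            )
        n_layers = len(spec.hidden_dims) + 1
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
    return TrainedModel(
        spec=spec,
        weights=weights,
        biases=biases,
        training_log=header["training_log"],
        stopped_epoch=header["stopped_epoch"],
    )
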