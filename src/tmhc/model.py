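"""Feed-forward binary contact classifier.

A six-hidden-layer fully connected network with leaky-ReLU activations and a
sigmoid output, trained with Adam (lr 1e-4) on binary cross-entropy in
mini-batches of 256 for a fixed number of epochs. Weights are initialised
from the Xavier-uniform distribution and every gradient is clipped
element-wise to [-1, 1] before the update.

For 40-dim structure-derived features a *static* fully connected linear layer
projects the input to 192 dimensions so the same network serves both feature
sets; "static" means the projection is Xavier-initialised once and excluded
from optimisation (a trainable variant is available via configuration).

The network is small enough that plain numpy forward/backward passes train it
in seconds on one CPU; no GPU framework is involved.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple
import logging

import numpy as np

from .errors import ModelConfigError, ModelFormatError
from .features import CF_DIM, SDF_DIM, ScalerParams, apply_scaler, fit_scaler
from .features import PairFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainedContactModel",
    "init_model",
    "train",
    "train_contact_model",
    "predict_scores",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1
_N_HIDDEN = 6


@dataclasses.dataclass
class ModelConfig:
    hidden_sizes: Tuple[int, ...] = (64, 48, 32, 24, 16, 8)
    leaky_slope: float = 0.01
    learning_rate: float = 1e-4
    batch_size: int = 256
    epochs: int = 400
    grad_clip: Tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    input_projection: str = "none"  # "none" | "static_40_to_192"
    trainable_projection: bool = False

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != _N_HIDDEN:
            raise ModelConfigError(
                f"expected {_N_HIDDEN} hidden layers, got {len(self.hidden_sizes)}"
            )
        if any(h <= 0 for h in self.hidden_sizes):
            raise ModelConfigError("hidden layer widths must be positive")
        if self.learning_rate <= 0:
            raise ModelConfigError("learning rate must be positive")
        if self.batch_size < 1:
            raise ModelConfigError("batch size must be >= 1")
        if self.input_projection not in ("none", "static_40_to_192"):
            raise ModelConfigError(
                f"unknown input projection {self.input_projection!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["grad_clip"] = list(self.grad_clip)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        d["grad_clip"] = tuple(d["grad_clip"])
        return cls(**d)


@dataclasses.dataclass
class TrainedContactModel:
    config: ModelConfig
    input_dim: int
    weights: List[Tuple[np.ndarray, np.ndarray]]  # (W out x in, b out)
    projection: Optional[Tuple[np.ndarray, np.ndarray]]
    scaler: Optional[ScalerParams] = None
    feature_kind: Optional[str] = None
    loss_trace: List[float] = dataclasses.field(default_factory=list)
    grad_extrema: List[Tuple[float, float]] = dataclasses.field(default_factory=list)

    @property
    def expected_width(self) -> int:
        return self.input_dim


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_model(config: ModelConfig, input_dim: Optional[int] = None) -> TrainedContactModel:
    """Deterministically initialise an untrained model from ``config.seed``.

    ``input_dim`` defaults to 40 when the static projection is enabled and
    192 otherwise.
    """
    if input_dim is None:
        input_dim = SDF_DIM if config.input_projection == "static_40_to_192" else CF_DIM
    rng = np.random.default_rng(config.seed)
    projection = None
    first_in = input_dim
    if config.input_projection == "static_40_to_192":
        projection = (_xavier(rng, CF_DIM, input_dim), np.zeros(CF_DIM))
        first_in = CF_DIM
    weights: List[Tuple[np.ndarray, np.ndarray]] = []
    fan_in = first_in
    for width in config.hidden_sizes:
        weights.append((_xavier(rng, width, fan_in), np.zeros(width)))
        fan_in = width
    weights.append((_xavier(rng, 1, fan_in), np.zeros(1)))  # output layer
    return TrainedContactModel(config, input_dim, weights, projection)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    model: TrainedContactModel, X: np.ndarray
) -> Tuple[np.ndarray, List[np.ndarray], List[np.ndarray]]:
    """Returns (logits, per-layer inputs, per-hidden pre-activations)."""
    slope = model.config.leaky_slope
    h = X
    if model.projection is not None:
        Wp, bp = model.projection
        h = h @ Wp.T + bp
    inputs = [h]
    preacts: List[np.ndarray] = []
    for W, b in model.weights[:-1]:
        z = h @ W.T + b
        preacts.append(z)
        h = np.where(z > 0, z, slope * z)
        inputs.append(h)
    W_out, b_out = model.weights[-1]
    logits = (inputs[-1] @ W_out.T + b_out).ravel()
    return logits, inputs, preacts


def predict_scores(model: TrainedContactModel, X: np.ndarray) -> np.ndarray:
    """Sigmoid contact scores in (0, 1); X must already be scaled."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.expected_width:
        raise ModelConfigError(
            f"input has width {X.shape[1] if X.ndim == 2 else '?'}, "
            f"model expects {model.expected_width}"
        )
    logits, _, _ = _forward(model, X)
    return _sigmoid(logits)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train(
    model: TrainedContactModel,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[ModelConfig] = None,
) -> TrainedContactModel:
    """Train in place with Adam/BCE per the fixed recipe; returns the model.

    Mini-batch order is reshuffled every epoch from the run seed, gradients
    are clipped element-wise to ``config.grad_clip`` before each update, and
    the static input projection (when present) is left untouched unless
    ``trainable_projection`` is set.
    """
    config = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ModelConfigError("X and y row counts differ")
    if X.shape[1] != model.expected_width:
        raise ModelConfigError(
            f"input width {X.shape[1]} != model width {model.expected_width}"
        )
    if len(np.unique(y)) < 2:
        logger.warning("training labels are single-class; model will be degenerate")

    params: List[np.ndarray] = []
    train_proj = model.projection is not None and config.trainable_projection
    if train_proj:
        params.extend(model.projection)
    for W, b in model.weights:
        params.extend((W, b))
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lo, hi = config.grad_clip
    step = 0
    n = X.shape[0]
    slope = config.leaky_slope

    for epoch in range(config.epochs):
        rng = np.random.default_rng((config.seed, 1000 + epoch))
        order = rng.permutation(n)
        epoch_losses = []
        gmin, gmax = np.inf, -np.inf
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits, inputs, preacts = _forward(model, xb)
            p = _sigmoid(logits)
            epoch_losses.append(_bce(p, yb))

            grads: List[np.ndarray] = []
            # output layer
            dlogit = ((p - yb) / len(yb))[:, None]  # (B,1)
            W_out, _ = model.weights[-1]
            gW_out = dlogit.T @ inputs[-1]
            gb_out = dlogit.sum(axis=0)
            dh = dlogit @ W_out  # grad wrt last hidden activation
            hidden_grads: List[Tuple[np.ndarray, np.ndarray]] = []
            for l in range(len(model.weights) - 2, -1, -1):
                dz = dh * np.where(preacts[l] > 0, 1.0, slope)
                W, _ = model.weights[l]
                hidden_grads.append((dz.T @ inputs[l], dz.sum(axis=0)))
                dh = dz @ W
            hidden_grads.reverse()
            if train_proj:
                grads.extend((dh.T @ xb, dh.sum(axis=0)))
            for gW, gb in hidden_grads:
                grads.extend((gW, gb))
            grads.extend((gW_out, gb_out))

            step += 1
            for k, (param, grad) in enumerate(zip(params, grads)):
                g = np.clip(grad, lo, hi)
                gmin = min(gmin, float(g.min()))
                gmax = max(gmax, float(g.max()))
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                m_hat = adam_m[k] / (1 - beta1**step)
                v_hat = adam_v[k] / (1 - beta2**step)
                param -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        model.loss_trace.append(float(np.mean(epoch_losses)))
        model.grad_extrema.append((gmin, gmax))
    return model


def train_contact_model(
    features: PairFeatureSet, config: ModelConfig
) -> TrainedContactModel:
    """Fit scaler on the feature set, train, and attach scaler + feature kind."""
    if features.labels is None:
        raise ModelConfigError("feature set has no labels")
    if features.feature_kind == "SDF" and config.input_projection == "none":
        config = dataclasses.replace(config, input_projection="static_40_to_192")
    scaler = fit_scaler(features.X, fitted_on=f"{features.feature_kind} train set")
    model = init_model(config, input_dim=features.X.shape[1])
    train(model, apply_scaler(features.X, scaler), features.labels, config)
    model.scaler = scaler
    model.feature_kind = features.feature_kind
    return model


def save_model(model: TrainedContactModel, path: str | Path) -> None:
    """Serialise to a directory: weights.npz + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for k, (W, b) in enumerate(model.weights):
        arrays[f"W{k}"] = W
        arrays[f"b{k}"] = b
    if model.projection is not None:
        arrays["Wp"], arrays["bp"] = model.projection
    if model.scaler is not None:
        arrays["scaler_min"] = model.scaler.minimum
        arrays["scaler_max"] = model.scaler.maximum
    arrays["loss_trace"] = np.array(model.loss_trace)
    np.savez(path / "weights.npz", **arrays)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "input_dim": model.input_dim,
        "n_layers": len(model.weights),
        "has_projection": model.projection is not None,
        "has_scaler": model.scaler is not None,
        "feature_kind": model.feature_kind,
        "scaler_fitted_on": model.scaler.fitted_on if model.scaler else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedContactModel:
    path = Path(path)
    meta_path = path / "meta.json"
    weights_path = path / "weights.npz"
    if not meta_path.exists() or not weights_path.exists():
        raise ModelFormatError(f"{path}: not a model archive")
    try:
        meta = json.loads(meta_path.read_text())
        arrays = np.load(weights_path)
    except (json.JSONDecodeError, ValueError, OSError) as exc:
        raise ModelFormatError(f"{path}: corrupt model archive: {exc}") from exc
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {meta.get('format_version')} "
            f"!= {MODEL_FORMAT_VERSION}"
        )
    try:
        config = ModelConfig.from_dict(meta["config"])
        weights = [
            (arrays[f"W{k}"], arrays[f"b{k}"]) for k in range(meta["n_layers"])
        ]
        projection = (arrays["Wp"], arrays["bp"]) if meta["has_projection"] else None
        scaler = None
        if meta["has_scaler"]:
            scaler = ScalerParams(
                arrays["scaler_min"], arrays["scaler_max"],
                meta.get("scaler_fitted_on") or "",
            )
        model = TrainedContactModel(
            config, int(meta["input_dim"]), weights, projection, scaler,
            meta.get("feature_kind"), list(arrays["loss_trace"]),
        )
    except KeyError as exc:
        raise ModelFormatError(f"{path}: missing field {exc}") from exc
    return model
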