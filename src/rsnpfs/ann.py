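"""Deep feed-forward PFS regressor trained by L-BFGS.

Architecture: input -> three equally sized fully connected hidden layers,
each followed by a sigmoid activation and layer normalization (zero mean /
unit variance over the layer's units per sample, then learnable per-unit
gain and offset) -> linear output in months. The output layer is linear
because the target is an unbounded positive regression quantity.

Training minimizes MSE, MAE or Huber loss with the limited-memory
quasi-Newton optimizer (scipy's L-BFGS-B), with early termination when a
held-out validation loss stops improving; the parameters of the best
validation checkpoint are returned. Gradients are exact (hand-derived
backpropagation through the sigmoid/layer-norm stack).

Hyperparameter search enumerates hidden widths x loss kinds, repeating
training from fresh random initializations (and freshly built augmented
data, supplied by a caller-provided builder) and keeping the model with the
lowest validation loss seen anywhere in the search.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

_LN_EPS = 1e-5
_LOSSES = ("mse", "mae", "huber")


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimizer settings.

    ``hidden_sizes`` must be three equal widths; the default search grid uses
    widths 5, 10 and 15.
    """

    input_dim: int = 15
    hidden_sizes: tuple[int, int, int] = (5, 5, 5)
    loss_kind: str = "mse"
    huber_delta: float = 1.0
    max_iterations: int = 500
    tolerance: float = 1e-7
    patience: int = 20
    lbfgs_memory: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise ValueError("exactly 3 hidden layers required")
        if len(set(self.hidden_sizes)) != 1:
            raise ValueError("hidden layers must share one width")
        if min(self.hidden_sizes) < 2:
            raise ValueError("hidden width must be >= 2 (layer norm needs >= 2 units)")
        if self.loss_kind not in _LOSSES:
            raise ValueError(f"loss_kind must be one of {_LOSSES}")
        if self.huber_delta <= 0 or self.tolerance <= 0:
            raise ValueError("huber_delta and tolerance must be positive")


def _shapes(cfg: ModelConfig) -> list[tuple[int, ...]]:
    d, h = cfg.input_dim, cfg.hidden_sizes[0]
    shapes: list[tuple[int, ...]] = []
    prev = d
    for _ in range(3):
        shapes += [(h, prev), (h,), (h,), (h,)]  # W, b, gamma, beta
        prev = h
    shapes += [(h,), ()]  # output weights, output bias
    return shapes


def n_parameters(cfg: ModelConfig) -> int:
    return int(sum(np.prod(s) for s in _shapes(cfg)))


def _unpack(theta: np.ndarray, cfg: ModelConfig) -> list[np.ndarray]:
    out, pos = [], 0
    for s in _shapes(cfg):
        size = int(np.prod(s))
        out.append(theta[pos : pos + size].reshape(s))
        pos += size
    if pos != theta.size:
        raise ValueError("parameter vector has wrong length for config")
    return out


def init_parameters(cfg: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Symmetric uniform init scaled by fan-in; gains 1, offsets/biases 0."""
    shapes = _shapes(cfg)
    theta = np.zeros(n_parameters(cfg))
    pos = 0
    for idx, s in enumerate(shapes):
        size = int(np.prod(s))
        if len(s) == 2:  # hidden weight matrix: fan-in = s[1]
            a = 1.0 / np.sqrt(s[1])
            theta[pos : pos + size] = rng.uniform(-a, a, size=size)
        elif idx == len(shapes) - 2:  # output weight vector
            a = 1.0 / np.sqrt(cfg.hidden_sizes[0])
            theta[pos : pos + size] = rng.uniform(-a, a, size=size)
        elif idx % 4 == 2:  # layer-norm gains
            theta[pos : pos + size] = 1.0
        # biases and offsets stay 0
        pos += size
    return theta


def _forward_cached(theta: np.ndarray, x: np.ndarray, cfg: ModelConfig):
    params = _unpack(theta, cfg)
    h = x
    cache = []
    for layer in range(3):
        w, b, gamma, beta = params[4 * layer : 4 * layer + 4]
        a = h @ w.T + b
        z = expit(a)
        mu = z.mean(axis=1, keepdims=True)
        var = z.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        norm = (z - mu) * inv
        cache.append((h, w, gamma, z, norm, inv))
        h = gamma * norm + beta
    w_out, b_out = params[-2], params[-1]
    pred = h @ w_out + b_out
    cache.append((h, w_out))
    return pred, cache


def forward(model_or_theta, x: np.ndarray, config: ModelConfig | None = None) -> np.ndarray:
    """Predicted PFS (months) for one or more 15-feature rows. Deterministic."""
    if isinstance(model_or_theta, TrainedModel):
        theta, cfg = model_or_theta.parameters, model_or_theta.config
    else:
        theta, cfg = np.asarray(model_or_theta, dtype=float), config
        if cfg is None:
            raise ValueError("config required when passing a raw parameter vector")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != cfg.input_dim:
        raise ValueError(f"expected {cfg.input_dim} inputs, got {x.shape[1]}")
    if not np.isfinite(x).all():
        raise ValueError("inputs must be finite")
    pred, _ = _forward_cached(theta, x, cfg)
    return pred


def loss(predictions: np.ndarray, targets: np.ndarray, kind: str = "mse", delta: float = 1.0) -> float:
    """Mean loss over samples: MSE, MAE, or Huber with threshold ``delta``."""
    r = np.asarray(predictions, dtype=float) - np.asarray(targets, dtype=float)
    if kind == "mse":
        return float(np.mean(r**2))
    if kind == "mae":
        return float(np.mean(np.abs(r)))
    if kind == "huber":
        a = np.abs(r)
        per = np.where(a <= delta, 0.5 * r**2, delta * (a - 0.5 * delta))
        return float(np.mean(per))
    raise ValueError(f"unknown loss kind: {kind}")


def _loss_grad(pred: np.ndarray, y: np.ndarray, kind: str, delta: float) -> tuple[float, np.ndarray]:
    r = pred - y
    n = len(r)
    if kind == "mse":
        return float(np.mean(r**2)), 2.0 * r / n
    if kind == "mae":
        return float(np.mean(np.abs(r))), np.sign(r) / n
    a = np.abs(r)
    val = float(np.mean(np.where(a <= delta, 0.5 * r**2, delta * (a - 0.5 * delta))))
    return val, np.clip(r, -delta, delta) / n


def value_and_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray, cfg: ModelConfig) -> tuple[float, np.ndarray]:
    """Loss and exact gradient via backpropagation through the full stack."""
    pred, cache = _forward_cached(theta, x, cfg)
    val, dpred = _loss_grad(pred, np.asarray(y, dtype=float), cfg.loss_kind, cfg.huber_delta)
    if not np.isfinite(val):
        raise TrainingDiverged("non-finite training loss")
    grads: list[np.ndarray] = [None] * (4 * 3 + 2)  # type: ignore[list-item]
    h3, w_out = cache[-1]
    grads[-2] = h3.T @ dpred
    grads[-1] = np.array(dpred.sum())
    dh = np.outer(dpred, w_out)
    for layer in reversed(range(3)):
        h_prev, w, gamma, z, norm, inv = cache[layer]
        dgamma = (dh * norm).sum(axis=0)
        dbeta = dh.sum(axis=0)
        dnorm = dh * gamma
        dz = inv * (
            dnorm
            - dnorm.mean(axis=1, keepdims=True)
            - norm * (dnorm * norm).mean(axis=1, keepdims=True)
        )
        da = dz * z * (1.0 - z)
        grads[4 * layer] = da.T @ h_prev
        grads[4 * layer + 1] = da.sum(axis=0)
        grads[4 * layer + 2] = dgamma
        grads[4 * layer + 3] = dbeta
        dh = da @ w
    flat = np.concatenate([np.atleast_1d(g).ravel() for g in grads])
    return val, flat


@dataclass
class TrainedModel:
    """Trained parameters at the best validation checkpoint.

    ``selection_score`` is the validation loss normalized by the loss of a
    trivial predictor on the same validation set (a skill score in [0, inf);
    lower is better, 1.0 means no better than predicting the center of the
    validation targets). Restarts draw different validation subjects, so the
    raw validation losses are not comparable across restarts while the
    skill scores are; the hyperparameter search selects by score.
    """

    parameters: np.ndarray = field(repr=False)
    config: ModelConfig
    validation_loss: float
    train_loss: float = float("nan")
    n_iterations: int = 0
    selection_score: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return forward(self, x)

    def to_json(self) -> str:
        d = {
            "parameters": self.parameters.tolist(),
            "config": asdict(self.config),
            "validation_loss": self.validation_loss,
            "train_loss": self.train_loss,
            "n_iterations": self.n_iterations,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        cfg = d["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            parameters=np.asarray(d["parameters"], dtype=float),
            config=ModelConfig(**cfg),
            validation_loss=d["validation_loss"],
            train_loss=d["train_loss"],
            n_iterations=d["n_iterations"],
        )


def train(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: ModelConfig,
    init: np.ndarray | None = None,
) -> TrainedModel:
    """Fit by L-BFGS, returning the best validation checkpoint.

    Terminates on gradient tolerance, the iteration cap, or ``patience``
    consecutive validation checks without improvement. Raises
    :class:`TrainingDiverged` if the loss becomes non-finite.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    val_x = np.atleast_2d(np.asarray(val_x, dtype=float))
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if len(train_x) < 1 or len(val_x) < 1:
        raise ValueError("train and validation sets each need >= 1 sample")
    rng = np.random.default_rng(config.seed)
    theta0 = init_parameters(config, rng) if init is None else np.asarray(init, dtype=float)

    def val_loss(theta: np.ndarray) -> float:
        pred, _ = _forward_cached(theta, val_x, config)
        return loss(pred, val_y, config.loss_kind, config.huber_delta)

    state = {"best": theta0.copy(), "best_val": val_loss(theta0), "stale": 0, "iters": 0}

    def callback(intermediate_result):
        theta = np.asarray(intermediate_result.x)
        state["iters"] += 1
        v = val_loss(theta)
        if not np.isfinite(v):
            raise TrainingDiverged("non-finite validation loss")
        if v < state["best_val"]:
            state["best_val"] = v
            state["best"] = theta.copy()
            state["stale"] = 0
        else:
            state["stale"] += 1
            if state["stale"] >= config.patience:
                raise StopIteration

    minimize(
        value_and_grad,
        theta0,
        args=(train_x, train_y, config),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iterations,
            "gtol": config.tolerance,
            "maxcor": config.lbfgs_memory,
            "ftol": 1e-12,
        },
    )
    best = state["best"]
    pred, _ = _forward_cached(best, train_x, config)
    return TrainedModel(
        parameters=best,
        config=config,
        validation_loss=float(state["best_val"]),
        train_loss=loss(pred, train_y, config.loss_kind, config.huber_delta),
        n_iterations=int(state["iters"]),
        selection_score=float(state["best_val"])
        / max(_trivial_loss(val_y, config.loss_kind, config.huber_delta), 1e-12),
    )


def _trivial_loss(targets: np.ndarray, kind: str, delta: float) -> float:
    """Loss of the best constant predictor (mean, or median for MAE)."""
    center = np.median(targets) if kind == "mae" else float(np.mean(targets))
    return loss(np.full(len(targets), center), targets, kind, delta)


def hyperparameter_search(
    configs: list[ModelConfig],
    data_builder,
    n_restarts: int = 50,
    seed: int = 0,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Grid of configurations x random restarts; keeps the global best.

    ``data_builder(rng)`` must return ``(train_x, train_y, val_x, val_y)``
    (or an object with those attributes), freshly drawn per restart so each
    newly initialized model trains on a distinct augmented sample. The
    model with the best (lowest) validation skill score anywhere in the
    search is retained — scores, unlike raw losses, are comparable across
    the freshly drawn validation sets. Every restart is logged in the
    returned trace.
    """
    if not configs:
        raise ValueError("empty configuration grid")
    best: TrainedModel | None = None
    rows = []
    for ci, cfg in enumerate(configs):
        for r in range(n_restarts):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, r))
            rng = np.random.default_rng(ss)
            data = data_builder(rng)
            if isinstance(data, tuple):
                tx, ty, vx, vy = data
            else:
                tx, ty, vx, vy = data.train_x, data.train_y, data.val_x, data.val_y
            run_cfg = replace(cfg, seed=int(ss.generate_state(1)[0] % 2**31))
            row = {
                "config": ci,
                "width": cfg.hidden_sizes[0],
                "loss_kind": cfg.loss_kind,
                "restart": r,
                "n_train": len(tx),
                "n_val": len(vx),
            }
            try:
                model = train(tx, ty, vx, vy, run_cfg)
            except TrainingDiverged:
                row.update({"val_loss": np.nan, "train_loss": np.nan,
                            "selection_score": np.nan, "diverged": True})
                rows.append(row)
                continue
            row.update(
                {
                    "val_loss": model.validation_loss,
                    "train_loss": model.train_loss,
                    "selection_score": model.selection_score,
                    "diverged": False,
                }
            )
            rows.append(row)
            if best is None or model.selection_score < best.selection_score:
                best = model
    if best is None:
        raise TrainingDiverged("every restart diverged")
    return best, pd.DataFrame(rows)
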