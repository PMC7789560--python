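"""C+/C− multilayer-perceptron regressors: training, prediction, RMSE.

Architecture (fixed): input (3 for C−, 7 for C+) → dense 256 (ReLU) →
dense 256 (ReLU) → dropout 0.5 (training only, inverted scaling) →
dense 64 (ReLU) → linear 4. Inputs and outputs are standardized per
feature with statistics from the training split; the loss is mean squared
error on standardized outputs, optimized with Adam. Predictions are
clamped to the distal joint limits before display.

The backend is exchangeable: anything satisfying :class:`MLPBackend` can
stand behind :class:`PredictorModel`; the in-package backend is a compact
numpy implementation chosen for exact seed-level determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .datasets import TrainingDataset
from .kinematics import limits_array

ARCHITECTURE = (256, 256, "dropout", 64)
DROPOUT_RATE = 0.5


@dataclass
class TrainingReport:
    epochs_run: int
    best_epoch: int
    train_loss: list[float]
    val_loss: list[float]


@dataclass
class RmseReport:
    """Root-mean-square prediction error, degrees."""

    per_dof: dict[str, float]
    pooled: float
    n_samples: int
    model_mode: str


@dataclass
class Hyperparameters:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    max_train_rows: int | None = None  # subsample cap (dwell rows are redundant)


class MLPBackend(Protocol):
    def fit(self, x: np.ndarray, y: np.ndarray, hyper: Hyperparameters, seed: int) -> TrainingReport: ...
    def forward(self, x: np.ndarray) -> np.ndarray: ...


def _relu(x):
    return np.maximum(x, 0.0)


class NumpyMLP:
    """Dense 256-256-dropout(0.5)-64-4 regressor with Adam, in numpy."""

    def __init__(self, n_inputs: int):
        self.n_inputs = n_inputs
        self.shapes = [(n_inputs, 256), (256, 256), (256, 64), (64, 4)]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []

    def _init_params(self, rng: np.random.Generator):
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            for fan_in, fan_out in self.shapes
        ]
        self.biases = [np.zeros(fan_out) for _, fan_out in self.shapes]

    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Inference forward pass; with ``dropout_rng``, training pass
        returning the activation cache."""
        w, b = self.weights, self.biases
        h1 = _relu(x @ w[0] + b[0])
        h2 = _relu(h1 @ w[1] + b[1])
        if dropout_rng is not None:
            mask = (dropout_rng.random(h2.shape) >= DROPOUT_RATE) / (1 - DROPOUT_RATE)
            h2d = h2 * mask
        else:
            mask = None
            h2d = h2
        h3 = _relu(h2d @ w[2] + b[2])
        out = h3 @ w[3] + b[3]
        if dropout_rng is None:
            return out
        return out, (x, h1, h2, mask, h2d, h3)

    def _backward(self, cache, d_out):
        x, h1, h2, mask, h2d, h3 = cache
        w = self.weights
        grads_w = [None] * 4
        grads_b = [None] * 4
        grads_w[3] = h3.T @ d_out
        grads_b[3] = d_out.sum(0)
        d3 = (d_out @ w[3].T) * (h3 > 0)
        grads_w[2] = h2d.T @ d3
        grads_b[2] = d3.sum(0)
        d2 = (d3 @ w[2].T) * mask * (h2 > 0)
        grads_w[1] = h1.T @ d2
        grads_b[1] = d2.sum(0)
        d1 = (d2 @ w[1].T) * (h1 > 0)
        grads_w[0] = x.T @ d1
        grads_b[0] = d1.sum(0)
        return grads_w, grads_b

    def fit(self, x: np.ndarray, y: np.ndarray, hyper: Hyperparameters, seed: int) -> TrainingReport:
        rng = np.random.default_rng(seed)
        self._init_params(rng)
        n = len(x)
        idx = rng.permutation(n)
        n_val = max(1, int(round(hyper.val_fraction * n))) if n > 10 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        xt, yt = x[tr_idx], y[tr_idx]
        xv, yv = x[val_idx], y[val_idx]

        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_epoch = 0
        best_params = [p.copy() for p in params]
        tr_losses, val_losses = [], []
        batches = max(1, len(xt) // hyper.batch_size)

        for epoch in range(hyper.max_epochs):
            order = rng.permutation(len(xt))
            ep_loss = 0.0
            for bi in range(batches):
                sl = order[bi * hyper.batch_size : (bi + 1) * hyper.batch_size]
                xb, yb = xt[sl], yt[sl]
                out, cache = self.forward(xb, dropout_rng=rng)
                diff = out - yb
                ep_loss += float((diff**2).mean())
                d_out = 2.0 * diff / diff.size
                gw, gb = self._backward(cache, d_out)
                t += 1
                grads = gw + gb
                params = self.weights + self.biases
                for pi, (p, g) in enumerate(zip(params, grads)):
                    m[pi] = b1 * m[pi] + (1 - b1) * g
                    v[pi] = b2 * v[pi] + (1 - b2) * g * g
                    mh = m[pi] / (1 - b1**t)
                    vh = v[pi] / (1 - b2**t)
                    p -= hyper.learning_rate * mh / (np.sqrt(vh) + eps)
            tr_losses.append(ep_loss / batches)
            if n_val:
                val = float(((self.forward(xv) - yv) ** 2).mean())
            else:
                val = tr_losses[-1]
            val_losses.append(val)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"training diverged (loss {val}) at epoch {epoch}"
                )
            if val < best_val - 1e-7:
                best_val = val
                best_epoch = epoch
                best_params = [p.copy() for p in self.weights + self.biases]
            elif epoch - best_epoch >= hyper.patience:
                break
        self.weights = best_params[:4]
        self.biases = best_params[4:]
        return TrainingReport(
            epochs_run=len(tr_losses),
            best_epoch=best_epoch,
            train_loss=tr_losses,
            val_loss=val_losses,
        )


@dataclass
class PredictorModel:
    """A trained C+ or C− regressor with its standardization statistics."""

    mode: str
    net: NumpyMLP
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    seed: int
    report: TrainingReport | None = None
    clamp: bool = True

    @property
    def input_width(self) -> int:
        return 7 if self.mode == "C+" else 3

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Distal angles (deg) for one row or a batch; dropout inactive,
        outputs clamped to the distal joint limits."""
        x = np.asarray(x, float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.input_width:
            raise ValueError(
                f"input width {x2.shape[1]} does not match mode {self.mode} "
                f"(expected {self.input_width})"
            )
        z = (x2 - self.x_mean) / self.x_std
        out = self.net.forward(z) * self.y_std + self.y_mean
        if self.clamp:
            lim = limits_array()[3:]
            out = np.clip(out, lim[:, 0], lim[:, 1])
        return out[0] if single else out


def train(
    dataset: TrainingDataset,
    hyper: Hyperparameters | None = None,
    seed: int = 0,
) -> PredictorModel:
    """Train a predictor on an in-zone-filtered dataset (deterministic per seed)."""
    hyper = hyper or Hyperparameters()
    if dataset.n_samples == 0:
        raise ValueError("cannot train on an empty dataset")
    x, y = dataset.inputs, dataset.outputs
    if hyper.max_train_rows and len(x) > hyper.max_train_rows:
        sub = np.random.default_rng(seed).permutation(len(x))[: hyper.max_train_rows]
        sub.sort()
        x, y = x[sub], y[sub]
    x_mean, x_std = x.mean(0), x.std(0)
    x_std[x_std < 1e-9] = 1.0
    y_mean, y_std = y.mean(0), y.std(0)
    y_std[y_std < 1e-9] = 1.0
    net = NumpyMLP(x.shape[1])
    report = net.fit((x - x_mean) / x_std, (y - y_mean) / y_std, hyper, seed)
    return PredictorModel(
        mode=dataset.mode,
        net=net,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        seed=seed,
        report=report,
    )


def offline_rmse(model: PredictorModel, dataset: TrainingDataset) -> RmseReport:
    """Pooled and per-DoF RMSE (deg) of the model on a dataset.

    Pooled RMSE is the root of the mean squared error over all
    (sample, DoF) pairs, so pooled² = mean(per-DoF RMSE²).
    """
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    if dataset.mode != model.mode:
        raise ValueError(
            f"dataset mode {dataset.mode} does not match model mode {model.mode}"
        )
    pred = model.predict(dataset.inputs)
    err2 = (pred - dataset.outputs) ** 2
    from .datasets import DISTAL_COLS

    per_dof = {c: float(np.sqrt(err2[:, j].mean())) for j, c in enumerate(DISTAL_COLS)}
    return RmseReport(
        per_dof=per_dof,
        pooled=float(np.sqrt(err2.mean())),
        n_samples=dataset.n_samples,
        model_mode=model.mode,
    )


def save_model(model: PredictorModel, path: str | Path) -> None:
    """Single-archive save: npz with weight arrays + JSON schema string."""
    path = Path(path)
    schema = {
        "mode": model.mode,
        "seed": model.seed,
        "shapes": model.net.shapes,
        "architecture": list(ARCHITECTURE),
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.net.biases)})
    arrays.update(
        x_mean=model.x_mean, x_std=model.x_std,
        y_mean=model.y_mean, y_std=model.y_std,
        schema=np.frombuffer(json.dumps(schema).encode(), dtype=np.uint8),
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> PredictorModel:
    """Load a saved model; rejects any non-conforming architecture."""
    data = np.load(path)
    schema = json.loads(bytes(data["schema"].tobytes()).decode())
    net = NumpyMLP(7 if schema["mode"] == "C+" else 3)
    net.weights = [data[f"w{i}"] for i in range(4)]
    net.biases = [data[f"b{i}"] for i in range(4)]
    for (fi, fo), w in zip(net.shapes, net.weights):
        if w.shape != (fi, fo):
            raise ValueError(
                f"architecture mismatch: expected {(fi, fo)}, got {w.shape}"
            )
    return PredictorModel(
        mode=schema["mode"],
        net=net,
        x_mean=data["x_mean"],
        x_std=data["x_std"],
        y_mean=data["y_mean"],
        y_std=data["y_std"],
        seed=schema["seed"],
    )
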