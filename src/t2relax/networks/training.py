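"""Training strategies, losses, inference and checkpoints.

Two training strategies are supported for either architecture:

supervised
    Mean-squared error against the ground-truth (S0, T) maps of a
    synthetic corpus.  The network implicitly learns the Rician noise
    statistics because its noisy inputs are paired with noise-free labels.

self-supervised
    The predicted (S0, T) are pushed through the decay forward model and
    the mean-squared error against the *measured* series is minimised; no
    labels are consumed.  Because the forward model decays to zero while
    Rician magnitudes plateau at a noise floor, this strategy inherits the
    positive T bias of Gaussian least-squares fitting at low SNR.

The 1D network trains on individual pixel decay curves extracted from
every spatial position of every training series; the CNN trains on whole
image series.  Series are split train/validation (default 80/20) for
monitoring only — no early stopping — though the best-epoch weights are
additionally snapshotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..series import ImageSeries, ParameterMap
from ..signal_model import SamplingGrid
from ..synthetic import SyntheticDataset
from .layers import Module
from .models import MLP1D, NetworkConfig, ResidualUNet, build_network
from .optim import AdamW

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "supervised_loss",
    "self_supervised_loss",
    "train_model",
    "predict_parameter_map",
    "extracted_curve_count",
    "save_model",
    "load_model",
]

# T is clipped to this interval (straight-through gradient) inside the
# self-supervised forward model; exp(-eta/T) is ill-posed at T <= 0.
_T_CLIP = (0.01, 100.0)


@dataclass
class TrainingConfig:
    """Strategy and optimisation hyper-parameters.

    ``batch_size`` counts decay curves for nn1d and image series for the
    CNN.  Full-scale reference values: nn1d 5 epochs / batch 10,000; CNN
    1000 epochs / batch 100; AdamW lr 0.002; 80/20 train/validation split.
    """

    strategy: str = "supervised"
    epochs: int = 5
    batch_size: int = 10000
    learning_rate: float = 0.002
    weight_decay: float = 0.01
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("supervised", "self_supervised"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch losses plus the best-epoch snapshot."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    n_train_series: int = 0
    n_val_series: int = 0
    n_train_curves: int | None = None
    best_state: tuple | None = None

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss)) if self.val_loss else -1

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def extracted_curve_count(n_series: int, shape: tuple[int, int]) -> int:
    """Number of 1D decay curves extracted from a stack of image series."""
    return int(n_series) * int(shape[0]) * int(shape[1])


def supervised_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """MSE over pixels and both (S0, T) channels."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean((pred - truth) ** 2))


def _supervised_grad(pred, truth):
    diff = pred - truth
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


def self_supervised_loss(
    s0: np.ndarray, t: np.ndarray, series: np.ndarray, grid: SamplingGrid
) -> float:
    """Data-consistency MSE between the forward-modelled and measured series."""
    loss, _, _ = _self_supervised_grad(
        np.asarray(s0, float), np.asarray(t, float), np.asarray(series, float), grid.eta
    )
    return loss


def _self_supervised_grad(s0, t, series, eta):
    """Loss plus gradients w.r.t. (s0, t); shapes s0/t (...,), series (..., N)."""
    if s0.shape + (eta.size,) != series.shape:
        raise ValueError(
            f"series shape {series.shape} incompatible with maps {s0.shape}"
        )
    tc = np.clip(t, *_T_CLIP)
    e = np.exp(-eta / tc[..., None])
    resid = s0[..., None] * e - series
    size = resid.size
    loss = float(np.sum(resid**2) / size)
    gs0 = 2.0 * np.sum(resid * e, axis=-1) / size
    gt = 2.0 * np.sum(resid * s0[..., None] * e * eta / tc[..., None] ** 2, axis=-1) / size
    return loss, gs0, gt


def _split_indices(n: int, train_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    return perm[:n_train], perm[n_train:]


def _require_truth(dataset: SyntheticDataset) -> None:
    if dataset.s0 is None or dataset.t is None:
        raise ValueError("supervised training requires a dataset with truth maps")


def _model_grid(model: Module) -> np.ndarray | None:
    return getattr(model, "grid_eta", None)


def train_model(
    model: Module, dataset: SyntheticDataset, config: TrainingConfig
) -> TrainingHistory:
    """Train in place; returns the per-epoch history.

    Fully deterministic for a fixed (model seed, dataset, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    train_idx, val_idx = _split_indices(n, config.train_fraction, rng)
    history = TrainingHistory(
        n_train_series=len(train_idx), n_val_series=len(val_idx)
    )
    model.grid_eta = dataset.grid.eta.copy()
    opt = AdamW(
        model.params(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    eta = dataset.grid.eta
    h, w = dataset.images.shape[1:3]

    if isinstance(model, MLP1D):
        history.n_train_curves = extracted_curve_count(len(train_idx), (h, w))
        x_train, y_train, s_train = _curves(dataset, train_idx)
        x_val, y_val, s_val = _curves(dataset, val_idx)
        for _ in range(config.epochs):
            model.set_training(True)
            perm = rng.permutation(x_train.shape[0])
            losses = []
            for start in range(0, perm.size, config.batch_size):
                sel = perm[start : start + config.batch_size]
                loss = _step_1d(model, opt, x_train[sel], y_train, s_train, sel, eta, config.strategy)
                losses.append(loss)
            history.train_loss.append(float(np.mean(losses)))
            history.val_loss.append(
                _eval_1d(model, x_val, y_val, s_val, eta, config.strategy, config.batch_size)
            )
            _snapshot_best(model, history)
    else:
        x = dataset.images.transpose(0, 3, 1, 2).astype(float)  # (n, N_eta, H, W)
        targets = None
        if config.strategy == "supervised":
            _require_truth(dataset)
            targets = np.stack([dataset.s0, dataset.t], axis=1).astype(float)
        for _ in range(config.epochs):
            model.set_training(True)
            perm = rng.permutation(train_idx.size)
            losses = []
            for start in range(0, perm.size, config.batch_size):
                sel = train_idx[perm[start : start + config.batch_size]]
                loss = _step_cnn(model, opt, x[sel], targets, sel, dataset, eta, config.strategy)
                losses.append(loss)
            history.train_loss.append(float(np.mean(losses)))
            history.val_loss.append(
                _eval_cnn(model, x, targets, val_idx, dataset, eta, config.strategy)
            )
            _snapshot_best(model, history)
    model.set_training(False)
    return history


def _curves(dataset: SyntheticDataset, idx):
    """Flatten selected series into (curves, N_eta) plus per-curve labels."""
    n_eta = dataset.grid.n
    x = dataset.images[idx].reshape(-1, n_eta).astype(float)
    y = None
    if dataset.s0 is not None and dataset.t is not None:
        y = np.stack(
            [dataset.s0[idx].reshape(-1), dataset.t[idx].reshape(-1)], axis=1
        ).astype(float)
    return x, y, x  # measured series doubles as the self-supervision target


def _step_1d(model, opt, xb, y, s, sel, eta, strategy):
    pred = model(xb)
    if strategy == "supervised":
        if y is None:
            raise ValueError("supervised training requires a dataset with truth maps")
        loss, grad = _supervised_grad(pred, y[sel])
    else:
        loss, gs0, gt = _self_supervised_grad(pred[:, 0], pred[:, 1], s[sel], eta)
        grad = np.stack([gs0, gt], axis=1)
    opt.zero_grad()
    model.backward(grad)
    opt.step()
    return loss


def _eval_1d(model, x, y, s, eta, strategy, batch_size):
    model.set_training(False)
    losses = []
    weights = []
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        pred = model(xb)
        if strategy == "supervised":
            losses.append(supervised_loss(pred, y[start : start + batch_size]))
        else:
            losses.append(
                _self_supervised_grad(
                    pred[:, 0], pred[:, 1], s[start : start + batch_size], eta
                )[0]
            )
        weights.append(xb.shape[0])
    return float(np.average(losses, weights=weights))


def _step_cnn(model, opt, xb, targets, sel, dataset, eta, strategy):
    pred = model(xb)
    if strategy == "supervised":
        loss, grad = _supervised_grad(pred, targets[sel])
    else:
        series = np.moveaxis(xb, 1, -1)  # (B, H, W, N_eta)
        loss, gs0, gt = _self_supervised_grad(pred[:, 0], pred[:, 1], series, eta)
        grad = np.stack([gs0, gt], axis=1)
    opt.zero_grad()
    model.backward(grad)
    opt.step()
    return loss


def _eval_cnn(model, x, targets, idx, dataset, eta, strategy):
    model.set_training(False)
    losses = []
    for i in idx:
        pred = model(x[i : i + 1])
        if strategy == "supervised":
            losses.append(supervised_loss(pred, targets[i : i + 1]))
        else:
            series = np.moveaxis(x[i : i + 1], 1, -1)
            losses.append(
                _self_supervised_grad(pred[:, 0], pred[:, 1], series, eta)[0]
            )
    return float(np.mean(losses))


def _snapshot_best(model, history: TrainingHistory) -> None:
    if history.best_epoch == len(history.val_loss) - 1:
        history.best_state = (
            model.state(),
            [b.copy() for b in model.buffers()],
        )


def restore_best(model: Module, history: TrainingHistory) -> None:
    """Load the best-validation-epoch snapshot back into the model."""
    if history.best_state is None:
        raise ValueError("history carries no snapshot")
    params, buffers = history.best_state
    model.load_state(params)
    for dst, src in zip(model.buffers(), buffers):
        dst[...] = src


def predict_parameter_map(
    model: Module, series: ImageSeries, clip_t: tuple[float, float] | None = None
) -> ParameterMap:
    """Run inference on one image series, returning (S0, T) maps.

    The 1D network is applied per pixel, the CNN per series.  If the model
    was trained, its sampling grid must match the series grid.  Optional
    ``clip_t`` clips the T map at evaluation time (off by default; range
    restriction is normally learned from the training data).
    """
    grid_eta = _model_grid(model)
    if grid_eta is not None and (
        grid_eta.size != series.grid.n
        or not np.allclose(grid_eta, series.grid.eta, atol=1e-8)
    ):
        raise ValueError(
            f"grid mismatch: model eta {np.round(grid_eta, 3)} vs "
            f"series eta {np.round(series.grid.eta, 3)}"
        )
    model.set_training(False)
    h, w, n_eta = series.data.shape
    if isinstance(model, MLP1D):
        out = model(series.data.reshape(-1, n_eta).astype(float))
        s0 = out[:, 0].reshape(h, w)
        t = out[:, 1].reshape(h, w)
    else:
        out = model(series.data.transpose(2, 0, 1)[None].astype(float))
        s0, t = out[0, 0], out[0, 1]
    if clip_t is not None:
        t = np.clip(t, *clip_t)
    arch = getattr(model, "config", None)
    return ParameterMap(s0=s0, t=t, method=arch.arch if arch else "network")


def save_model(model: Module, path: str | Path) -> Path:
    """Serialize weights, buffers, config and grid fingerprint to .npz."""
    import json

    path = Path(path)
    cfg = model.config
    arrays = {f"param_{i}": a for i, a in enumerate(model.state())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(model.buffers())})
    grid_eta = _model_grid(model)
    if grid_eta is not None:
        arrays["grid_eta"] = grid_eta
    meta = json.dumps(
        {
            "arch": cfg.arch,
            "n_inputs": cfg.n_inputs,
            "n_outputs": cfg.n_outputs,
            "n_hidden_layers": cfg.n_hidden_layers,
            "hidden_width": cfg.hidden_width,
            "encoder_widths": list(cfg.encoder_widths),
            "kernel": cfg.kernel,
            "n_residual_levels": cfg.n_residual_levels,
        }
    )
    np.savez(path, __config__=np.array(meta), **arrays)
    return path


def load_model(path: str | Path) -> Module:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        meta["encoder_widths"] = tuple(meta["encoder_widths"])
        config = NetworkConfig(**meta)
        model = build_network(config, seed=0)
        n_params = len(model.params())
        model.load_state([data[f"param_{i}"] for i in range(n_params)])
        for i, buf in enumerate(model.buffers()):
            buf[...] = data[f"buffer_{i}"]
        if "grid_eta" in data:
            model.grid_eta = np.asarray(data["grid_eta"])
    return model
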