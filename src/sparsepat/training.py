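"""Training protocol and evaluation for the artifact-removal networks.

Optimisation follows the reference protocol: Adam, initial learning rate
0.005, batch size 4, MSE loss, 150 epochs, with k-fold cross-validation
(k = 10) drawn from the train+validation pool while the 10% test split
stays held out.  The best checkpoint is the one with the highest
validation SSIM seen across all folds and epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .models import MSDNet
from .nn.autodiff import Tensor, mse_loss
from .nn.optim import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train_model",
    "kfold_train",
    "predict",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.005
    batch_size: int = 4
    epochs: int = 150
    k_folds: int = 10
    seed: int = 0
    loss: str = "mse"
    lr_plateau_decay: bool = False  # halve lr when val SSIM stalls 10 epochs

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.loss != "mse":
            raise ValueError("only the MSE loss is supported")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)  # one entry per step
    epoch_train_loss: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)  # one entry per epoch
    val_loss: list[float] = field(default_factory=list)


def _as_batch(x: np.ndarray) -> np.ndarray:
    """(N, H, W) -> (N, 1, H, W) float32."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("expected (N, H, W) image stacks")
    return x[:, None, :, :]


def predict(model: MSDNet, inputs: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Run the network in eval mode over an (N, H, W) stack."""
    xb = _as_batch(inputs)
    was_training = model.training
    model.eval()
    outs = []
    for start in range(0, xb.shape[0], batch_size):
        out = model(Tensor(xb[start : start + batch_size]))
        outs.append(out.data[:, 0])
    model.train(was_training)
    return np.concatenate(outs, axis=0)


def train_model(
    model: MSDNet,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    cfg: TrainConfig,
    val_inputs: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    epoch_callback=None,
) -> TrainHistory:
    """Adam/MSE training loop; returns the full step/epoch history."""
    if train_inputs.shape[0] == 0:
        raise ValueError("empty training set")
    xb = _as_batch(train_inputs)
    yb = _as_batch(train_targets)
    rng = rng or np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    stall = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(xb.shape[0])
        model.train()
        epoch_losses = []
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            out = model(Tensor(xb[idx]))
            loss = mse_loss(out, yb[idx])
            loss.backward()
            opt.step()
            history.train_loss.append(float(loss.data))
            epoch_losses.append(float(loss.data))
        history.epoch_train_loss.append(float(np.mean(epoch_losses)))
        if val_inputs is not None and val_inputs.shape[0] > 0:
            preds = predict(model, val_inputs)
            ssims = [
                metrics.ssim(p, g, mode="windowed")
                for p, g in zip(preds, val_targets)
            ]
            history.val_ssim.append(float(np.mean(ssims)))
            history.val_loss.append(float(np.mean((preds - val_targets) ** 2)))
            if cfg.lr_plateau_decay:
                if len(history.val_ssim) > 1 and history.val_ssim[-1] <= max(
                    history.val_ssim[:-1]
                ):
                    stall += 1
                    if stall >= 10:
                        opt.lr *= 0.5
                        stall = 0
                else:
                    stall = 0
        if epoch_callback is not None:
            epoch_callback(_epoch, model, history)
    return history


def kfold_train(
    inputs: np.ndarray,
    targets: np.ndarray,
    model_builder,
    cfg: TrainConfig,
) -> dict:
    """k-fold cross-validation over the given pool.

    The pool is shuffled once with ``cfg.seed`` and partitioned into
    ``k_folds`` disjoint validation folds.  Each fold trains a fresh model
    (``model_builder()``) for ``cfg.epochs`` epochs; the returned "best"
    checkpoint is the state with the highest validation SSIM across all
    folds and epochs.
    """
    n = inputs.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if n < cfg.k_folds:
        raise ValueError(f"need at least k_folds={cfg.k_folds} samples, got {n}")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cfg.k_folds)
    histories: list[TrainHistory] = []
    best = {"ssim": -np.inf, "state": None, "fold": -1, "epoch": -1}
    for k, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        model = model_builder()
        fold_rng = np.random.default_rng(cfg.seed + 1000 + k)

        def snapshot(epoch: int, mdl: MSDNet, hist: TrainHistory, fold: int = k) -> None:
            if hist.val_ssim and hist.val_ssim[-1] > best["ssim"]:
                best.update(
                    ssim=hist.val_ssim[-1],
                    state=mdl.state_dict(),
                    fold=fold,
                    epoch=epoch,
                )

        hist = train_model(
            model,
            inputs[train_idx],
            targets[train_idx],
            cfg,
            val_inputs=inputs[val_idx],
            val_targets=targets[val_idx],
            rng=fold_rng,
            epoch_callback=snapshot,
        )
        histories.append(hist)
    return {"histories": histories, "best": best, "folds": folds}


def evaluate(
    model: MSDNet, inputs: np.ndarray, targets: np.ndarray
) -> metrics.MetricsReport:
    """Per-image SSIM/PSNR/MAE/MSE of the model outputs on a test stack."""
    if inputs.shape[0] == 0:
        raise ValueError("empty test set")
    preds = predict(model, inputs)
    return metrics.compute_report(preds, np.asarray(targets, dtype=np.float64))
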