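"""Single-stage training loop: Adam on per-voxel binary cross entropy with
best-training-loss checkpointing and early stopping."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, TrainingDivergenceError
from .nets.models import SegModel
from .nets.optim import Adam, bce_from_logits

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow common practice for this task family: Adam at 1e-4,
    mini-batches of 20 slices, up to 200 epochs with early stopping on the
    training loss.  The loss is binary cross entropy; the checkpoint kept is
    the one with the lowest epoch training loss, not the final weights.
    """

    learning_rate: float = 1e-4
    batch_size: int = 20
    max_epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")


def train_stage_model(
    model: SegModel,
    slices_nhwc: np.ndarray,
    labels_nhw: np.ndarray,
    cfg: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> SegModel:
    """Train one 2D segmentation model on a stack of slice/label pairs.

    Slices are shuffled each epoch; the epoch loss is the sample-weighted
    mean of the mini-batch losses.  After each epoch the weights are
    checkpointed if the loss is the lowest seen so far; training stops at
    ``max_epochs`` or after ``early_stop_patience`` epochs without
    improvement, and the *checkpointed* weights are restored before return.
    """
    if slices_nhwc.shape[0] == 0:
        raise ConfigurationError("empty training set")
    x = np.ascontiguousarray(np.moveaxis(slices_nhwc, 3, 1), dtype=np.float32)
    y = np.ascontiguousarray(labels_nhw, dtype=np.float32)[:, None]
    n = x.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)

    best_loss = math.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    history: list[float] = []
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        total = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(x[idx], training=True)
            loss, dlogits = bce_from_logits(logits, y[idx])
            if not math.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        epoch_loss = total / n
        history.append(epoch_loss)
        log.info("epoch %d: bce=%.5f", epoch, epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                log.info("early stop at epoch %d (best bce=%.5f)", epoch, best_loss)
                break
    assert best_state is not None
    model.load_state_arrays(best_state)
    model.history = history  # type: ignore[attr-defined]
    model.best_loss = best_loss  # type: ignore[attr-defined]
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model
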