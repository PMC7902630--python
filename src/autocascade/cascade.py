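"""Three-stage auto-context cascade over orthogonal slicing planes.

Stage 1 segments one slicing orientation of the raw volume.  Its reassembled
3D output is binarized and reduced to its largest 3D connected component,
then stacked as an extra input channel for stage 2, which slices along a
different orientation — and likewise for stage 3.  Each stage therefore sees
the raw intensities plus the (post-processed) posterior masks of all
predecessors: 2D networks, but with injected 3D context.  The final stage's
post-processed mask is the system output, so it always has at most one
connected component — the structural prior that distinguishes the target
from disconnected look-alike confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ContractError
from .nets.models import SegModel, SegModelConfig, build_model, predict_stack
from .training import TrainConfig, train_stage_model
from .volume_io import (
    ANATOMICAL_AXES,
    IntensityNormalizer,
    LabelVolume,
    SliceStack,
    Volume,
    apply_normalizer,
    assemble_volume,
    extract_slices,
    fit_normalizer,
)

log = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class CascadeConfig:
    """Pipeline hyperparameters; stage s uses in_channels = s."""

    stage_configs: list[SegModelConfig]
    axis_order: tuple[str, str, str] = ("coronal", "sagittal", "axial")
    threshold: float = 0.5
    connectivity: int = 26

    def __post_init__(self) -> None:
        if sorted(self.axis_order) != sorted(ANATOMICAL_AXES):
            raise ConfigurationError(
                f"axis_order must be a permutation of {ANATOMICAL_AXES}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(f"threshold must be in (0,1), got {self.threshold}")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError(f"connectivity must be 6, 18 or 26")
        if len(self.stage_configs) != 3:
            raise ConfigurationError("need exactly three stage configs")
        for s, cfg in enumerate(self.stage_configs, start=1):
            if cfg.in_channels != s:
                raise ConfigurationError(
                    f"stage {s} must have in_channels={s}, got {cfg.in_channels}"
                )

    @classmethod
    def build(cls, arch: str = "unet", depth: int = 4, base_filters: int = 16,
              input_size: int = 256, **kwargs) -> "CascadeConfig":
        stages = [
            SegModelConfig(arch=arch, in_channels=s, depth=depth,
                           base_filters=base_filters,
                           input_size=(input_size, input_size))
            for s in (1, 2, 3)
        ]
        return cls(stage_configs=stages, **kwargs)


@dataclass
class CascadeModel:
    stages: list  # three per-stage models (SegModel or duck-typed stand-ins)
    config: CascadeConfig
    normalizer: IntensityNormalizer | None = None

    def __post_init__(self) -> None:
        for s, m in enumerate(self.stages, start=1):
            if m.config.in_channels != s:
                raise ConfigurationError(
                    f"stage {s} model has in_channels={m.config.in_channels}"
                )


# ---------------------------------------------------------------------------
# mask-level primitives
# ---------------------------------------------------------------------------

def binarize(p: Volume, threshold: float = 0.5) -> LabelVolume:
    """Strict thresholding: voxel = 1 iff probability > threshold."""
    data = np.asarray(p.data)
    if data.min() < 0.0 or data.max() > 1.0:
        raise ContractError("binarize expects probabilities in [0,1]")
    return LabelVolume(data=(data > threshold).astype(np.uint8),
                       spacing=p.spacing, axes=p.axes)


def largest_component(m: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Keep only the largest 3D connected component of a binary mask.

    Ties in component size are broken by the smallest first-voxel index in
    grid scan order.  An empty mask is returned unchanged (with a warning) —
    a total miss propagates rather than aborting the pipeline.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    fg = np.asarray(m.data).astype(bool)
    labeled, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    if n == 0:
        log.warning("largest_component: empty mask")
        return LabelVolume(data=np.zeros_like(m.data, dtype=np.uint8),
                           spacing=m.spacing, axes=m.axes)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    candidates = np.flatnonzero(sizes == sizes.max())
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        flat = labeled.ravel()
        chosen = min(candidates, key=lambda lbl: int(np.argmax(flat == lbl)))
    return LabelVolume(data=(labeled == chosen).astype(np.uint8),
                       spacing=m.spacing, axes=m.axes)


def stack_stage_input(image: Volume, priors: Sequence[LabelVolume],
                      axis: str) -> SliceStack:
    """Slice image and prior masks along ``axis`` into a multichannel stack.

    Channel order is [image, prior_1, prior_2, ...] in stage order; channel
    count is 1 + len(priors), i.e. the auto-context X of the consuming stage.
    """
    if len(priors) > 2:
        raise ContractError(f"at most two prior masks supported, got {len(priors)}")
    stacks = [extract_slices(image, axis)]
    for i, prior in enumerate(priors):
        if prior.shape != image.shape:
            raise ContractError(
                f"prior {i + 1} shape {prior.shape} does not match image {image.shape}"
            )
        stacks.append(extract_slices(prior, axis))
    return SliceStack(
        slices=np.concatenate([s.slices for s in stacks], axis=3), axis=axis
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def run_cascade(cm: CascadeModel, raw: Volume,
                return_probs: bool = False) -> LabelVolume | tuple[LabelVolume, Volume]:
    """Full three-stage inference on one (already resampled) volume.

    Optionally also returns the final stage's assembled probability volume
    (pre-threshold), which ROC-AUC evaluation needs.
    """
    image = apply_normalizer(cm.normalizer, raw) if cm.normalizer else raw
    priors: list[LabelVolume] = []
    prob_vol: Volume | None = None
    for s, (model, axis) in enumerate(zip(cm.stages, cm.config.axis_order), start=1):
        try:
            stack = stack_stage_input(image, priors, axis)
            probs = predict_stack(model, stack)
            prob_vol = assemble_volume(probs, raw)
        except ContractError as exc:
            raise ContractError(f"stage {s}: {exc}") from exc
        mask = binarize(prob_vol, cm.config.threshold)
        mask = largest_component(mask, cm.config.connectivity)
        if not mask.data.any():
            log.warning("stage %d produced an empty mask", s)
        priors.append(mask)
    final = priors[-1]
    return (final, prob_vol) if return_probs else final


# ---------------------------------------------------------------------------
# sequential stage training
# ---------------------------------------------------------------------------

def _as_pairs(train) -> list[tuple[Volume, LabelVolume]]:
    pairs = []
    for item in train:
        if hasattr(item, "image") and hasattr(item, "label"):
            pairs.append((item.image, item.label))
        else:
            pairs.append(tuple(item))
    if not pairs:
        raise ConfigurationError("need at least one training pair")
    shapes = {p[0].shape for p in pairs}
    if len(shapes) != 1:
        raise ConfigurationError(f"training volumes have mixed shapes: {shapes}")
    return pairs


def _stage_seed(base_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence((base_seed, stage)).generate_state(1)[0] % (2**31))


def train_cascade(
    train,
    cfg: CascadeConfig,
    train_cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
    normalizer: IntensityNormalizer | None = None,
) -> CascadeModel:
    """Train the three stages strictly sequentially.

    The intensity normalizer is fitted on the training volumes (unless one
    fitted elsewhere is supplied).  For stage s > 1, the prior channels fed
    during training are the post-processed *predictions* of the already
    trained stages on the training volumes — never the ground-truth masks —
    so training and inference see the same input distribution.
    """
    pairs = _as_pairs(train)
    if normalizer is None:
        normalizer = fit_normalizer([img for img, _ in pairs])
    images = [apply_normalizer(normalizer, img) for img, _ in pairs]
    labels = [lab for _, lab in pairs]
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    priors: list[list[LabelVolume]] = [[] for _ in pairs]
    stages: list[SegModel] = []
    for s in range(3):
        axis = cfg.axis_order[s]
        x_parts, y_parts = [], []
        for img, lab, pri in zip(images, labels, priors):
            x_parts.append(stack_stage_input(img, pri, axis).slices)
            y_parts.append(extract_slices(lab, axis).slices[..., 0])
        x_all = np.concatenate(x_parts, axis=0)
        y_all = np.concatenate(y_parts, axis=0)

        model = build_model(cfg.stage_configs[s], seed=_stage_seed(train_cfg.seed, s))
        stage_cfg = TrainConfig(
            learning_rate=train_cfg.learning_rate, batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            early_stop_patience=train_cfg.early_stop_patience,
            seed=_stage_seed(train_cfg.seed, 100 + s),
        )
        ckpt = checkpoint_dir / f"stage{s + 1}.npz" if checkpoint_dir else None
        train_stage_model(model, x_all, y_all, stage_cfg, checkpoint_path=ckpt)
        stages.append(model)

        if s < 2:  # post-processed predictions become the next stage's priors
            for i, (img, pri) in enumerate(zip(images, priors)):
                stack = stack_stage_input(img, pri, axis)
                prob_vol = assemble_volume(predict_stack(model, stack), img)
                mask = largest_component(binarize(prob_vol, cfg.threshold),
                                         cfg.connectivity)
                priors[i] = pri + [mask]
    return CascadeModel(stages=stages, config=cfg, normalizer=normalizer)
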