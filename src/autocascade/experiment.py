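"""Cross-validation, baseline-vs-cascade comparison and reporting.

Splits are always specimen-level: every slice of a volume lives in the fold
of its volume, and the intensity normalizer is refitted per fold from the
training volumes only, so no test information leaks into preprocessing or
training.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cascade import (
    CascadeConfig,
    CascadeModel,
    binarize,
    largest_component,
    run_cascade,
    train_cascade,
)
from .errors import ConfigurationError, DegenerateDataError
from .metrics import MetricsReport, evaluate_pair, wilcoxon_paired
from .nets.models import SegModel, SegModelConfig, build_model, predict_stack
from .training import TrainConfig, train_stage_model
from .volume_io import (
    IntensityNormalizer,
    LabelVolume,
    Volume,
    apply_normalizer,
    assemble_volume,
    extract_slices,
    fit_normalizer,
)

__all__ = [
    "TrainConfig", "train_stage_model", "FoldAssignment", "make_folds",
    "BaselineModel", "train_baseline", "run_baseline",
    "CrossvalResult", "run_crossval", "ComparisonReport", "compare_frameworks",
    "write_manifest",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    k: int
    mapping: dict  # specimen id -> fold index

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.mapping.items() if f == fold]

    def sizes(self) -> list[int]:
        return [len(self.fold_ids(f)) for f in range(self.k)]


def make_folds(ids: Sequence, k: int, seed: int) -> FoldAssignment:
    """Random balanced specimen-level partition; fold sizes differ by <= 1."""
    ids = list(ids)
    if k > len(ids):
        raise ConfigurationError(f"cannot split {len(ids)} specimens into {k} folds")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("specimen ids must be unique")
    order = list(np.random.default_rng(seed).permutation(len(ids)))
    mapping = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(k=k, mapping=mapping)


# ---------------------------------------------------------------------------
# single-orientation baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """One 2D network on a single slicing orientation, plus largest-component
    post-processing — the non-cascaded reference each architecture is
    compared against (axial orientation by default)."""

    model: SegModel
    axis: str = "axial"
    threshold: float = 0.5
    connectivity: int = 26
    normalizer: IntensityNormalizer | None = None


def train_baseline(
    train,
    seg_cfg: SegModelConfig,
    train_cfg: TrainConfig,
    axis: str = "axial",
    threshold: float = 0.5,
    connectivity: int = 26,
    normalizer: IntensityNormalizer | None = None,
) -> BaselineModel:
    if seg_cfg.in_channels != 1:
        raise ConfigurationError("baseline network takes the raw slice only (X=1)")
    pairs = [(it.image, it.label) if hasattr(it, "image") else tuple(it) for it in train]
    if normalizer is None:
        normalizer = fit_normalizer([img for img, _ in pairs])
    x_parts, y_parts = [], []
    for img, lab in pairs:
        x_parts.append(extract_slices(apply_normalizer(normalizer, img), axis).slices)
        y_parts.append(extract_slices(lab, axis).slices[..., 0])
    model = build_model(seg_cfg, seed=train_cfg.seed)
    train_stage_model(model, np.concatenate(x_parts), np.concatenate(y_parts), train_cfg)
    return BaselineModel(model=model, axis=axis, threshold=threshold,
                         connectivity=connectivity, normalizer=normalizer)


def run_baseline(bm: BaselineModel, raw: Volume,
                 return_probs: bool = False) -> LabelVolume | tuple[LabelVolume, Volume]:
    image = apply_normalizer(bm.normalizer, raw) if bm.normalizer else raw
    probs = predict_stack(bm.model, extract_slices(image, bm.axis))
    prob_vol = assemble_volume(probs, raw)
    mask = largest_component(binarize(prob_vol, bm.threshold), bm.connectivity)
    return (mask, prob_vol) if return_probs else mask


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _pairs_of(data) -> list[tuple[Volume, LabelVolume]]:
    return [(it.image, it.label) if hasattr(it, "image") else tuple(it) for it in data]


def _report_row(rep: MetricsReport, **extra) -> dict:
    return {**extra, **rep.as_dict()}


def summarize(per_volume: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd rows over all volumes, one column per metric."""
    cols = [c for c in MetricsReport.METRIC_NAMES if c in per_volume]
    return pd.DataFrame(
        {"mean": per_volume[cols].mean(), "sd": per_volume[cols].std(ddof=1)}
    )


@dataclass
class CrossvalResult:
    per_volume: pd.DataFrame
    summary: pd.DataFrame
    folds: FoldAssignment
    fold_normalizers: dict[int, IntensityNormalizer]
    models: dict[int, CascadeModel] = field(default_factory=dict, repr=False)


def run_crossval(
    data,
    cfg: CascadeConfig,
    tcfg: TrainConfig,
    k: int = 4,
    seed: int = 0,
    keep_models: bool = False,
) -> CrossvalResult:
    """k-fold specimen-level cross-validation of the full cascade.

    For each fold the normalizer and all three stages are fitted on the
    training folds only; all eight metrics are computed on each held-out
    volume (Hausdorff in mm using its voxel spacing).
    """
    pairs = _pairs_of(data)
    folds = make_folds(list(range(len(pairs))), k, seed)
    rows = []
    fold_norms: dict[int, IntensityNormalizer] = {}
    models: dict[int, CascadeModel] = {}
    for f in range(k):
        test_ids = folds.fold_ids(f)
        train_ids = [i for i in range(len(pairs)) if i not in test_ids]
        train_pairs = [pairs[i] for i in train_ids]
        norm = fit_normalizer([img for img, _ in train_pairs])
        fold_norms[f] = norm
        fold_tcfg = TrainConfig(
            learning_rate=tcfg.learning_rate, batch_size=tcfg.batch_size,
            max_epochs=tcfg.max_epochs, early_stop_patience=tcfg.early_stop_patience,
            seed=int(np.random.SeedSequence((tcfg.seed, f)).generate_state(1)[0] % 2**31),
        )
        cm = train_cascade(train_pairs, cfg, fold_tcfg, normalizer=norm)
        if keep_models:
            models[f] = cm
        for i in test_ids:
            img, gt = pairs[i]
            mask, prob = run_cascade(cm, img, return_probs=True)
            rep = evaluate_pair(mask, gt, prob=prob, spacing=img.spacing)
            rows.append(_report_row(rep, volume=i, fold=f))
    per_volume = pd.DataFrame(rows).sort_values("volume").reset_index(drop=True)
    return CrossvalResult(per_volume=per_volume, summary=summarize(per_volume),
                          folds=folds, fold_normalizers=fold_norms, models=models)


# ---------------------------------------------------------------------------
# baseline vs cascade comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Paired per-volume metrics for the single-orientation baseline and the
    cascade of the same architecture, plus Wilcoxon p-values per metric
    (None when the paired test is degenerate or underpowered)."""

    arch: str
    baseline: pd.DataFrame
    cascade: pd.DataFrame
    table: pd.DataFrame  # metric x {baseline_mean, baseline_sd, cascade_mean, cascade_sd, p}


def compare_frameworks(
    train,
    test,
    arch: str,
    cfg: CascadeConfig,
    tcfg: TrainConfig,
    baseline_axis: str = "axial",
) -> ComparisonReport:
    """Train the baseline and the cascade on the same data and compare them
    volume-by-volume on the held-out set."""
    if cfg.stage_configs[0].arch != arch:
        raise ConfigurationError("cfg.stage_configs arch does not match requested arch")
    test_pairs = _pairs_of(test)

    cm = train_cascade(train, cfg, tcfg)
    bm = train_baseline(train, cfg.stage_configs[0], tcfg, axis=baseline_axis,
                        threshold=cfg.threshold, connectivity=cfg.connectivity,
                        normalizer=cm.normalizer)

    rows_b, rows_c = [], []
    for i, (img, gt) in enumerate(test_pairs):
        mask_b, prob_b = run_baseline(bm, img, return_probs=True)
        rows_b.append(_report_row(
            evaluate_pair(mask_b, gt, prob=prob_b, spacing=img.spacing), volume=i))
        mask_c, prob_c = run_cascade(cm, img, return_probs=True)
        rows_c.append(_report_row(
            evaluate_pair(mask_c, gt, prob=prob_c, spacing=img.spacing), volume=i))
    df_b = pd.DataFrame(rows_b)
    df_c = pd.DataFrame(rows_c)

    table_rows = []
    for metric in MetricsReport.METRIC_NAMES:
        a, b = df_c[metric].to_numpy(float), df_b[metric].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        try:
            p = wilcoxon_paired(a[ok], b[ok])
        except DegenerateDataError:
            p = None
        table_rows.append({
            "metric": metric,
            "baseline_mean": np.nanmean(b), "baseline_sd": np.nanstd(b, ddof=1) if ok.sum() > 1 else np.nan,
            "cascade_mean": np.nanmean(a), "cascade_sd": np.nanstd(a, ddof=1) if ok.sum() > 1 else np.nan,
            "p_value": p,
        })
    return ComparisonReport(arch=arch, baseline=df_b, cascade=df_c,
                            table=pd.DataFrame(table_rows).set_index("metric"))


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, config: dict, seeds: dict,
                   data_arrays: Sequence[np.ndarray] = ()) -> None:
    """Record config, seeds and data hashes alongside a result for replay."""
    hashes = [hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]
              for a in data_arrays]
    Path(path).write_text(yaml.safe_dump(
        {"config": config, "seeds": seeds, "data_sha256_16": hashes},
        sort_keys=False))
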