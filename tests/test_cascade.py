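import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pytest

from autocascade.cascade import (
    CascadeConfig,
    CascadeModel,
    binarize,
    largest_component,
    run_cascade,
    stack_stage_input,
    train_cascade,
)
from autocascade.errors import ConfigurationError, ContractError
from autocascade.nets import SegModelConfig
from autocascade.training import TrainConfig
from autocascade.volume_io import (
    IntensityNormalizer,
    LabelVolume,
    SliceStack,
    Volume,
    extract_slices,
)


def _mask(data):
    return LabelVolume(np.asarray(data, dtype=np.uint8), spacing=(1, 1, 1))


# ---------------------------------------------------------------------------
# exhaustive flood-fill oracle
# ---------------------------------------------------------------------------

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if 0 < abs(i) + abs(j) + abs(k) <= 2],
    26: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """BFS over foreground voxels; components in first-voxel scan order."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.ndindex(*mask.shape):
        if mask[idx] and not seen[idx]:
            comp = []
            q = deque([idx])
            seen[idx] = True
            while q:
                cur = q.popleft()
                comp.append(cur)
                for off in _OFFSETS[connectivity]:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= c < s for c, s in zip(nb, mask.shape)) \
                            and mask[nb] and not seen[nb]:
                        seen[nb] = True
                        q.append(nb)
            comps.append(comp)
    return comps


def oracle_largest(mask: np.ndarray, connectivity: int) -> np.ndarray:
    comps = flood_fill_components(mask, connectivity)
    out = np.zeros_like(mask)
    if not comps:
        return out
    best = max(comps, key=len)  # max() keeps the first (scan-order) on ties
    for idx in best:
        out[idx] = 1
    return out


class TestBinarize:
    def test_strict_inequality_tie_rule(self):
        p = Volume(np.full((2, 2, 2), 0.5), spacing=(1, 1, 1))
        assert not binarize(p, 0.5).data.any()

    def test_values_straddling_threshold(self):
        p = Volume(np.array([[[0.2, 0.7]]]), spacing=(1, 1, 1))
        np.testing.assert_array_equal(binarize(p, 0.5).data, [[[0, 1]]])

    def test_idempotent_on_binary_input(self, rng):
        p = Volume((rng.random((4, 4, 4)) > 0.5).astype(float), spacing=(1, 1, 1))
        once = binarize(p, 0.5)
        twice = binarize(Volume(once.data.astype(float), spacing=(1, 1, 1)), 0.5)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            binarize(Volume(np.full((2, 2, 2), 1.5), spacing=(1, 1, 1)), 0.5)


class TestLargestComponent:
    def test_keeps_bigger_of_two_blobs(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m[1:3, 1:3, 1:3] = 1          # 8 voxels... make it 10
        m[1, 1, 3] = 1
        m[1, 2, 3] = 1
        m[7:8, 7:8, 7:5+8] = 0
        m[7, 7, 4:9] = 1              # 5-voxel line, not touching the blob
        out = largest_component(_mask(m), 26)
        np.testing.assert_array_equal(out.data, oracle_largest(m, 26))
        assert out.data.sum() == 10

    def test_empty_mask_passes_through(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = largest_component(_mask(np.zeros((4, 4, 4))), 26)
        assert not out.data.any()
        assert any("empty" in r.message for r in caplog.records)

    def test_diagonal_voxels_connectivity_dependence(self):
        # offsets (1,1,0): one 26-connected component, two 6-connected ones
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[1, 1, 1] = 1
        m[2, 2, 1] = 1
        assert largest_component(_mask(m), 26).data.sum() == 2
        assert largest_component(_mask(m), 6).data.sum() == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((12, 12, 12)) < 0.15).astype(np.uint8)
        out = largest_component(_mask(m), connectivity)
        np.testing.assert_array_equal(out.data, oracle_largest(m, connectivity))

    def test_idempotent_subset_connected(self, rng):
        m = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        out = largest_component(_mask(m), 26)
        # subset of input
        assert not (out.data & ~m).any()
        # idempotent
        np.testing.assert_array_equal(largest_component(out, 26).data, out.data)
        # output is one component
        assert len(flood_fill_components(out.data, 26)) <= 1


class TestStackStageInput:
    def test_no_priors_reduces_to_extract_slices(self, rng):
        v = Volume(rng.random((6, 6, 6)), spacing=(1, 1, 1))
        np.testing.assert_array_equal(
            stack_stage_input(v, [], "axial").slices,
            extract_slices(v, "axial").slices)

    def test_prior_channel_is_binary(self, rng):
        v = Volume(rng.random((6, 6, 6)), spacing=(1, 1, 1))
        prior = _mask(rng.random((6, 6, 6)) > 0.5)
        stack = stack_stage_input(v, [prior], "coronal")
        assert stack.channels == 2
        assert set(np.unique(stack.slices[..., 1])) <= {0.0, 1.0}

    def test_channel_order_verified_voxelwise(self, rng):
        v = Volume(rng.random((8, 8, 8)), spacing=(1, 1, 1))
        m1 = _mask(rng.random((8, 8, 8)) > 0.5)
        m2 = _mask(rng.random((8, 8, 8)) > 0.5)
        stack = stack_stage_input(v, [m1, m2], "axial")
        ax = v.grid_axis("axial")
        assert stack.slices.shape == (8, 8, 8, 3)
        for k in range(8):
            np.testing.assert_array_equal(stack.slices[k, ..., 0],
                                          np.take(v.data, k, axis=ax))
            np.testing.assert_array_equal(stack.slices[k, ..., 1],
                                          np.take(m1.data, k, axis=ax))
            np.testing.assert_array_equal(stack.slices[k, ..., 2],
                                          np.take(m2.data, k, axis=ax))

    def test_geometry_mismatch_rejected(self, rng):
        v = Volume(rng.random((6, 6, 6)), spacing=(1, 1, 1))
        with pytest.raises(ContractError):
            stack_stage_input(v, [_mask(np.zeros((4, 4, 4)))], "axial")


# ---------------------------------------------------------------------------
# cascade orchestration with stub stage models
# ---------------------------------------------------------------------------

@dataclass
class _StubConfig:
    in_channels: int
    input_size: tuple


class StubModel:
    """Duck-typed stage model emitting a fixed volume's slices as probabilities.

    The stub slices its fixed volume along the grid axis its stage slices
    along, so reassembly reproduces the volume exactly."""

    DEFAULT_AXES = ("sagittal", "coronal", "axial")

    def __init__(self, in_channels, size, emit: np.ndarray, axis: str, record=None):
        self.config = _StubConfig(in_channels, (size, size))
        self.emit = emit.astype(np.float64)
        self.grid_axis = self.DEFAULT_AXES.index(axis)
        self.record = record

    def predict_probs(self, x_nhwc, batch_size=16):
        if self.record is not None:
            self.record.append(x_nhwc.copy())
        return np.moveaxis(self.emit, self.grid_axis, 0)


def _stub_cascade(emits, size, axis_order=("coronal", "sagittal", "axial")):
    stages = [StubModel(s + 1, size, np.asarray(e, dtype=float), axis)
              for s, (e, axis) in enumerate(zip(emits, axis_order))]
    cfg = CascadeConfig(
        stage_configs=[SegModelConfig(arch="unet", in_channels=s, depth=1,
                                      base_filters=2, input_size=(size, size))
                       for s in (1, 2, 3)],
        axis_order=tuple(axis_order),
    )
    return CascadeModel(stages=stages, config=cfg, normalizer=None)


class TestRunCascade:
    def test_oracle_stubs_reproduce_ground_truth_exactly(self, tiny_sample):
        gt = tiny_sample.label.data.astype(float)
        cm = _stub_cascade([gt, gt, gt], size=gt.shape[0])
        out = run_cascade(cm, tiny_sample.image)
        np.testing.assert_array_equal(out.data, tiny_sample.label.data)

    def test_disconnected_blob_removed_before_stage_two(self, tiny_sample):
        gt = tiny_sample.label.data.astype(float)
        noisy = gt.copy()
        noisy[1:3, 1:3, 1:3] = 1.0  # far-corner blob, disconnected from target
        record = []
        cm = _stub_cascade([noisy, gt, gt], size=gt.shape[0])
        cm.stages[1].record = record
        out = run_cascade(cm, tiny_sample.image)
        # stage 2 sees the prior mask in channel 2: blob must be gone
        stage2_prior = record[0][..., 1]
        assert stage2_prior[1:3, 1:3, 1:3].sum() == 0
        np.testing.assert_array_equal(out.data, tiny_sample.label.data)

    def test_all_zero_stubs_propagate_empty_mask(self, tiny_sample, caplog):
        zero = np.zeros_like(tiny_sample.label.data, dtype=float)
        cm = _stub_cascade([zero, zero, zero], size=zero.shape[0])
        with caplog.at_level(logging.WARNING):
            out = run_cascade(cm, tiny_sample.image)
        assert not out.data.any()
        assert sum("empty" in r.message for r in caplog.records) >= 3

    def test_final_output_single_component_for_any_axis_order(self, tiny_sample, rng):
        blobs = (rng.random(tiny_sample.label.data.shape) < 0.02).astype(float)
        for order in (("coronal", "sagittal", "axial"),
                      ("axial", "coronal", "sagittal"),
                      ("sagittal", "axial", "coronal")):
            cm = _stub_cascade([blobs, blobs, blobs], size=blobs.shape[0],
                               axis_order=order)
            out = run_cascade(cm, tiny_sample.image)
            assert set(np.unique(out.data)) <= {0, 1}
            assert len(flood_fill_components(out.data, 26)) <= 1


class TestCascadeConfig:
    def test_stage_channel_progression_enforced(self):
        cfgs = [SegModelConfig(arch="unet", in_channels=1, depth=1,
                               base_filters=2, input_size=(32, 32))] * 3
        with pytest.raises(ConfigurationError):
            CascadeConfig(stage_configs=list(cfgs))

    def test_axis_order_must_be_permutation(self):
        with pytest.raises(ConfigurationError):
            CascadeConfig.build(depth=1, base_filters=2, input_size=32,
                                axis_order=("axial", "axial", "coronal"))


class TestTrainCascade:
    def test_single_epoch_produces_three_checkpoints(self, tmp_path, tiny_spec):
        from autocascade.phantom import generate_dataset
        data = generate_dataset(tiny_spec, n=2, seed=3)
        cfg = CascadeConfig.build(arch="unet", depth=2, base_filters=4, input_size=32)
        tcfg = TrainConfig(max_epochs=1, batch_size=16, seed=0)
        cm = train_cascade(data, cfg, tcfg, checkpoint_dir=tmp_path)
        for s in (1, 2, 3):
            assert (tmp_path / f"stage{s}.npz").exists()
            assert (tmp_path / f"stage{s}.yaml").exists()
        assert isinstance(cm.normalizer, IntensityNormalizer)

    def test_deterministic_retraining_is_bit_identical(self, tiny_spec):
        from autocascade.phantom import generate_dataset
        data = generate_dataset(tiny_spec, n=2, seed=3)
        cfg = CascadeConfig.build(arch="unet", depth=2, base_filters=4, input_size=32)
        tcfg = TrainConfig(max_epochs=1, batch_size=16, seed=0)
        a = train_cascade(data, cfg, tcfg)
        b = train_cascade(data, cfg, tcfg)
        for ma, mb in zip(a.stages, b.stages):
            sa, sb = ma.state_arrays(), mb.state_arrays()
            assert sa.keys() == sb.keys()
            for k in sa:
                np.testing.assert_array_equal(sa[k], sb[k])
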