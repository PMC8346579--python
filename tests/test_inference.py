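"""Sliding-window stitching, region-growing stubs, tree extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayseg import (
    PhantomConfig,
    VolumeGrid,
    dice_coefficient,
    extract_airway_tree,
    generate_phantom,
    plan_sliding_windows,
    predict_volume,
    segment_central_airways,
    segment_lungs,
)
from airwayseg.inference import AggregationState, SeedNotFoundError


class ConstantModel:
    """Size-preserving stub emitting a constant probability."""

    def __init__(self, value):
        self.value = value

    def predict_patch(self, patch):
        return np.full(patch.shape, self.value, dtype=np.float32)

    def output_margin(self, shape):
        return (0, 0, 0)


class CenterCropModel:
    """Stub that outputs the centered crop of its input, like a valid-conv
    network whose prediction equals the image."""

    def __init__(self, margin):
        self.margin = margin

    def predict_patch(self, patch):
        m = self.margin
        return patch[m:-m or None, m:-m or None, m:-m or None]

    def output_margin(self, shape):
        return (self.margin,) * 3


class TestPlan:
    def test_volume_equals_patch_gives_single_window(self):
        plan = plan_sliding_windows((32, 32, 32), (32, 32, 32), 0.5)
        assert len(plan.windows) == 1
        assert plan.windows[0].corner == (0, 0, 0)
        assert not plan.padded

    def test_double_volume_half_overlap_gives_27_windows(self):
        # corners {0, p/2, p} per axis
        plan = plan_sliding_windows((40, 40, 40), (20, 20, 20), 0.5)
        corners = sorted({w.corner[0] for w in plan.windows})
        assert corners == [0, 10, 20]
        assert len(plan.windows) == 27

    def test_final_window_clamped(self):
        plan = plan_sliding_windows((50,) * 3, (20,) * 3, 0.5)
        corners = sorted({w.corner[0] for w in plan.windows})
        assert corners == [0, 10, 20, 30]  # 30 = 50 - 20, clamped

    def test_random_plans_cover_every_voxel(self, rng):
        for _ in range(100):
            shape = tuple(int(rng.integers(10, 40)) for _ in range(3))
            patch = tuple(int(rng.integers(4, s + 1)) for s in shape)
            overlap = float(rng.uniform(0, 0.75))
            plan = plan_sliding_windows(shape, patch, overlap)
            covered = np.zeros(shape, dtype=bool)
            for w in plan.windows:
                covered[w.slices] = True
            assert covered.all()

    def test_oversized_patch_sets_padding_flag(self):
        plan = plan_sliding_windows((16, 16, 16), (20, 20, 20), 0.5)
        assert plan.padded and len(plan.windows) == 1

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            plan_sliding_windows((32,) * 3, (16,) * 3, 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        shape=st.tuples(*[st.integers(6, 40)] * 3),
        frac=st.tuples(*[st.floats(0.2, 1.0)] * 3),
        overlap=st.floats(0.0, 0.9),
    )
    def test_plan_covers_volume_property(self, shape, frac, overlap):
        patch = tuple(max(2, int(round(f * s))) for f, s in zip(frac, shape))
        patch = tuple(min(p, s) for p, s in zip(patch, shape))
        plan = plan_sliding_windows(shape, patch, overlap)
        covered = np.zeros(shape, dtype=bool)
        for w in plan.windows:
            covered[w.slices] = True
        assert covered.all()
        # stride rule: consecutive corners differ by floor(patch*(1-overlap))
        stride = max(1, int(np.floor(patch[0] * (1 - overlap))))
        corners = sorted({w.corner[0] for w in plan.windows})
        for a, b in zip(corners, corners[1:-1] or []):
            assert b - a == stride


class TestPredictVolume:
    def test_constant_model_aggregates_to_constant(self, rng):
        image = VolumeGrid(rng.random((30, 30, 30), dtype=np.float32))
        model = ConstantModel(0.7)
        plan = plan_sliding_windows(image.shape, (12, 12, 12), 0.5)
        prob = predict_volume(model, image, plan)
        assert np.allclose(prob.values, 0.7, atol=1e-6)

    def test_copy_model_reproduces_input_interior(self, rng):
        image = VolumeGrid(rng.random((28, 28, 28), dtype=np.float32))
        model = CenterCropModel(margin=2)
        prob = predict_volume(model, image, overlap=0.5, patch_size=(12, 12, 12))
        # interior voxels see only true image content (reflect padding
        # affects a boundary shell at most `margin` thick)
        inner = (slice(2, -2),) * 3
        assert np.allclose(prob.values[inner], image.values[inner], atol=1e-5)

    def test_counts_cover_every_voxel(self, rng):
        state = AggregationState.for_shape((20, 20, 20))
        plan = plan_sliding_windows((20, 20, 20), (8, 8, 8), 0.5)
        for w in plan.windows:
            state.add(w.corner, np.ones(w.size, dtype=np.float32))
        assert state.counts.min() >= 1

    def test_overlap_idempotence(self, rng):
        image = VolumeGrid(rng.random((30, 30, 30), dtype=np.float32))
        model = CenterCropModel(margin=3)
        a = predict_volume(model, image, overlap=0.5, patch_size=(14, 14, 14))
        b = predict_volume(model, image, overlap=0.75, patch_size=(14, 14, 14))
        assert np.allclose(a.values, b.values, atol=1e-5)

    def test_patch_larger_than_volume_is_padded_through(self, rng):
        image = VolumeGrid(rng.random((10, 10, 10), dtype=np.float32))
        model = ConstantModel(0.25)
        plan = plan_sliding_windows((10, 10, 10), (16, 16, 16), 0.5)
        prob = predict_volume(model, image, plan)
        assert prob.shape == (10, 10, 10)
        assert np.allclose(prob.values, 0.25)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(PhantomConfig(seed=21))


class TestSegmentLungs:
    def test_recovers_phantom_lung_field(self, phantom):
        seg = segment_lungs(phantom.image)
        truth = phantom.lung_mask.values.astype(bool)
        assert dice_coefficient(seg.values, truth) >= 0.9

    def test_uniform_bright_volume_gives_empty_mask(self):
        image = VolumeGrid(np.zeros((20, 20, 20), dtype=np.float32))
        with pytest.warns(UserWarning, match="air"):
            seg = segment_lungs(image)
        assert not seg.values.any()

    def test_output_binary_same_grid(self, phantom):
        seg = segment_lungs(phantom.image)
        assert seg.shape == phantom.image.shape
        assert set(np.unique(seg.values)).issubset({0, 1})


class TestSegmentCentralAirways:
    def test_grown_region_contains_root(self, phantom):
        seg = segment_central_airways(phantom.image)
        root = phantom.root_mask.values.astype(bool)
        covered = (seg.values.astype(bool) & root).sum() / root.sum()
        assert covered >= 0.95

    def test_bright_seed_rejected(self, phantom):
        # a corner voxel lies in the bright body background
        with pytest.raises(ValueError, match="seed"):
            segment_central_airways(phantom.image, seed_point=(0, 0, 0))

    def test_no_seed_found_raises(self):
        image = VolumeGrid(np.zeros((20, 20, 20), dtype=np.float32))
        with pytest.raises(SeedNotFoundError):
            segment_central_airways(image)

    def test_output_is_26_connected(self, phantom):
        from scipy import ndimage

        seg = segment_central_airways(phantom.image)
        _, n = ndimage.label(
            seg.values, structure=ndimage.generate_binary_structure(3, 3)
        )
        assert n == 1


class TestExtractAirwayTree:
    def grid(self, arr):
        return VolumeGrid(np.asarray(arr))

    def test_zero_probability_keeps_central_mask(self):
        shape = (16, 16, 16)
        prob = self.grid(np.zeros(shape, dtype=np.float32))
        lungs = self.grid(np.ones(shape, dtype=np.uint8))
        central = np.zeros(shape, dtype=np.uint8)
        central[2:8, 7:9, 7:9] = 1
        tree = extract_airway_tree(prob, lungs, self.grid(central))
        assert np.array_equal(tree.values, central)

    def test_largest_component_survives(self):
        shape = (20, 20, 20)
        prob = np.zeros(shape, dtype=np.float32)
        prob[2:7, 2:7, 2:7] = 0.9  # 125 voxels
        prob[12:16, 12:16, 12:14] = 0.9  # 32 voxels
        lungs = np.ones(shape, dtype=np.uint8)
        central = np.zeros(shape, dtype=np.uint8)
        tree = extract_airway_tree(
            self.grid(prob), self.grid(lungs), self.grid(central)
        )
        assert tree.values.sum() == 125
        assert tree.values[3, 3, 3] == 1

    def test_probability_outside_lungs_discarded(self):
        shape = (16, 16, 16)
        prob = np.full(shape, 0.99, dtype=np.float32)
        lungs = np.zeros(shape, dtype=np.uint8)
        lungs[:, :8] = 1
        central = np.zeros(shape, dtype=np.uint8)
        tree = extract_airway_tree(
            self.grid(prob), self.grid(lungs), self.grid(central)
        )
        assert not tree.values[:, 8:].any()

    def test_lower_threshold_never_removes_voxels(self, rng):
        shape = (16, 16, 16)
        prob = rng.random(shape).astype(np.float32)
        lungs = (rng.random(shape) > 0.3).astype(np.uint8)
        central = np.zeros(shape, dtype=np.uint8)
        masked = prob * lungs
        high = masked >= 0.5
        low = masked >= 0.1
        assert not (high & ~low).any()

    def test_output_single_connected_component(self, rng):
        from scipy import ndimage

        shape = (20, 20, 20)
        prob = (rng.random(shape) > 0.6).astype(np.float32)
        lungs = np.ones(shape, dtype=np.uint8)
        central = np.zeros(shape, dtype=np.uint8)
        central[0:3, 0:3, 0:3] = 1
        for connectivity, order in ((26, 3), (6, 1)):
            tree = extract_airway_tree(
                self.grid(prob), self.grid(lungs), self.grid(central),
                threshold=0.5, connectivity=connectivity,
            )
            _, n = ndimage.label(
                tree.values, structure=ndimage.generate_binary_structure(3, order)
            )
            assert n == 1

    def test_empty_everything_warns(self):
        shape = (8, 8, 8)
        zeros = np.zeros(shape)
        with pytest.warns(UserWarning, match="empty"):
            tree = extract_airway_tree(
                self.grid(zeros), self.grid(zeros), self.grid(zeros)
            )
        assert not tree.values.any()

    def test_invalid_threshold_rejected(self):
        zeros = self.grid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="threshold"):
            extract_airway_tree(zeros, zeros, zeros, threshold=0.0)
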