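"""Paired geometric transforms: index oracles, binarity, determinism."""

import numpy as np
import pytest

from vesselseg.augmentation import (
    AugmentPlan,
    augment_dataset,
    mirror,
    random_crops,
    random_shift,
    rotations,
)
from vesselseg.io_datasets import SamplePair


def _pair_with_pixel(r, c, size=64):
    truth = np.zeros((size, size), dtype=np.uint8)
    truth[r, c] = 1
    img = np.stack([truth * 200] * 3, axis=-1).astype(np.uint8)
    return SamplePair(img, truth, id="px")


class TestRotations:
    def test_twelve_orientations_at_30_degrees(self, phantom_pair):
        assert len(rotations(phantom_pair, 30.0)) == 12

    def test_full_turn_is_identity_only(self, phantom_pair):
        out = rotations(phantom_pair, 360.0)
        assert len(out) == 1
        assert np.array_equal(out[0].truth, phantom_pair.truth)

    def test_corner_pixel_visits_four_corners(self):
        # 90-degree steps on a 3x3 grid: the on-pixel cycles the corners
        pair = _pair_with_pixel(0, 0, size=3)
        corners = set()
        for rp in rotations(pair, 90.0):
            on = np.argwhere(rp.truth)
            assert len(on) == 1
            corners.add(tuple(on[0]))
        assert corners == {(0, 0), (0, 2), (2, 2), (2, 0)}

    def test_masks_stay_binary(self, phantom_pair):
        for rp in rotations(phantom_pair, 30.0):
            assert set(np.unique(rp.truth)) <= {0, 1}
            assert set(np.unique(rp.fov)) <= {0, 1}

    def test_bad_step_rejected(self, phantom_pair):
        with pytest.raises(ValueError):
            rotations(phantom_pair, 0.0)


class TestMirror:
    def test_involution(self, phantom_pair):
        twice = mirror(mirror(phantom_pair))
        assert np.array_equal(twice.image, phantom_pair.image)
        assert np.array_equal(twice.truth, phantom_pair.truth)

    def test_horizontal_moves_column_zero_to_last(self):
        pair = _pair_with_pixel(5, 0, size=8)
        assert mirror(pair, "horizontal").truth[5, 7] == 1

    def test_vessel_count_preserved(self, phantom_pair):
        assert mirror(phantom_pair).truth.sum() == phantom_pair.truth.sum()


class TestRandomShift:
    def plan(self, lo=20, hi=50):
        return AugmentPlan(shift_min_px=lo, shift_max_px=hi)

    def test_deterministic_given_seed(self, phantom_pair):
        a = random_shift(phantom_pair, self.plan(5, 10), np.random.default_rng(3))
        b = random_shift(phantom_pair, self.plan(5, 10), np.random.default_rng(3))
        assert np.array_equal(a.image, b.image) and a.id == b.id

    def test_known_displacement_moves_pixel(self):
        pair = _pair_with_pixel(25, 25, size=64)
        plan = AugmentPlan(shift_min_px=20, shift_max_px=20)
        # direction random, magnitude fixed at 20: the pixel lands on a corner
        # of the square centered at (25,25) with half-diagonal (20,20)
        out = random_shift(pair, plan, np.random.default_rng(0))
        on = tuple(np.argwhere(out.truth)[0])
        assert on in {(5, 5), (5, 45), (45, 5), (45, 45)}

    def test_zero_magnitude_is_identity(self, phantom_pair):
        plan = AugmentPlan(shift_min_px=0, shift_max_px=0)
        out = random_shift(phantom_pair, plan, np.random.default_rng(1))
        assert np.array_equal(out.truth, phantom_pair.truth)

    def test_oversized_shift_rejected(self, phantom_pair):
        plan = AugmentPlan(shift_min_px=0, shift_max_px=999)
        with pytest.raises(ValueError):
            random_shift(phantom_pair, plan, np.random.default_rng(0))


class TestRandomCrops:
    def test_patch_count_and_size(self, phantom_pair):
        plan = AugmentPlan(n_crops=4, crop_size=32)
        out = random_crops(phantom_pair, plan, np.random.default_rng(0))
        assert len(out) == 4
        assert all(c.truth.shape == (32, 32) for c in out)

    def test_full_frame_crop_is_copy(self, phantom_pair):
        plan = AugmentPlan(n_crops=2, crop_size=64)
        for c in random_crops(phantom_pair, plan, np.random.default_rng(0)):
            assert np.array_equal(c.truth, phantom_pair.truth)

    def test_patches_are_subarrays(self, phantom_pair):
        plan = AugmentPlan(n_crops=3, crop_size=16)
        rng = np.random.default_rng(5)
        for c in random_crops(phantom_pair, plan, rng):
            # every patch must occur somewhere in the source truth
            found = False
            src = phantom_pair.truth
            for r in range(64 - 16 + 1):
                for col in range(64 - 16 + 1):
                    if np.array_equal(src[r : r + 16, col : col + 16], c.truth):
                        found = True
                        break
                if found:
                    break
            assert found


class TestAugmentDataset:
    def test_multiplicity_bookkeeping(self, phantom_pairs_small):
        plan = AugmentPlan(rotation_step_deg=90, n_crops=2, crop_size=32,
                           shift_min_px=2, shift_max_px=4)
        out = augment_dataset(phantom_pairs_small[:2], plan)
        # 2 sources x 4 rotations x 2 (mirror) x 1 shift x 2 crops
        assert len(out) == 2 * 4 * 2 * 1 * 2

    def test_disabled_plan_is_identity(self, phantom_pairs_small):
        plan = AugmentPlan(do_rotate=False, do_mirror=False, do_shift=False, do_crop=False)
        out = augment_dataset(phantom_pairs_small, plan)
        assert [p.id for p in out] == [p.id for p in phantom_pairs_small]

    def test_same_seed_reproducible(self, phantom_pairs_small):
        plan = AugmentPlan(rotation_step_deg=180, n_crops=1, crop_size=32,
                           shift_min_px=2, shift_max_px=6, seed=9)
        a = augment_dataset(phantom_pairs_small[:2], plan)
        b = augment_dataset(phantom_pairs_small[:2], plan)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))
        assert [x.id for x in a] == [y.id for y in b]

    def test_geometry_shared_between_image_and_mask(self):
        # transform a coordinate-grid image and compare against the mask path
        size = 32
        grid = (np.indices((size, size)).sum(axis=0) % 2).astype(np.uint8)
        pair = SamplePair(np.stack([grid * 255] * 3, -1), grid, id="grid")
        plan = AugmentPlan(rotation_step_deg=180, shift_min_px=3, shift_max_px=3,
                           n_crops=1, crop_size=16, seed=4)
        for out in augment_dataset([pair], plan):
            assert np.array_equal((out.image[:, :, 0] > 127).astype(np.uint8), out.truth)
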