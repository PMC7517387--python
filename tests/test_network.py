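"""Architecture contracts: pooling indices, block channel split, shapes,
finiteness, determinism, checkpoint round trip."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesselseg.network import (
    NetworkSpec,
    SegmentationModel,
    build_msffu_net,
    build_unet,
    load_checkpoint,
    max_pool_with_indices,
    predict,
    save_checkpoint,
    unpool_with_indices,
)


def brute_force_pool(x):
    N, C, H, W = x.shape
    out = np.zeros((N, C, H // 2, W // 2), dtype=x.dtype)
    arg = np.zeros((N, C, H // 2, W // 2), dtype=int)
    for n in range(N):
        for c in range(C):
            for i in range(H // 2):
                for j in range(W // 2):
                    win = x[n, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    out[n, c, i, j] = win.max()
                    arg[n, c, i, j] = int(win.argmax())
    return out, arg


class TestPoolUnpool:
    def test_window_value_and_index(self):
        x = np.array([[[[1.0, 3.0], [2.0, 0.0]]]])
        pooled, idx = max_pool_with_indices(x)
        assert pooled[0, 0, 0, 0] == 3.0
        assert idx[0, 0, 0, 0] == 1  # row-major position (0, 1)

    def test_tie_takes_first_row_major(self):
        x = np.full((1, 1, 2, 2), 5.0)
        _, idx = max_pool_with_indices(x)
        assert idx[0, 0, 0, 0] == 0

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        pooled, idx = max_pool_with_indices(x)
        ref_pool, ref_idx = brute_force_pool(x)
        assert np.array_equal(pooled, ref_pool)
        assert np.array_equal(idx, ref_idx)

    def test_unpool_places_value_at_index(self):
        x = np.array([[[[3.0]]]])
        idx = np.array([[[[1]]]], dtype=np.int8)
        out = unpool_with_indices(x, idx)
        assert np.array_equal(out[0, 0], [[0.0, 3.0], [0.0, 0.0]])

    def test_all_zero_input_stays_zero(self):
        out = unpool_with_indices(np.zeros((1, 2, 2, 2)),
                                  np.zeros((1, 2, 2, 2), dtype=np.int8))
        assert not out.any()

    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_nonzeros_are_argmax_positions(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(1, 2, 6, 6))
        pooled, idx = max_pool_with_indices(x)
        up = unpool_with_indices(pooled, idx)
        # exactly one nonzero per window, equal to the window max, at argmax
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    win_x = x[0, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    win_u = up[0, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    assert np.count_nonzero(win_u) <= 1
                    assert win_u.ravel()[win_x.argmax()] == win_x.max()

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            max_pool_with_indices(np.zeros((1, 1, 3, 4)))


class TestMultiscaleBlock:
    def test_channel_split_quarter_half_quarter(self, rng):
        from vesselseg._nn import Tape
        from vesselseg.network import MultiScaleBlock

        blk = MultiScaleBlock(8, 64, NetworkSpec(), np.random.default_rng(0))
        x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)
        t = Tape()
        a = blk.a1(t, x)
        b = blk.b3(t, blk.b_reduce(t, x))
        c = blk.c3b(t, blk.c3a(t, blk.c_reduce(t, x)))
        assert a.shape[1] == 16 and b.shape[1] == 32 and c.shape[1] == 16
        out = blk(Tape(), x)
        assert out.shape == (1, 64, 16, 16)

    def test_indivisible_width_rejected(self):
        from vesselseg.network import MultiScaleBlock

        with pytest.raises(ValueError):
            MultiScaleBlock(8, 30, NetworkSpec(), np.random.default_rng(0))

    def test_output_finite_everywhere(self, rng):
        from vesselseg.network import MultiScaleBlock

        blk = MultiScaleBlock(4, 16, NetworkSpec(), np.random.default_rng(1))
        from vesselseg._nn import Tape

        out = blk(Tape(), rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        assert np.isfinite(out).all()


class TestBuilders:
    def test_depth4_bottleneck_geometry(self):
        # 512 -> 256 -> 128 -> 64 -> 32 at the bottleneck, back to 512 out
        model = build_msffu_net(NetworkSpec(depth=4, base_channels=8), seed=0)
        x = np.random.default_rng(0).uniform(size=(1, 1, 512, 512)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 1, 512, 512)
        assert model.pools[-1].indices.shape[2:] == (32, 32)
        assert np.isfinite(out).all() and out.min() >= 0 and out.max() <= 1

    def test_encoder_channels_double_per_stage(self):
        model = build_msffu_net(NetworkSpec(depth=3, base_channels=16), seed=0)
        widths = [blk2.out_channels for _, blk2 in model.enc_blocks]
        assert widths == [16, 32, 64]

    @pytest.mark.parametrize("depth", [1, 2, 3])
    @pytest.mark.parametrize("base", [8, 16])
    @pytest.mark.parametrize("builder", [build_msffu_net, build_unet], ids=["msffu", "unet"])
    def test_forward_in_unit_interval_across_grid(self, depth, base, builder):
        spec = NetworkSpec(depth=depth, base_channels=base)
        model = builder(spec, seed=1)
        size = 8 * 2**depth
        x = np.random.default_rng(2).normal(size=(1, 1, size, size)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 1, size, size)
        assert np.isfinite(out).all() and out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_input_rejected_with_message(self):
        model = build_msffu_net(NetworkSpec(depth=2, base_channels=8), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 30, 32), dtype=np.float32))

    def test_identical_seed_reproduces_weights(self):
        spec = NetworkSpec(depth=1, base_channels=8)
        a, b = build_msffu_net(spec, seed=5), build_msffu_net(spec, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_parameter_count_positive_and_reported(self):
        model = build_unet(NetworkSpec(depth=1, base_channels=8, block="unet"), seed=0)
        assert model.n_parameters() > 0
        assert f"{model.n_parameters():,}" in model.summary()

    def test_sum_merge_mode_runs(self):
        spec = NetworkSpec(depth=1, base_channels=8, merge_mode="sum")
        model = build_msffu_net(spec, seed=0)
        out = model.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))
        assert out.shape == (1, 1, 16, 16)


@pytest.fixture(scope="module")
def model():
    return build_msffu_net(NetworkSpec(depth=1, base_channels=8), seed=3)


class TestPredict:

    def test_threshold_zero_all_ones(self, model, phantom_pair):
        from vesselseg.preprocessing import green_channel

        _, mask = predict(model, green_channel(phantom_pair.image), threshold=0.0)
        assert mask.all()

    def test_threshold_above_one_all_zeros(self, model, phantom_pair):
        from vesselseg.preprocessing import green_channel

        _, mask = predict(model, green_channel(phantom_pair.image), threshold=1.0 + 1e-9)
        assert not mask.any()

    def test_mask_monotone_in_threshold(self, model, phantom_pair):
        from vesselseg.preprocessing import green_channel

        g = green_channel(phantom_pair.image)
        counts = [predict(model, g, threshold=t)[1].sum() for t in (0.2, 0.5, 0.8)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_non_divisible_input_padded_and_cropped(self, model):
        img = np.random.default_rng(0).integers(0, 256, (33, 47), dtype=np.uint8).astype(np.uint8)
        prob, mask = predict(model, img)
        assert prob.shape == (33, 47) and mask.shape == (33, 47)
        assert 0.0 <= prob.min() and prob.max() <= 1.0


class TestCheckpoint:
    def test_round_trip_reproduces_output(self, tmp_path):
        model = build_msffu_net(NetworkSpec(depth=1, base_channels=8), seed=4)
        x = np.random.default_rng(1).uniform(size=(1, 1, 16, 16)).astype(np.float32)
        before = model.forward(x)
        save_checkpoint(model, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        after = restored.forward(x)
        assert np.array_equal(before, after)
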