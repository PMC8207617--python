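"""Architectural components: 4-channel input adapter, ACP pooling,
buffering head, batch hard sampler."""

import itertools

import numpy as np
import pytest

from microloc import nn
from microloc.components import (
    ACPConfig,
    BatchLossRecord,
    HeadSpec,
    acp_pool,
    adapt_input_layer,
    build_head,
    default_hard_k,
    hard_sample_select,
    head_parameter_count,
)


def conv_forward(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Direct valid convolution used as an oracle for the adapter."""
    out_c, in_c, kh, kw = weights.shape
    h, w = x.shape[1] - kh + 1, x.shape[2] - kw + 1
    out = np.zeros((out_c, h, w))
    for o in range(out_c):
        for i in range(in_c):
            for di in range(kh):
                for dj in range(kw):
                    out[o] += weights[o, i, di, dj] * x[i, di : di + h, dj : dj + w]
    return out


class TestInputAdapter:
    def test_zero_strategy_preserves_rgb_forward(self, rng):
        w3 = rng.normal(size=(5, 3, 3, 3))
        w4 = adapt_input_layer(w3, "zero")
        rgb = rng.normal(size=(3, 10, 10))
        yellow = rng.normal(size=(1, 10, 10))
        x4 = np.concatenate([rgb, yellow])
        assert np.array_equal(conv_forward(w3, rgb), conv_forward(w4, x4))

    def test_mean_rgb_of_identical_kernels(self, rng):
        k = rng.normal(size=(4, 1, 3, 3))
        w3 = np.repeat(k, 3, axis=1)
        w4 = adapt_input_layer(w3, "mean_rgb")
        assert np.allclose(w4[:, 3], k[:, 0])

    def test_copy_red_is_bitwise_copy(self, rng):
        w3 = rng.normal(size=(2, 3, 5, 5))
        w4 = adapt_input_layer(w3, "copy_red")
        assert np.array_equal(w4[:, 3], w3[:, 0])

    def test_first_three_channels_unchanged(self, rng):
        w3 = rng.normal(size=(2, 3, 3, 3))
        for strategy in ("zero", "mean_rgb", "copy_red"):
            assert np.array_equal(adapt_input_layer(w3, strategy)[:, :3], w3)

    def test_rejects_non_rgb_weights(self, rng):
        with pytest.raises(ValueError):
            adapt_input_layer(rng.normal(size=(2, 4, 3, 3)), "zero")
        with pytest.raises(ValueError):
            adapt_input_layer(rng.normal(size=(2, 3, 3, 3)), "nope")


class TestACP:
    @pytest.mark.parametrize("channels,expected", [(1536, 3072), (2048, 4096)])
    def test_flattened_length(self, rng, channels, expected):
        fm = rng.normal(size=(channels, 4, 6))
        assert acp_pool(fm).shape == (expected,)
        assert ACPConfig(in_channels=channels).out_features == expected

    def test_output_independent_of_spatial_size(self, rng):
        for h, w in [(1, 1), (3, 9), (17, 2)]:
            assert acp_pool(rng.normal(size=(12, h, w))).shape == (24,)

    def test_mean_and_max_halves(self, rng):
        fm = rng.normal(size=(6, 5, 5))
        out = acp_pool(fm)
        assert np.allclose(out[:6], fm.mean(axis=(1, 2)))
        assert np.allclose(out[6:], fm.max(axis=(1, 2)))
        assert (out[:6] <= out[6:]).all()

    def test_constant_map_mean_equals_max(self):
        out = acp_pool(np.full((3, 4, 4), 2.5))
        assert np.allclose(out, 2.5)

    def test_channel_permutation_equivariance(self, rng):
        fm = rng.normal(size=(8, 3, 3))
        perm = rng.permutation(8)
        out, out_p = acp_pool(fm), acp_pool(fm[perm])
        assert np.allclose(out_p[:8], out[:8][perm])
        assert np.allclose(out_p[8:], out[8:][perm])

    def test_zero_spatial_rejected(self):
        with pytest.raises(ValueError):
            acp_pool(np.zeros((3, 0, 4)))


class TestHead:
    def test_resnet50_style_dims(self, rng):
        spec = HeadSpec(in_features=4096, buffering_sizes=(1024,), dropout_rates=(0.5,))
        head = build_head(spec, rng)
        x = rng.normal(size=(2, 4096))
        assert head.forward(x, train=False).shape == (2, 28)
        assert spec.layer_sizes == (4096, 1024, 28)

    def test_empty_buffering_single_linear(self, rng):
        spec = HeadSpec(in_features=4096)
        head = build_head(spec, rng)
        assert len([l for l in head.layers if isinstance(l, nn.Linear)]) == 1
        assert head.forward(rng.normal(size=(1, 4096)), train=False).shape == (1, 28)

    def test_parameter_count_closed_form(self):
        spec = HeadSpec(in_features=4096, buffering_sizes=(1024,), dropout_rates=(0.5,))
        expected = (4096 + 1) * 1024 + (1024 + 1) * 28
        assert head_parameter_count(spec) == expected
        built = sum(p.value.size for p in build_head(spec).parameters())
        assert built == expected

    def test_two_buffering_layers(self):
        # 4096 units @ 0.25 dropout then 1024 @ 0.5 (101-layer variant)
        spec = HeadSpec(
            in_features=8192, buffering_sizes=(4096, 1024), dropout_rates=(0.25, 0.5)
        )
        assert spec.layer_sizes == (8192, 4096, 1024, 28)

    def test_non_decreasing_buffering_rejected(self):
        with pytest.raises(ValueError):
            HeadSpec(in_features=1024, buffering_sizes=(1024,), dropout_rates=(0.5,))
        with pytest.raises(ValueError):
            HeadSpec(in_features=4096, buffering_sizes=(512, 512), dropout_rates=(0.1, 0.1))


class TestHardSampler:
    def test_k_equals_b_selects_all(self, rng):
        losses = rng.random(8)
        sel = hard_sample_select(BatchLossRecord(losses=losses, k=8))
        assert (sel == np.arange(8)).all()
        assert np.isclose(losses[sel].mean(), losses.mean())

    def test_top_two_of_four(self):
        sel = hard_sample_select(BatchLossRecord(losses=[0.1, 0.9, 0.5, 0.7], k=2))
        assert sel.tolist() == [1, 3]

    def test_ties_prefer_lower_index(self):
        sel = hard_sample_select(BatchLossRecord(losses=[0.5, 0.5, 0.5, 0.1], k=2))
        assert sel.tolist() == [0, 1]

    def test_matches_exhaustive_subset_argmax(self, rng):
        """Selected subset maximizes summed loss over all K-subsets."""
        for b in range(1, 9):
            losses = np.round(rng.random(b), 3)
            for k in range(1, b + 1):
                sel = hard_sample_select(BatchLossRecord(losses=losses, k=k))
                best = max(
                    itertools.combinations(range(b), k),
                    key=lambda s: losses[list(s)].sum(),
                )
                assert np.isclose(losses[sel].sum(), losses[list(best)].sum())

    def test_idempotent(self, rng):
        losses = rng.random(10)
        sel = hard_sample_select(BatchLossRecord(losses=losses, k=4))
        again = hard_sample_select(BatchLossRecord(losses=losses[sel], k=4))
        assert (sel[again] == sel).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            BatchLossRecord(losses=[0.1, 0.2], k=3)
        with pytest.raises(ValueError):
            BatchLossRecord(losses=[0.1, 0.2], k=0)

    def test_default_k_is_half_batch(self):
        assert default_hard_k(74) == 37
        assert default_hard_k(7) == 4
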