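"""Architecture structure, ablation stages and the profiler."""

from dataclasses import replace

import numpy as np
import pytest

from sparsepat.models import (
    STAGES,
    ModelConfig,
    MSDNet,
    build_dense_block,
    build_msdnet,
    build_stage,
    build_uiu_block,
    profile,
)
from sparsepat.nn.autodiff import Tensor, mse_loss
from sparsepat.nn.modules import Conv2d
from sparsepat.nn.optim import Adam

TINY = ModelConfig().scaled(0.0625)


def forward_random(model, n=1, seed=0):
    x = np.random.default_rng(seed).random((n, 1, 128, 128), dtype=np.float32)
    return x, model.eval()(Tensor(x)).data


class TestUIUBlock:
    @pytest.mark.parametrize(
        "size,levels", [(128, 4), (64, 3), (32, 2), (16, 1), (8, 1)]
    )
    def test_internal_depth_follows_stage_resolution(self, size, levels):
        block = build_uiu_block(size, 4, 8, mid_ch=4)
        assert block.n_internal_levels == levels

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            build_uiu_block(96, 4, 8)

    @pytest.mark.parametrize("size", [128, 16, 8])
    def test_forward_preserves_shape_and_is_finite(self, size):
        block = build_uiu_block(size, 2, 4, mid_ch=4).eval()
        out = block(Tensor(np.zeros((1, 2, size, size), dtype=np.float32)))
        assert out.shape == (1, 4, size, size)
        assert np.isfinite(out.data).all()

    def test_deepest_internal_map_is_8x8(self):
        """Pooling the first-stage input 4 times lands exactly on the 8x8
        bottleneck the block is built around."""
        block = build_uiu_block(128, 1, 4, mid_ch=4)
        assert 128 // 2**block.n_internal_levels == 8


class TestDenseBlock:
    def test_branch_dilations_give_3_5_7_receptive_fields(self):
        block = build_dense_block(4, 8, dilations=(1, 2, 3), growth=4)
        assert block.dilations == (1, 2, 3)
        # two conv layers per branch, each at the branch dilation
        for branch, dil in zip(block.branches, (1, 2, 3)):
            convs = [m for m in branch.modules() if isinstance(m, Conv2d)]
            assert len(convs) == 2
            assert all(c.dilation == dil for c in convs)

    def test_dense_connectivity_widths(self):
        """Each branch consumes the block input plus all previous outputs."""
        block = build_dense_block(6, 8, growth=4)
        widths = [
            [m for m in b.modules() if isinstance(m, Conv2d)][0].in_ch
            for b in block.branches
        ]
        assert widths == [6, 10, 14]

    def test_output_shape_preserved(self, rng):
        block = build_dense_block(3, 5, growth=4).eval()
        out = block(Tensor(rng.random((2, 3, 16, 16)).astype(np.float32)))
        assert out.shape == (2, 5, 16, 16)

    def test_empty_dilations_rejected(self):
        with pytest.raises(ValueError):
            build_dense_block(3, 5, dilations=())


class TestMSDNet:
    def test_forward_shape_and_sigmoid_range(self):
        model = MSDNet(TINY)
        _, out = forward_random(model, n=2)
        assert out.shape == (2, 1, 128, 128)
        assert (out > 0).all() and (out < 1).all()

    def test_multi_scale_head_concatenates_five_branches(self):
        model = MSDNet(TINY)
        forward_random(model)
        assert model.last_head_width == 5 * TINY.head_channels
        assert ModelConfig().head_concat_channels == 160

    def test_eval_forward_is_deterministic(self):
        model = MSDNet(TINY)
        _, a = forward_random(model, seed=3)
        _, b = forward_random(model, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)
        with pytest.raises(ValueError):
            ModelConfig(stage="stage4")
        with pytest.raises(ValueError):
            ModelConfig(encoder_channels=(8, 8))

    def test_translation_covariance(self):
        """Shifting the input shifts the output: the backbone is fully
        convolutional up to boundary effects and pooling alignment."""
        model = MSDNet(TINY)
        rng = np.random.default_rng(0)
        x = np.zeros((1, 1, 128, 128), dtype=np.float32)
        x[0, 0, 32:64, 32:64] = rng.random((32, 32))
        shifted = np.roll(x, (8, 8), axis=(2, 3))
        out = model.eval()(Tensor(x)).data
        out_shifted = model.eval()(Tensor(shifted)).data
        rolled = np.roll(out, (8, 8), axis=(2, 3))
        err = np.linalg.norm(out_shifted - rolled) / np.linalg.norm(out)
        assert err < 0.10

    def test_one_adam_step_decreases_training_mse(self):
        model = MSDNet(replace(TINY, seed=7))
        rng = np.random.default_rng(0)
        x = rng.random((4, 1, 128, 128), dtype=np.float32)
        y = rng.random((4, 1, 128, 128), dtype=np.float32)
        opt = Adam(model.parameters(), lr=1e-3)
        model.train()
        losses = []
        for _ in range(3):
            opt.zero_grad()
            loss = mse_loss(model(Tensor(x)), y)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        # training-batch MSE strictly decreases after each step
        assert losses[1] < losses[0] and losses[2] < losses[1]


class TestStages:
    @pytest.mark.parametrize("stage", STAGES)
    def test_all_stages_preserve_shape(self, stage):
        model = build_stage(TINY, stage)
        _, out = forward_random(model)
        assert out.shape == (1, 1, 128, 128)
        assert (out > 0).all() and (out < 1).all()

    def test_stage3_is_structurally_the_full_model(self):
        a = build_stage(TINY, "stage3_full")
        b = build_msdnet(TINY)
        assert a.n_parameters() == b.n_parameters()
        assert [type(m).__name__ for m in a.modules()] == [
            type(m).__name__ for m in b.modules()
        ]

    def test_parameter_counts_grow_with_components(self):
        n = {s: build_stage(TINY, s).n_parameters() for s in STAGES}
        assert n["baseline_unet"] < n["stage1_uiu"]
        assert n["stage2_uiu_dense"] != n["stage1_uiu"]


class TestProfiler:
    def test_single_conv_closed_form(self):
        conv = Conv2d(1, 1, 3, bias=False, rng=np.random.default_rng(0))
        assert sum(p.data.size for p in conv.parameters()) == 9

    def test_profile_is_deterministic_and_idempotent(self):
        model = MSDNet(TINY)
        a = profile(model)
        b = profile(model)
        assert a == b
        assert a.n_params == model.n_parameters()
        assert a.flops > 0 and a.n_params > 0

    def test_mac2_convention_doubles_flops(self):
        model = MSDNet(TINY)
        assert profile(model, convention="mac2").flops == pytest.approx(
            2 * profile(model).flops
        )

    def test_profiling_does_not_perturb_training_mode(self):
        model = MSDNet(TINY).train()
        profile(model)
        assert model.training
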