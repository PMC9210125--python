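"""Generator architecture contracts: shapes, fusion, aggregation, gradients."""

import numpy as np
import pytest

from medsrnet.config import GeneratorSpec
from medsrnet.errors import DimensionError, GeometryError, SpecError
from medsrnet.generator import (BilinearAggregation, DeconvAggregation,
                                FuseBlock, build_generator, deconv_geometry,
                                generator_forward)
from medsrnet.nn import Initializer
from medsrnet.nn import autograd as ag


class TestSpec:
    def test_default_widths_double_per_stream(self):
        gen = build_generator(GeneratorSpec(), scale=4)
        assert gen.stream_widths == (32, 64, 128, 256)

    def test_tiny_spec_is_valid(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=4)
        assert gen.stream_widths == (4, 8, 16, 32)

    def test_doubling_violation_rejected(self):
        with pytest.raises(SpecError):
            GeneratorSpec(widths=(32, 64, 100, 256))

    def test_kernel_must_cover_stride(self):
        with pytest.raises(SpecError):
            GeneratorSpec(deconv_kernels=(5, 7, 7), deconv_strides=(2, 4, 8))


class TestDeconvGeometry:
    @pytest.mark.parametrize("in_side,kernel,stride,expected", [
        (32, 11, 8, (2, 1, 256)),
        (64, 7, 4, (2, 1, 256)),
        (128, 5, 2, (2, 1, 256)),
    ])
    def test_published_kernel_stride_pairs(self, in_side, kernel, stride,
                                           expected):
        assert deconv_geometry(in_side, kernel, stride) == expected

    @pytest.mark.parametrize("in_side", [8, 12, 16, 24, 32, 48])
    @pytest.mark.parametrize("kernel,stride", [(5, 2), (7, 4), (11, 8),
                                               (4, 2), (9, 4)])
    def test_output_is_exact_multiple_over_grid(self, in_side, kernel, stride):
        pad, op, out = deconv_geometry(in_side, kernel, stride)
        assert out == in_side * stride
        assert (in_side - 1) * stride - 2 * pad + kernel + op == out
        assert 0 <= op < stride

    def test_kernel_not_exceeding_stride_rejected(self):
        with pytest.raises(GeometryError):
            deconv_geometry(32, 8, 8)


class TestForward:
    def test_scale8_maps_32_to_256(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=8)
        lr = np.random.default_rng(0).random((32, 32))
        assert generator_forward(gen, lr).shape == (256, 256)

    def test_scale4_maps_24_to_96(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=4)
        lr = np.random.default_rng(0).random((24, 24))
        assert generator_forward(gen, lr).shape == (96, 96)

    def test_output_clipped_to_unit_interval(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=4)
        out = generator_forward(gen, np.random.default_rng(1).random((16, 16)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_forward_is_deterministic(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=4, seed=5)
        lr = np.random.default_rng(2).random((16, 16))
        np.testing.assert_array_equal(generator_forward(gen, lr),
                                      generator_forward(gen, lr))

    def test_indivisible_upsampled_size_rejected(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=2)
        with pytest.raises(DimensionError):
            generator_forward(gen, np.zeros((15, 15)) + 0.5)


class TestFusion:
    def _pyramid(self, widths, side=16, fill=None, seed=0):
        rng = np.random.default_rng(seed)
        streams = []
        for k, w in enumerate(widths):
            s = side // (2 ** k)
            data = (np.zeros((1, w, s, s), dtype=np.float32) if fill == "zero"
                    else rng.random((1, w, s, s), dtype=np.float32))
            streams.append(ag.Tensor(data))
        return streams

    def test_zero_pyramid_stays_zero(self):
        widths = (4, 8, 16, 32)
        fuse = FuseBlock(widths, Initializer(0))
        out = fuse(self._pyramid(widths, fill="zero"))
        for s in out:
            assert np.all(s.data == 0.0)  # all biases are zero-initialised

    def test_shape_signature_preserved(self):
        widths = (4, 8, 16, 32)
        fuse = FuseBlock(widths, Initializer(0))
        streams = self._pyramid(widths)
        out = fuse(streams)
        assert [s.shape for s in out] == [s.shape for s in streams]

    def test_single_nonzero_stream_reaches_all_streams(self):
        widths = (4, 8)
        fuse = FuseBlock(widths, Initializer(3))
        streams = self._pyramid(widths, fill="zero")
        streams[1] = ag.Tensor(np.abs(np.random.default_rng(4).random(
            (1, 8, 8, 8), dtype=np.float32)) + 0.5)
        out = fuse(streams)
        assert all(np.any(s.data != 0.0) for s in out)


class TestAggregation:
    def test_concat_channel_count(self, tiny_gen_spec):
        head = DeconvAggregation(tiny_gen_spec, Initializer(0))
        assert head.concat_channels == sum(tiny_gen_spec.widths)
        assert DeconvAggregation(GeneratorSpec(),
                                 Initializer(0)).concat_channels == 480

    def test_deconv_outputs_match_top_stream(self, tiny_gen_spec):
        gen = build_generator(tiny_gen_spec, scale=4)
        x = ag.Tensor(np.random.default_rng(0).random(
            (1, 1, 32, 32), dtype=np.float32))
        assert gen(x).shape == (1, 1, 32, 32)

    def test_zero_pyramid_zero_output(self, tiny_gen_spec):
        head = DeconvAggregation(tiny_gen_spec, Initializer(0))
        streams = [ag.Tensor(np.zeros((1, w, 16 // 2 ** k, 16 // 2 ** k),
                                      dtype=np.float32))
                   for k, w in enumerate(tiny_gen_spec.widths)]
        assert np.all(head(streams).data == 0.0)

    def test_deconv_head_has_more_parameters_than_bilinear(self, tiny_gen_spec):
        deconv = DeconvAggregation(tiny_gen_spec, Initializer(0))
        bilinear = BilinearAggregation(tiny_gen_spec, Initializer(0))
        assert deconv.n_parameters() > bilinear.n_parameters()


def test_batchnorm_variant_forwards(tiny_gen_spec):
    import dataclasses

    spec = dataclasses.replace(tiny_gen_spec, batchnorm=True)
    gen = build_generator(spec, 4, seed=0)
    out = generator_forward(gen, np.random.default_rng(0).random((8, 8)))
    assert out.shape == (32, 32)
    assert np.all(np.isfinite(out))


def test_gradient_reaches_every_parameter(tiny_gen_spec):
    gen = build_generator(tiny_gen_spec, scale=4, seed=0)
    x = ag.Tensor(np.random.default_rng(0).random(
        (1, 1, 16, 16), dtype=np.float32))
    loss = ag.tmean(ag.square(gen(x)))
    loss.backward()
    dead = [name for name, p in gen.named_parameters()
            if p.grad is None or not np.any(p.grad != 0)]
    assert dead == []
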