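"""Loss oracles and PSNR/SSIM metric properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medsrnet.config import LossWeights
from medsrnet.errors import DimensionError, DomainError
from medsrnet.objectives import (adversarial_generator_loss, content_loss,
                                 discriminator_loss, psnr, ssim, total_loss)


def _naive_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Independent windowed SSIM oracle (explicit Gaussian window loops)."""
    from scipy.ndimage import gaussian_filter

    c1, c2 = 0.01 ** 2, 0.03 ** 2
    filt = lambda x: gaussian_filter(x, sigma=1.5, truncate=3.5)
    mu_a, mu_b = filt(a), filt(b)
    va = filt(a * a) - mu_a ** 2
    vb = filt(b * b) - mu_b ** 2
    cov = filt(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2))
    pad = 5  # exclude the border where the window spills over
    return float(s[pad:-pad, pad:-pad].mean())


class TestLosses:
    def test_content_loss_examples(self):
        a = np.full((8, 8), 0.5)
        assert content_loss(a, a) == 0.0
        assert content_loss(np.full((8, 8), 0.6), a) == pytest.approx(0.01)

    def test_content_loss_matches_double_loop(self, rng):
        sr, hr = rng.random((6, 7)), rng.random((6, 7))
        brute = sum((sr[i, j] - hr[i, j]) ** 2
                    for i in range(6) for j in range(7)) / 42
        assert content_loss(sr, hr) == pytest.approx(brute, abs=1e-10)

    def test_adversarial_loss_examples(self):
        assert adversarial_generator_loss([0.5]) == pytest.approx(
            math.log(2), abs=1e-4)
        assert adversarial_generator_loss([0.999999]) < 1e-5
        score = 0.3173
        assert adversarial_generator_loss([score]) == pytest.approx(
            -math.log(score), abs=1e-12)

    def test_discriminator_loss_examples(self):
        assert discriminator_loss([0.5], [0.5]) == pytest.approx(
            2 * math.log(2), abs=1e-4)
        assert discriminator_loss([0.9999999], [1e-7]) < 1e-5

    def test_discriminator_loss_matches_scalar_loop(self, rng):
        real = rng.uniform(0.1, 0.9, 5)
        fake = rng.uniform(0.1, 0.9, 4)
        brute = (-sum(math.log(x) for x in real) / 5
                 - sum(math.log(1 - x) for x in fake) / 4)
        assert discriminator_loss(real, fake) == pytest.approx(brute,
                                                               abs=1e-10)

    def test_scores_outside_open_interval_rejected(self):
        with pytest.raises(DomainError):
            adversarial_generator_loss([0.0])
        with pytest.raises(DomainError):
            discriminator_loss([0.5], [1.0])

    def test_total_loss_composition(self):
        w = LossWeights(a1=1.0, a2=0.001)
        br = total_loss(0.01, 0.6931, w)
        assert br.total == pytest.approx(0.0106931, abs=1e-12)
        assert total_loss(0.01, 0.7, LossWeights(1.0, 0.0)).total == 0.01
        assert total_loss(0.01, 0.7, LossWeights(0.0, 1.0)).total == 0.7

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a1=st.floats(0.01, 10), a2=st.floats(0.01, 10),
           c=st.floats(0, 5), g=st.floats(0, 5))
    def test_total_loss_linear_in_each_weight(self, a1, a2, c, g):
        base = total_loss(c, g, LossWeights(a1, a2)).total
        doubled = total_loss(c, g, LossWeights(2 * a1, a2)).total
        assert doubled - base == pytest.approx(a1 * c, rel=1e-9, abs=1e-12)


class TestPSNR:
    def test_identical_images_are_infinite(self, phantom64):
        assert math.isinf(psnr(phantom64, phantom64))

    def test_constant_offsets(self):
        a = np.full((16, 16), 0.4)
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)
        assert psnr(np.zeros((16, 16)), np.full((16, 16), 0.5)) == \
            pytest.approx(10 * math.log10(4), abs=1e-4)

    def test_symmetry_and_noise_monotonicity(self, phantom64, rng):
        noise = rng.standard_normal(phantom64.shape)
        prev = math.inf
        for amp in (0.01, 0.05, 0.1):
            noisy = np.clip(phantom64 + amp * noise, 0, 1)
            value = psnr(phantom64, noisy)
            assert value == psnr(noisy, phantom64)
            assert value < prev
            prev = value

    def test_size_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_inverts_content_loss(self, phantom64, rng):
        noisy = np.clip(phantom64 + 0.05 * rng.standard_normal(
            phantom64.shape), 0, 1)
        mse = content_loss(noisy, phantom64)
        assert psnr(noisy, phantom64) == pytest.approx(
            10 * math.log10(1 / mse), abs=1e-12)


class TestSSIM:
    def test_self_similarity_is_one(self, phantom64):
        assert ssim(phantom64, phantom64) == 1.0

    def test_constant_pair_closed_form(self):
        a = np.full((16, 16), 0.2)
        b = np.full((16, 16), 0.4)
        expected = (2 * 0.2 * 0.4 + 1e-4) / (0.2 ** 2 + 0.4 ** 2 + 1e-4)
        assert ssim(a, b) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.8001, abs=1e-4)

    def test_matches_independent_windowed_oracle(self, phantom64, rng):
        noisy = np.clip(phantom64 + 0.05 * rng.standard_normal(
            phantom64.shape), 0, 1)
        ours = ssim(phantom64, noisy)
        assert ours == pytest.approx(_naive_ssim(phantom64, noisy), abs=0.02)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(3):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            assert -1.0 <= ssim(a, b) <= 1.0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(DimensionError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))
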