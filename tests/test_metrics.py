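"""Image-quality metrics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from sparsepat.metrics import compute_report, mae, mse, psnr, ssim


def brute_force_global_ssim(y, g, c1=0.01, c2=0.03):
    """Direct mean/variance/covariance evaluation of the similarity index."""
    n = y.size
    mu_y = sum(y.ravel()) / n
    mu_g = sum(g.ravel()) / n
    var_y = sum((v - mu_y) ** 2 for v in y.ravel()) / n
    var_g = sum((v - mu_g) ** 2 for v in g.ravel()) / n
    cov = sum((a - mu_y) * (b - mu_g) for a, b in zip(y.ravel(), g.ravel())) / n
    return ((2 * mu_y * mu_g + c1) * (2 * cov + c2)) / (
        (mu_y**2 + mu_g**2 + c1) * (var_y + var_g + c2)
    )


class TestPointwiseMetrics:
    def test_identical_images_are_error_free(self, rng):
        img = rng.random((16, 16))
        assert mse(img, img) == 0.0
        assert mae(img, img) == 0.0
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)
        assert psnr(img, img) == math.inf

    def test_constant_offsets_match_closed_forms(self, rng):
        g = rng.random((12, 12))
        assert mse(g + 0.5, g) == pytest.approx(0.25, abs=1e-12)
        assert mae(g + 0.2, g) == pytest.approx(0.2, abs=1e-12)

    def test_psnr_closed_form_and_scale_invariance(self, rng):
        g = np.zeros((10, 10))
        g[0, 0] = 1.0  # peak 1
        y = g.copy()
        y += 0.1  # MSE 0.01, max still governed by the pair union
        y[0, 0] = 1.0
        val = psnr(y, g)
        expected = 10 * math.log10(max(y.max(), g.max()) ** 2 / mse(y, g))
        assert val == pytest.approx(expected, abs=1e-12)
        assert psnr(2 * y, 2 * g) == pytest.approx(val, abs=1e-9)

    def test_random_pairs_match_loop_oracles(self, rng):
        y, g = rng.random((8, 8)), rng.random((8, 8))
        loop_mse = sum((a - b) ** 2 for a, b in zip(y.ravel(), g.ravel())) / 64
        loop_mae = sum(abs(a - b) for a, b in zip(y.ravel(), g.ravel())) / 64
        assert mse(y, g) == pytest.approx(loop_mse, abs=1e-9)
        assert mae(y, g) == pytest.approx(loop_mae, abs=1e-9)
        assert psnr(y, g) == pytest.approx(
            10 * math.log10(max(y.max(), g.max()) ** 2 / loop_mse), abs=1e-9
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            mse(np.zeros((3, 3)), np.zeros((4, 4)))


class TestSSIM:
    def test_constant_images_reduce_to_luminance_term(self):
        a, b = 0.7, 0.3
        y = np.full((9, 9), a)
        g = np.full((9, 9), b)
        expected = (2 * a * b + 0.01) / (a**2 + b**2 + 0.01)
        assert ssim(y, g) == pytest.approx(expected, abs=1e-12)

    def test_global_mode_matches_brute_force_statistics(self, rng):
        y, g = rng.random((8, 8)), rng.random((8, 8))
        assert ssim(y, g, mode="global") == pytest.approx(
            brute_force_global_ssim(y, g), abs=1e-9
        )

    def test_windowed_mode_matches_reference_implementation(self, rng):
        """Cross-check against scikit-image with matched constants
        (K = sqrt(c) at unit data range, uniform 7x7 window, population
        covariance, border of win//2 excluded)."""
        y, g = rng.random((32, 32)), rng.random((32, 32))
        ours = ssim(y, g, mode="windowed", win_size=7)
        _, smap = structural_similarity(
            y,
            g,
            win_size=7,
            data_range=1.0,
            K1=math.sqrt(0.01),
            K2=math.sqrt(0.03),
            use_sample_covariance=False,
            full=True,
        )
        theirs = smap[3:-3, 3:-3].mean()
        assert ours == pytest.approx(theirs, abs=1e-7)

    def test_standard_constants_flag(self, rng):
        y, g = rng.random((8, 8)), rng.random((8, 8))
        lit = ssim(y, g, mode="global")
        std = ssim(y, g, mode="global", standard_constants=True)
        assert lit != std  # the printed constants differ from (kL)^2

    def test_bounds_on_many_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            y, g = rng.random((6, 6)), rng.random((6, 6))
            s = ssim(y, g)
            assert -1.0 <= s <= 1.0 + 1e-12
            assert mae(y, g) ** 2 <= mse(y, g) + 1e-15  # Jensen
            if mse(y, g) < 1.0 and max(y.max(), g.max()) >= 1.0 - 1e-9:
                assert psnr(y, g) > 0.0


class TestReport:
    def test_report_rows_and_aggregates(self, rng):
        outs = rng.random((5, 16, 16))
        tgts = rng.random((5, 16, 16))
        report = compute_report(outs, tgts)
        assert len(report) == 5
        summary = report.summary()
        for name in ("ssim", "psnr", "mae", "mse"):
            vals = np.asarray(getattr(report, name))
            assert summary[name]["mean"] == pytest.approx(vals.mean(), abs=1e-12)
            assert summary[name]["sd"] == pytest.approx(vals.std(), abs=1e-12)

    def test_identity_predictions_score_perfectly(self, rng):
        imgs = rng.random((3, 16, 16))
        report = compute_report(imgs, imgs.copy(), ssim_mode="global")
        summary = report.summary()
        assert summary["ssim"]["mean"] == pytest.approx(1.0, abs=1e-12)
        assert summary["mae"]["mean"] == 0.0

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            compute_report(np.empty((0, 4, 4)), np.empty((0, 4, 4)))


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


image_pairs = st.tuples(
    arrays(np.float64, (6, 6), elements=st.floats(0, 1, allow_nan=False)),
    arrays(np.float64, (6, 6), elements=st.floats(0, 1, allow_nan=False)),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(image_pairs)
def test_metric_invariants_on_arbitrary_images(pair):
    y, g = pair
    assert mse(y, g) >= 0.0
    assert mae(y, g) >= 0.0
    assert mae(y, g) ** 2 <= mse(y, g) + 1e-15
    # the similarity index is symmetric in its arguments
    assert ssim(y, g) == pytest.approx(ssim(g, y), abs=1e-12)
    assert -1.0 <= ssim(y, g) <= 1.0 + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(image_pairs, st.floats(0.25, 4.0))
def test_psnr_invariant_under_common_rescaling(pair, scale):
    y, g = pair
    if mse(y, g) == 0.0 or max(y.max(), g.max()) == 0.0:
        return
    assert psnr(scale * y, scale * g) == pytest.approx(psnr(y, g), abs=1e-8)
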