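import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from eics.metrics import (
    corr,
    evaluate_stack,
    fsim,
    mse,
    piqe,
    psnr,
    sharpness_index,
    ssim,
)
from eics.phantom import PhantomSpec, SliceStack, generate_phantom


@pytest.fixture(scope="module")
def image():
    return generate_phantom(PhantomSpec(n_slices=2, matrix_size=128, seed=4)).data[0]


def test_mse_hand_values():
    assert mse(np.zeros((2, 2)), np.ones((2, 2))) == 1.0
    assert mse(np.array([[0.0, 1.0], [1.0, 0.0]]),
               np.array([[1.0, 1.0], [0.0, 0.0]])) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        mse(np.zeros((2, 2)), np.zeros((3, 3)))


@pytest.mark.parametrize(
    "err, expected", [(0.01, 20.0), (1.0, 0.0), (0.0004, 33.9794)]
)
def test_psnr_closed_form(err, expected):
    x = np.zeros((4, 4))
    y = np.full((4, 4), np.sqrt(err))
    assert psnr(x, y) == pytest.approx(expected, abs=1e-3)


def test_psnr_identical_is_infinite(image):
    assert psnr(image, image) == float("inf")


def test_corr_identities(image):
    assert corr(image, image) == pytest.approx(1.0)
    assert corr(image, 1.0 - image) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        corr(np.ones((4, 4)), np.zeros((4, 4)) + np.arange(4))


def test_corr_matches_independent_oracle(rng):
    x = rng.standard_normal((3, 3))
    y = rng.standard_normal((3, 3))
    want = np.corrcoef(x.ravel(), y.ravel())[0, 1]
    assert corr(x, y) == pytest.approx(want, rel=1e-12)


def test_ssim_identity_and_symmetry(image, rng):
    noisy = np.clip(image + rng.normal(0, 0.05, image.shape), 0, 1)
    assert ssim(image, image) == pytest.approx(1.0)
    assert ssim(image, noisy) == pytest.approx(ssim(noisy, image))
    with pytest.raises(ValueError):
        ssim(np.zeros((8, 8)), np.zeros((8, 8)))


def test_ssim_global_mode_matches_direct_formula(rng):
    x = rng.random((4, 4))
    y = rng.random((4, 4))
    c1, c2 = (0.01 * 1.0) ** 2, (0.03 * 1.0) ** 2
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    want = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (x.var() + y.var() + c2)
    )
    assert ssim(x, y, mode="global") == pytest.approx(want, rel=1e-12)


def test_fsim_identity_bounds_and_blur(image, rng):
    assert fsim(image, image) == pytest.approx(1.0)
    a = rng.random((64, 64))
    b = rng.random((64, 64))
    val = fsim(a, b)
    assert 0.0 <= val <= 1.0
    assert fsim(image, gaussian_filter(image, 2.0)) < 0.999
    with pytest.raises(ValueError):
        fsim(np.zeros((16, 16)), np.zeros((16, 16)))


def test_sharpness_index_resample_self_consistency(image):
    """A random-phase resample of an image has median SI ≈ -log10(0.5): its
    tail probability is uniform by construction, so individual draws spread
    widely but the median over seeds pins down 0.30."""
    modulus = np.abs(np.fft.fft2(image))
    rng = np.random.default_rng(42)
    sis = []
    for seed in range(31):
        phase = np.exp(1j * np.angle(np.fft.fft2(rng.standard_normal(image.shape))))
        resample = np.fft.ifft2(modulus * phase).real
        sis.append(sharpness_index(resample, n_resamples=100, seed=seed))
    assert np.median(sis) == pytest.approx(0.301, abs=0.15)


def test_sharpness_index_blur_monotonicity_and_determinism(image):
    sharp = sharpness_index(image, seed=0)
    blurred = sharpness_index(gaussian_filter(image, 2.0), seed=0)
    assert sharp > blurred
    assert sharpness_index(image, seed=0) == sharp
    with pytest.raises(ValueError):
        sharpness_index(np.ones((32, 32)))


def test_sharpness_index_literal_mode(image):
    tail = sharpness_index(image, seed=0, mode="tail")
    literal = sharpness_index(image, seed=0, mode="literal")
    assert np.isfinite(literal) and tail > literal


def test_piqe_flat_image_empty_sum():
    assert piqe(np.full((64, 64), 0.5)) == pytest.approx(1.0)


def test_piqe_range_and_noise_monotonicity(image, rng):
    base = piqe(image)
    assert 0.0 <= base <= 100.0
    assert 0.0 <= piqe(rng.random((64, 64))) <= 100.0
    noisy = np.clip(image + rng.normal(0, 0.15, image.shape), 0, 1)
    assert piqe(noisy) > base
    with pytest.raises(ValueError):
        piqe(np.zeros((32, 32)))


def test_degradation_monotonicity_in_expectation(image):
    """Increasing additive noise worsens mse, psnr, ssim, corr and piqe on
    average (seeded repeats)."""
    rng = np.random.default_rng(11)
    levels = (0.02, 0.08)
    agg = {m: [] for m in ("mse", "psnr", "ssim", "corr", "piqe")}
    for sigma in levels:
        vals = {m: [] for m in agg}
        for _ in range(20):
            noisy = np.clip(image + rng.normal(0, sigma, image.shape), 0, 1)
            vals["mse"].append(mse(image, noisy))
            vals["psnr"].append(psnr(image, noisy))
            vals["ssim"].append(ssim(image, noisy))
            vals["corr"].append(corr(image, noisy))
            vals["piqe"].append(piqe(noisy))
        for m in agg:
            agg[m].append(np.mean(vals[m]))
    assert agg["mse"][1] > agg["mse"][0]
    assert agg["piqe"][1] > agg["piqe"][0]
    assert agg["psnr"][1] < agg["psnr"][0]
    assert agg["ssim"][1] < agg["ssim"][0]
    assert agg["corr"][1] < agg["corr"][0]


def test_evaluate_stack_identity_and_averages():
    stack = generate_phantom(PhantomSpec(n_slices=3, matrix_size=64, seed=6))
    report = evaluate_stack(stack, stack, si_resamples=20, seed=0)
    assert set(report.per_slice.columns) == {
        "ssim", "fsim", "mse", "psnr_db", "corr", "si", "piqe"
    }
    np.testing.assert_allclose(report.per_slice["ssim"], 1.0)
    np.testing.assert_allclose(report.per_slice["fsim"], 1.0)
    np.testing.assert_allclose(report.per_slice["corr"], 1.0)
    np.testing.assert_allclose(report.per_slice["mse"], 0.0)
    np.testing.assert_allclose(
        report.averages.values, report.per_slice.mean(axis=0).values
    )


def test_evaluate_stack_no_reference_only():
    stack = generate_phantom(PhantomSpec(n_slices=2, matrix_size=64, seed=6))
    report = evaluate_stack(stack, None, si_resamples=20, seed=0)
    assert set(report.per_slice.columns) == {"si", "piqe"}


def test_evaluate_stack_shape_mismatch():
    a = generate_phantom(PhantomSpec(n_slices=2, matrix_size=64, seed=6))
    b = generate_phantom(PhantomSpec(n_slices=3, matrix_size=64, seed=6))
    with pytest.raises(ValueError):
        evaluate_stack(a, b)
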