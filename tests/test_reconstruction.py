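import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from eics.nufft import build_operator
from eics.phantom import PhantomSpec, generate_phantom
from eics.reconstruction import (
    ObjectiveBreakdown,
    ReconParams,
    gradient,
    l1_wavelet,
    ncg_reconstruct,
    objective,
    reconstruct_stack,
    total_variation,
)
from eics.trajectories import make_trajectory, nyquist_spokes


def test_total_variation_hand_values():
    assert total_variation(np.ones((5, 5)) * 3.7) == 0.0
    assert total_variation(np.array([[0.0, 1.0], [0.0, 1.0]])) == pytest.approx(2.0)


def test_total_variation_positive_homogeneity(rng):
    x = rng.standard_normal((16, 16))
    assert total_variation(-2.5 * x) == pytest.approx(2.5 * total_variation(x))


def test_l1_wavelet_basics(rng):
    assert l1_wavelet(np.zeros((16, 16)), levels=2) == 0.0
    x = rng.standard_normal((16, 16))
    assert l1_wavelet(3.0 * x, levels=2) == pytest.approx(3.0 * l1_wavelet(x, levels=2))
    with pytest.raises(ValueError):
        l1_wavelet(np.zeros((12, 12)), levels=4)


def test_wavelet_is_orthogonal_parseval(rng):
    from eics.reconstruction import _WaveletTransform

    x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
    w = _WaveletTransform((32, 32), "db4", 3)
    c = w.forward(x)
    assert np.sum(np.abs(c) ** 2) == pytest.approx(np.sum(np.abs(x) ** 2), rel=1e-8)
    np.testing.assert_allclose(w.adjoint(c), x, atol=1e-10)


@pytest.fixture(scope="module")
def small_problem():
    N = 16
    op = build_operator(make_trajectory(8, "golden", N))
    rng = np.random.default_rng(5)
    y = op.forward(rng.standard_normal((N, N)))
    return op, y


def test_objective_breakdown_consistency(small_problem, rng):
    op, y = small_problem
    p = ReconParams(lambda1=0.1, lambda2=0.2, wavelet_levels=2)
    x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    b = objective(x, y, op, p)
    # independent term-by-term recomputation
    r = op.forward(x) - y
    assert b.data_term == pytest.approx(float(np.sum(np.abs(r) ** 2)))
    assert b.l1_term == pytest.approx(l1_wavelet(x, "db4", 2))
    assert b.tv_term == pytest.approx(total_variation(x))
    assert b.total == pytest.approx(b.data_term + 0.1 * b.l1_term + 0.2 * b.tv_term)
    # switching the penalties off leaves pure least squares
    b0 = objective(x, y, op, ReconParams(lambda1=0.0, lambda2=0.0, wavelet_levels=2))
    assert b0.total == pytest.approx(b0.data_term)
    zero = objective(np.zeros((16, 16)), np.zeros_like(y), op, p)
    assert zero.total == 0.0


def test_gradient_matches_finite_differences(small_problem, rng):
    op, y = small_problem
    p = ReconParams(lambda1=0.05, lambda2=0.05, wavelet_levels=2,
                    l1_smooth=1e-8, weighted_data=False)
    x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    g = gradient(x, y, op, p, 0.05, 0.05)

    def f(z):
        r = op.forward(z) - y
        data = float(np.sum(np.abs(r) ** 2))
        from eics.reconstruction import _WaveletTransform, _grad2

        c = _WaveletTransform((16, 16), p.wavelet, 2).forward(z)
        l1 = float(np.sum(np.sqrt(np.abs(c) ** 2 + p.l1_smooth)))
        dx, dy = _grad2(z)
        tv = float(np.sum(np.sqrt(np.abs(dx) ** 2 + np.abs(dy) ** 2 + p.l1_smooth)))
        return data + 0.05 * l1 + 0.05 * tv

    eps = 1e-6
    for _ in range(5):
        d = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        num = (f(x + eps * d) - f(x - eps * d)) / (2 * eps)
        ana = float(np.sum((g.conj() * d).real))
        assert abs(num - ana) / abs(num) <= 1e-4


def test_ncg_nyquist_least_squares_recovery():
    """With full Nyquist sampling and no regularization the solver recovers a
    band-limited phantom (radial spokes never sample the spectral corners,
    so the target is smoothed into the observable disc)."""
    N = 32
    ph = generate_phantom(PhantomSpec(n_slices=3, matrix_size=N, noise_sigma=0, seed=2)).data[0]
    ph = gaussian_filter(ph, 1.0)
    op = build_operator(make_trajectory(nyquist_spokes(N), "uniform", N))
    y = op.forward(ph)
    xh, trace = ncg_reconstruct(
        y, op, ReconParams(lambda1=0.0, lambda2=0.0, max_iter=40, wavelet_levels=2)
    )
    err = np.linalg.norm(np.abs(xh) - ph) / np.linalg.norm(ph)
    assert err <= 0.05
    assert trace[-1].total <= trace[0].total


def test_ncg_monotone_objective_trace(small_problem):
    op, y = small_problem
    _, trace = ncg_reconstruct(y, op, ReconParams(max_iter=25, wavelet_levels=2))
    tot = [t.total_smoothed for t in trace]
    assert all(b <= a + 1e-9 * (1 + abs(a)) for a, b in zip(tot, tot[1:]))
    assert all(isinstance(t, ObjectiveBreakdown) for t in trace)


def test_cs_beats_gridding_on_undersampled_phantom():
    N = 64
    ph = generate_phantom(PhantomSpec(n_slices=3, matrix_size=N, noise_sigma=0, seed=3)).data[0]
    op = build_operator(make_trajectory(20, "golden", N))
    y = op.forward(ph)
    x0 = op.adjoint(y, apply_dcf=True)
    xh, _ = ncg_reconstruct(y, op, ReconParams(max_iter=40))
    err_grid = np.linalg.norm(np.abs(x0) - ph) / np.linalg.norm(ph)
    err_cs = np.linalg.norm(np.abs(xh) - ph) / np.linalg.norm(ph)
    assert err_cs < err_grid
    assert total_variation(np.abs(xh)) < total_variation(np.abs(x0))


def test_reconstruct_stack_matches_single_slice_calls():
    from eics.interpolation import combined_operator, interpolate_stack, undersample_stack
    from eics.trajectories import make_mask_triple

    stack = generate_phantom(PhantomSpec(n_slices=3, matrix_size=32, noise_sigma=0, seed=9))
    triple = make_mask_triple(3, "uniform", 32)
    u = interpolate_stack(undersample_stack(stack, triple), "eics")
    p = ReconParams(max_iter=10, wavelet_levels=2)
    recon = reconstruct_stack(u, p)
    assert recon.n_slices == 3
    for i, s in enumerate(u.slices):
        op = combined_operator(s, 32, 32)
        x, _ = ncg_reconstruct(s.values, op, p)
        np.testing.assert_allclose(recon.data[i], np.abs(x), atol=1e-12)


def test_reconstruct_stack_zero_input_gives_zero():
    from eics.interpolation import undersample_stack
    from eics.phantom import SliceStack
    from eics.trajectories import make_mask_triple

    stack = SliceStack(data=np.zeros((3, 32, 32)))
    triple = make_mask_triple(2, "uniform", 32)
    u = undersample_stack(stack, triple)
    recon = reconstruct_stack(u, ReconParams(lambda1=0.0, lambda2=0.0,
                                             max_iter=5, wavelet_levels=2))
    assert np.allclose(recon.data, 0.0)


def test_recon_params_validation():
    with pytest.raises(ValueError):
        ReconParams(lambda1=-1.0)
    with pytest.raises(ValueError):
        ReconParams(ls_alpha=0.7)
    with pytest.raises(ValueError):
        ReconParams(ls_beta=1.5)
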