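"""Image-quality metrics: SSIM, FSIM, MSE, PSNR, CORR (full-reference) and
sharpness index, PIQE (no-reference).

All metrics consume real magnitude images.  Full-reference metrics expect
both images normalized to [0, 1] by the ground-truth maximum (done by
:func:`evaluate_stack`); the two no-reference metrics rescale internally.

FSIM and PIQE have no implementation in the installed scientific stack, so
both are implemented here from their published algorithms: FSIM as the
phase-congruency (log-Gabor, 4 scales × 4 orientations) and Scharr-gradient
similarity with constants T1 = 0.85 and T2 = 160 on a 0–255 scale; PIQE as
a 16×16 blockwise distortion score on the MSCN image with activity
threshold 0.1, with a simplified homogeneity test for the noise criterion
and per-block scores scaled so the final ratio lies in [0, 100] and a flat
image (no active blocks, empty sum) scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import convolve2d
from scipy.stats import norm
from skimage.metrics import structural_similarity as _sk_ssim

from eics.reconstruction import total_variation


# ---------------------------------------------------------------- basic FR


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10·log10(MAX²/MSE)`` in dB.

    ``x`` is the reference; identical images give ``inf``.
    """
    e = mse(x, y)
    if e == 0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / e))


def corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over all pixels."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if den == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.sum(xc * yc) / den)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
    mode: str = "windowed",
) -> float:
    """Structural similarity index.

    ``mode="windowed"`` (default) is the standard sliding Gaussian-window
    mean; ``mode="global"`` evaluates the single-window statistic over the
    whole image (the literal one-term formula), used for closed-form checks.
    """
    x, y = _check_pair(x, y)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    if mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = np.mean((x - mx) * (y - my))
        return float(
            (2 * mx * my + c1) * (2 * cxy + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if mode != "windowed":
        raise ValueError("mode must be 'windowed' or 'global'")
    if min(x.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}-pixel window")
    return float(
        _sk_ssim(
            x, y,
            gaussian_weights=True, sigma=sigma, win_size=win_size,
            use_sample_covariance=False, K1=k1, K2=k2, data_range=data_range,
        )
    )


# ---------------------------------------------------------------------- FSIM


def _loggabor_bank(shape, n_scales=4, n_orient=4, min_wavelength=6.0,
                   mult=2.0, sigma_onf=0.55, d_theta_sigma=1.2):
    """Single-sided log-Gabor frequency-domain filters (analytic responses)."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    radial = []
    for s in range(n_scales):
        f0 = 1.0 / (min_wavelength * mult**s)
        g = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2))
        g[0, 0] = 0.0
        radial.append(g)

    dtheta_std = (np.pi / n_orient) / d_theta_sigma
    angular = []
    for o in range(n_orient):
        angl = o * np.pi / n_orient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dt = np.abs(np.arctan2(ds, dc))
        angular.append(np.exp(-(dt**2) / (2 * dtheta_std**2)))
    return radial, angular


def phase_congruency(image: np.ndarray, n_scales=4, n_orient=4, noise_k=2.0):
    """Phase-congruency map (log-Gabor bank, per-orientation noise threshold)."""
    image = np.asarray(image, dtype=float)
    F = np.fft.fft2(image)
    radial, angular = _loggabor_bank(image.shape, n_scales, n_orient)
    eps = 1e-4
    energy_sum = np.zeros(image.shape)
    amp_sum = np.zeros(image.shape)
    for ang in angular:
        resp_sum = np.zeros(image.shape, dtype=complex)
        an_sum = np.zeros(image.shape)
        a1_med = 0.0
        for s, rad in enumerate(radial):
            resp = np.fft.ifft2(F * rad * ang)
            an = np.abs(resp)
            resp_sum += resp
            an_sum += an
            if s == 0:
                a1_med = float(np.median(an))
        energy = np.abs(resp_sum)
        # noise threshold estimated from the finest-scale amplitude (Rayleigh)
        tau = a1_med / np.sqrt(np.log(4))
        total_tau = tau * (1 - 0.5**n_scales) / 0.5
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        T = noise_mean + noise_k * noise_sigma
        energy_sum += np.maximum(energy - T, 0.0)
        amp_sum += an_sum
    return energy_sum / (amp_sum + eps)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0


def _scharr_gradient(x: np.ndarray) -> np.ndarray:
    gx = convolve2d(x, _SCHARR_X, mode="same", boundary="symm")
    gy = convolve2d(x, _SCHARR_X.T, mode="same", boundary="symm")
    return np.hypot(gx, gy)


def fsim(x: np.ndarray, y: np.ndarray, t1: float = 0.85, t2: float = 160.0) -> float:
    """Feature similarity index: phase-congruency- and gradient-based.

    Images are rescaled internally to 0–255 (the scale of the stabilization
    constants).  ``x`` is the reference (the PC-weighted pooling uses the
    pointwise max of the two PC maps, so the value is symmetric in practice).
    """
    x, y = _check_pair(x, y)
    if min(x.shape) < 32:
        raise ValueError("fsim needs images of at least 32x32 pixels")
    scale = max(x.max(), y.max(), 1e-12)
    x = x * (255.0 / scale)
    y = y * (255.0 / scale)
    pc1, pc2 = phase_congruency(x), phase_congruency(y)
    g1, g2 = _scharr_gradient(x), _scharr_gradient(y)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pcm = np.maximum(pc1, pc2)
    return float(np.sum(s_pc * s_g * pcm) / (np.sum(pcm) + 1e-12))


# ----------------------------------------------------------------------- SI


def sharpness_index(
    x: np.ndarray,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
    mode: str = "tail",
) -> float:
    """Sharpness index from total variation under random-phase resampling.

    The TV of ``x`` is compared with the TV distribution of images sharing
    its Fourier modulus but with randomized phases: with ``z = (μ_TV −
    TV(x))/σ_TV``, ``mode="tail"`` (default) returns ``−log10 Φ̄(z)`` (upper
    Gaussian tail, computed in log space so very sharp images score in the
    hundreds), while ``mode="literal"`` returns ``−log10 z`` directly.
    Higher is sharper; a random-phase image itself scores ≈ ``−log10 0.5``.
    """
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise ValueError("sharpness index undefined for a constant image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modulus = np.abs(np.fft.fft2(x))
    tvs = np.empty(n_resamples)
    for i in range(n_resamples):
        noise = rng.standard_normal(x.shape)
        phase = np.exp(1j * np.angle(np.fft.fft2(noise)))  # Hermitian phases
        tvs[i] = total_variation(np.fft.ifft2(modulus * phase).real)
    mu, sigma = tvs.mean(), tvs.std()
    if sigma == 0:
        raise ValueError("degenerate TV distribution under phase resampling")
    z = (mu - total_variation(x)) / sigma
    if mode == "literal":
        if z <= 0:
            return float("-inf")
        return float(-np.log10(z))
    if mode != "tail":
        raise ValueError("mode must be 'tail' or 'literal'")
    return float(-norm.logsf(z) / np.log(10.0))


# --------------------------------------------------------------------- PIQE


def _mscn(image255: np.ndarray) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients (7×7 Gaussian window)."""
    mu = gaussian_filter(image255, sigma=7.0 / 6.0, truncate=2.9)
    sigma = np.sqrt(np.abs(gaussian_filter(image255**2, sigma=7.0 / 6.0, truncate=2.9) - mu**2))
    return (image255 - mu) / (sigma + 1.0)


def _segment_stds(line: np.ndarray, width: int = 6) -> np.ndarray:
    n = line.size - width + 1
    return np.array([line[i:i + width].std() for i in range(n)])


def piqe(
    x: np.ndarray,
    block_size: int = 16,
    activity_threshold: float = 0.1,
    segment_threshold: float = 0.1,
    c1: float = 1.0,
) -> float:
    """Perceptual image quality evaluator; lower is better, range [0, 100].

    Blockwise on the MSCN image: blocks with variance ≥ 0.1 are spatially
    active; active blocks are scored for noticeable artifacts (a low-variance
    6-pixel segment on any block edge) and for Gaussian noise (homogeneous
    activity: center and full-block deviations agree).  Per-block distortions
    are on a 0–100 scale and pooled as ``(Σ D + C1)/(N_SA + C1)`` with
    ``C1 = 1``, so an image with no active blocks scores exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if min(x.shape) < 64:
        raise ValueError("piqe needs images of at least 64x64 pixels")
    scale = x.max()
    img = x * (255.0 / scale) if scale > 0 else x
    m = _mscn(img)
    B = block_size
    rows, cols = (s // B for s in m.shape)
    n_active = 0
    dist_sum = 0.0
    for bi in range(rows):
        for bj in range(cols):
            blk = m[bi * B:(bi + 1) * B, bj * B:(bj + 1) * B]
            var = blk.var()
            if var < activity_threshold:
                continue
            n_active += 1
            edges = [blk[0], blk[-1], blk[:, 0], blk[:, -1]]
            impaired = any(
                np.any(_segment_stds(e) < segment_threshold) for e in edges
            )
            center = blk[B // 4: -B // 4, B // 4: -B // 4]
            ratio = center.std() / (blk.std() + 1e-12)
            noisy = abs(ratio - 1.0) < 0.35
            d = 0.0
            if impaired:
                d = 1.0
            if noisy:
                d = max(d, min(var, 1.0))
            dist_sum += 100.0 * d
    return float((dist_sum + c1) / (n_active + c1))


# ------------------------------------------------------------------- report


@dataclass
class MetricsReport:
    """Per-slice metric table, its column means, and run metadata."""

    per_slice: pd.DataFrame
    averages: pd.Series
    metadata: dict

    def __post_init__(self) -> None:
        expected = self.per_slice.mean(axis=0)
        if not np.allclose(
            self.averages.values, expected.values, equal_nan=True
        ):
            raise ValueError("averages must equal per-slice column means")


FR_COLUMNS = ("ssim", "fsim", "mse", "psnr_db", "corr")
NR_COLUMNS = ("si", "piqe")
#: True where larger metric values mean better quality.
HIGHER_IS_BETTER = {
    "ssim": True, "fsim": True, "mse": False, "psnr_db": True,
    "corr": True, "si": True, "piqe": False,
}


def evaluate_stack(
    recon,
    truth=None,
    si_resamples: int = 100,
    seed: int = 0,
    metadata: dict | None = None,
) -> MetricsReport:
    """Score a reconstructed stack slice by slice.

    With ground truth, both stacks are normalized by the truth's maximum and
    all seven metrics are computed; without it only the two no-reference
    metrics are.  The report's averages are the arithmetic per-column means.
    """
    rdata = np.asarray(recon.data, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    if truth is not None:
        tdata = np.asarray(truth.data, dtype=float)
        if tdata.shape != rdata.shape:
            raise ValueError("reconstruction and truth stacks differ in shape")
        peak = tdata.max()
        tnorm = tdata / peak
        rnorm = rdata / peak
    for i in range(rdata.shape[0]):
        row: dict[str, float] = {}
        if truth is not None:
            t, r = tnorm[i], rnorm[i]
            row["ssim"] = ssim(t, r)
            row["fsim"] = fsim(t, r)
            row["mse"] = mse(t, r)
            row["psnr_db"] = psnr(t, r)
            row["corr"] = corr(t, r)
        row["si"] = sharpness_index(rdata[i], n_resamples=si_resamples, seed=rng)
        row["piqe"] = piqe(rdata[i])
        rows.append(row)
    per_slice = pd.DataFrame(rows)
    per_slice.index.name = "slice"
    return MetricsReport(
        per_slice=per_slice,
        averages=per_slice.mean(axis=0),
        metadata=metadata or {},
    )
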