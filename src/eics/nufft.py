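"""Nonuniform Fourier operators via oversampled-FFT Kaiser-Bessel gridding.

The forward operator evaluates the discrete-space Fourier transform of an
N×N image at arbitrary k-space locations (type-2 NUFFT, "inverse gridding");
the adjoint spreads samples back onto the Cartesian grid ("gridding").  The
pair is an exact matrix adjoint by construction: forward is

    ``s = (1/N) · A · F · Z · D · x``

with D the diagonal deapodization, Z zero-padding into the oversampled grid,
F the (unnormalized, centered) 2-D FFT and A the sparse Kaiser-Bessel
interpolation matrix; the adjoint applies the conjugate transposes in
reverse.  The 1/N scale makes the forward agree with the unitary-style
direct transform ``s(k) = (1/N) Σ_n x[n] exp(-2πi k·(n - N/2))``.

Defaults (oversampling 2, kernel width 4, Beatty shape parameter) give a
relative ℓ2 accuracy of ~1e-4 against the direct transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import i0

from eics.kspace import SampledKSpace
from eics.trajectories import DensityWeights, RadialTrajectory, ramp_dcf


def _kb_beta(width: int, oversampling: float) -> float:
    """Kaiser-Bessel shape parameter.

    Beatty's closed form, raised by 3%: the published constant minimizes the
    worst-case aliasing amplitude, while the slightly larger value balances
    low-frequency (smooth-image) against broadband interpolation error and
    keeps both near 7e-4 relative l2 at width 4, oversampling 2.
    """
    w, s = float(width), float(oversampling)
    return 1.03 * np.pi * np.sqrt((w / s) ** 2 * (s - 0.5) ** 2 - 0.8)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on grid offsets u, support |u| <= W/2."""
    t = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=float)
    inside = t > 0
    out[inside] = i0(beta * np.sqrt(t[inside]))
    return out


def _kb_apodization(pos: np.ndarray, width: int, beta: float, grid: int) -> np.ndarray:
    """Continuous Fourier transform of the kernel at image positions (pixels).

    Closed form of ∫ I0(β√(1-(2u/W)²)) e^{-2πiup/G} du; always on the sinh
    branch for the supported geometry (β > πW·N/(2G)).
    """
    t = np.pi * width * np.asarray(pos, dtype=float) / grid
    arg = beta**2 - t**2
    out = np.empty_like(t)
    pos_branch = arg > 0
    s = np.sqrt(arg[pos_branch])
    out[pos_branch] = np.sinh(s) / s
    s = np.sqrt(-arg[~pos_branch] + 1e-30)
    out[~pos_branch] = np.sinc(s / np.pi)
    return width * out


@dataclass(frozen=True)
class NufftOperator:
    """Matched forward/adjoint nonuniform Fourier operator for one trajectory."""

    coords: np.ndarray
    dcf: np.ndarray
    matrix_size: int
    oversampling: float = 2.0
    kernel_width: int = 4
    normalization: float = field(init=False, default=0.0)
    _interp: sp.csr_matrix = field(init=False, default=None, repr=False)  # type: ignore
    _apod2d: np.ndarray = field(init=False, default=None, repr=False)  # type: ignore
    _grid: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.size == 0 or coords.shape[1] != 2:
            raise ValueError("trajectory must contain at least one (kx, ky) sample")
        if np.any(coords < -0.5) or np.any(coords >= 0.5):
            raise ValueError("k-space coordinates must lie in [-0.5, 0.5)")
        dcf = np.asarray(self.dcf, dtype=float)
        if dcf.shape != (coords.shape[0],):
            raise ValueError("dcf must hold one weight per trajectory sample")
        N = int(self.matrix_size)
        if N < 2:
            raise ValueError("matrix_size must be >= 2")
        G = int(round(self.oversampling * N))
        G += G % 2
        W = int(self.kernel_width)
        beta = _kb_beta(W, G / N)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "dcf", dcf)
        object.__setattr__(self, "matrix_size", N)
        object.__setattr__(self, "_grid", G)
        object.__setattr__(self, "normalization", 1.0 / N)
        object.__setattr__(self, "_interp", self._build_interp(coords, G, W, beta))
        pos = np.arange(N) - N // 2
        apod = _kb_apodization(pos, W, beta, G)
        object.__setattr__(self, "_apod2d", np.outer(apod, apod))

    @staticmethod
    def _build_interp(coords: np.ndarray, G: int, W: int, beta: float) -> sp.csr_matrix:
        n = coords.shape[0]
        g = coords * G + G // 2  # continuous grid positions in [0, G)
        offsets = np.arange(-(W // 2) + 1, W // 2 + 1)
        rows = np.repeat(np.arange(n), W * W)
        mx = np.floor(g[:, 0])[:, None] + offsets[None, :]
        my = np.floor(g[:, 1])[:, None] + offsets[None, :]
        wx = _kb_kernel(g[:, 0][:, None] - mx, W, beta)
        wy = _kb_kernel(g[:, 1][:, None] - my, W, beta)
        cols = ((mx.astype(int) % G)[:, :, None] * G
                + (my.astype(int) % G)[:, None, :])
        vals = wx[:, :, None] * wy[:, None, :]
        A = sp.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(n, G * G)
        )
        A.sum_duplicates()
        return A

    @property
    def n_samples(self) -> int:
        return int(self.coords.shape[0])

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate the image's Fourier transform at the trajectory samples."""
        image = np.asarray(image)
        N, G = self.matrix_size, self._grid
        if image.shape != (N, N):
            raise ValueError(f"image must be {N}x{N}, got {image.shape}")
        x = image.astype(complex) / self._apod2d
        pad = np.zeros((G, G), dtype=complex)
        lo = (G - N) // 2
        pad[lo:lo + N, lo:lo + N] = x
        spectrum = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pad)))
        return (self._interp @ spectrum.ravel()) * self.normalization

    def adjoint(self, samples: np.ndarray, apply_dcf: bool = False) -> np.ndarray:
        """Spread samples back to an N×N image (exact adjoint of :meth:`forward`).

        With ``apply_dcf`` the samples are density-compensated first, giving
        the conventional gridding reconstruction; without it, the plain
        adjoint used inside iterative solvers.
        """
        samples = np.asarray(samples, dtype=complex).ravel()
        if samples.size != self.n_samples:
            raise ValueError(
                f"expected {self.n_samples} samples, got {samples.size}"
            )
        if apply_dcf:
            samples = samples * self.dcf
        N, G = self.matrix_size, self._grid
        grid = (self._interp.conj().T @ samples).reshape(G, G)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * (G * G)
        lo = (G - N) // 2
        img = img[lo:lo + N, lo:lo + N]
        return img / self._apod2d * self.normalization

    def forward_kspace(self, image: np.ndarray, source_mask: object = None) -> SampledKSpace:
        """Forward transform packaged as a :class:`SampledKSpace` set."""
        return SampledKSpace.from_samples(
            self.coords, self.forward(image), source_mask=source_mask
        )


def build_operator(
    traj: RadialTrajectory | np.ndarray,
    dcf: DensityWeights | np.ndarray | None = None,
    matrix_size: int | None = None,
    oversampling: float = 2.0,
    kernel_width: int = 4,
) -> NufftOperator:
    """Construct a :class:`NufftOperator` from a trajectory or raw coordinates.

    When ``traj`` is a :class:`RadialTrajectory`, the matrix size defaults to
    the trajectory's and the DCF to its Ram-Lak ramp.
    """
    if isinstance(traj, RadialTrajectory):
        coords = traj.coords
        if matrix_size is None:
            matrix_size = traj.matrix_size
        if dcf is None:
            dcf = ramp_dcf(traj)
    else:
        coords = np.atleast_2d(np.asarray(traj, dtype=float))
        if matrix_size is None:
            raise ValueError("matrix_size is required for raw coordinates")
        if dcf is None:
            raise ValueError("dcf is required for raw coordinates")
    weights = dcf.weights if isinstance(dcf, DensityWeights) else np.asarray(dcf, float)
    return NufftOperator(
        coords=coords,
        dcf=weights,
        matrix_size=int(matrix_size),
        oversampling=oversampling,
        kernel_width=kernel_width,
    )


def direct_nudft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force nonuniform DFT oracle, O(N²·n) — small problems only.

    Same convention as :meth:`NufftOperator.forward`:
    ``s(k) = (1/N) Σ_n x[n] exp(-2πi k·(n - N/2))``.
    """
    image = np.asarray(image, dtype=complex)
    N = image.shape[0]
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = np.arange(N) - N // 2
    ex = np.exp(-2j * np.pi * coords[:, 0][:, None] * n[None, :])
    ey = np.exp(-2j * np.pi * coords[:, 1][:, None] * n[None, :])
    return np.einsum("ki,ij,kj->k", ex, image, ey) / N
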