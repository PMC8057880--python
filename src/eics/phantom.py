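"""Synthetic multislice phantom with controllable interslice correlation.

Multislice interpolation works because anatomy changes slowly from slice to
slice.  The generator emulates exactly that: slice 0 is a Shepp-Logan-like
superposition of random ellipses, and each subsequent slice perturbs every
ellipse's center, axes and orientation by small independent Gaussian steps —
a random walk across the slice dimension, so pixelwise correlation decays
with slice distance (the property the interslice-gap experiment stresses).
It does not model MR physics: no coil sensitivities, relaxation contrast or
k-space noise correlation, only magnitude images with additive Gaussian
noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np


@dataclass
class SliceStack:
    """Ordered real magnitude slices with spacing metadata.

    Generated phantoms are normalized to [0, 1]; reconstructed stacks may
    overshoot 1 slightly, so the container only requires finite nonnegative
    magnitudes.
    """

    data: np.ndarray
    slice_thickness: float = 1.0
    interslice_gap: int = 0
    seed: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("stack data must be (n_slices, N, N)")
        if not np.all(np.isfinite(data)) or data.min() < 0:
            raise ValueError("slice magnitudes must be finite and nonnegative")
        self.data = data

    @property
    def n_slices(self) -> int:
        return int(self.data.shape[0])

    @property
    def matrix_size(self) -> int:
        return int(self.data.shape[1])


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom parameters.

    ``drift`` is the per-slice random-walk step for ellipse centers and axes,
    as a fraction of the matrix size; 0 gives identical slices.  Defaults are
    a desk-scale stand-in for a 320×320×256 knee acquisition.
    """

    n_slices: int = 24
    matrix_size: int = 128
    drift: float = 0.004
    n_ellipses: int = 8
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.matrix_size % 16 != 0:
            raise ValueError("matrix_size must be a multiple of 16")
        if self.drift < 0 or self.noise_sigma < 0:
            raise ValueError("drift and noise_sigma must be >= 0")
        if self.n_ellipses < 1:
            raise ValueError("n_ellipses must be >= 1")


def _render_ellipses(N: int, params: np.ndarray) -> np.ndarray:
    """Accumulate ellipses given rows (cx, cy, a, b, theta, intensity)."""
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    img = np.zeros((N, N))
    for cx, cy, a, b, theta, val in params:
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] += val
    return img


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> SliceStack:
    """Generate a multislice phantom stack; deterministic for a fixed spec.

    Slice 0 is a large head-like ellipse plus ``n_ellipses - 1`` random
    interior ellipses with signed intensities; each later slice applies a
    Gaussian random-walk step of std ``drift × N`` pixels to every ellipse's
    center and axes (and a proportional step to its orientation), then adds
    Gaussian noise and clips to [0, 1].
    """
    spec = spec or PhantomSpec()
    if overrides:
        from dataclasses import replace

        spec = replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    N = spec.matrix_size
    k = spec.n_ellipses

    params = np.zeros((k, 6))
    params[0] = (N / 2, N / 2, 0.44 * N, 0.38 * N, rng.uniform(0, np.pi), 0.6)
    for i in range(1, k):
        params[i] = (
            rng.uniform(0.3 * N, 0.7 * N),
            rng.uniform(0.3 * N, 0.7 * N),
            rng.uniform(0.04 * N, 0.18 * N),
            rng.uniform(0.04 * N, 0.18 * N),
            rng.uniform(0, np.pi),
            rng.uniform(-0.35, 0.35),
        )

    step = spec.drift * N
    slices = []
    for _ in range(spec.n_slices):
        img = np.clip(_render_ellipses(N, params), 0.0, 1.0)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        slices.append(np.clip(img, 0.0, 1.0))
        walk = np.zeros_like(params)
        walk[:, 0:2] = rng.normal(0.0, step, size=(k, 2))      # centers
        walk[:, 2:4] = rng.normal(0.0, 0.5 * step, size=(k, 2))  # axes
        walk[:, 4] = rng.normal(0.0, 2.0 * spec.drift, size=k)   # orientation
        params = params + walk
        params[:, 2:4] = np.maximum(params[:, 2:4], 2.0)  # keep ellipses nondegenerate
    return SliceStack(
        data=np.stack(slices),
        seed=spec.seed,
        description=(
            f"synthetic ellipse phantom: n={spec.n_slices}, N={N}, "
            f"drift={spec.drift}, noise={spec.noise_sigma}, seed={spec.seed}"
        ),
    )


def correlation_profile(stack: SliceStack, max_lag: int) -> np.ndarray:
    """Mean pixelwise Pearson correlation between slice pairs at each lag.

    Element g of the result (lag g = 0 … max_lag) is the mean correlation of
    all slice pairs (i, i+g); sampling the profile at lag g+1 predicts the
    adjacent-slice correlation of a stack decimated with interslice gap g.
    """
    data = stack.data
    S = data.shape[0]
    if not (0 <= max_lag < S):
        raise ValueError("max_lag must satisfy 0 <= max_lag < n_slices")
    flat = data.reshape(S, -1)
    sd = flat.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant slice: correlation undefined")
    z = (flat - flat.mean(axis=1, keepdims=True)) / sd[:, None]
    out = np.empty(max_lag + 1)
    for g in range(max_lag + 1):
        out[g] = np.mean(np.sum(z[: S - g] * z[g:], axis=1) / flat.shape[1])
    return out


def save_stack(stack: SliceStack, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a stack as NIfTI (``.nii``/``.nii.gz``, axes (N, N, S)) or ``.npz``."""
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([1.0, 1.0, stack.slice_thickness, 1.0])
        img = nib.Nifti1Image(np.moveaxis(stack.data, 0, -1), affine)
        img.header["descrip"] = stack.description[:79].encode()
        nib.save(img, os.fspath(path))
    elif fmt == "npz":
        np.savez(
            os.fspath(path),
            data=stack.data,
            slice_thickness=stack.slice_thickness,
            interslice_gap=stack.interslice_gap,
            seed=-1 if stack.seed is None else stack.seed,
            description=stack.description,
        )
    else:
        raise ValueError(f"unsupported stack format: {fmt!r}")


def load_stack(path: str | os.PathLike, fmt: str | None = None) -> SliceStack:
    """Load a stack; magnitudes are normalized to [0, 1], scale in description."""
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(os.fspath(path))
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        thickness = float(img.header.get_zooms()[2]) if len(img.header.get_zooms()) > 2 else 1.0
        desc = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
        return _normalized(data, thickness, None, desc)
    if fmt == "npz":
        with np.load(os.fspath(path), allow_pickle=False) as f:
            seed = int(f["seed"])
            return _normalized(
                np.asarray(f["data"], dtype=float),
                float(f["slice_thickness"]),
                None if seed < 0 else seed,
                str(f["description"]),
                gap=int(f["interslice_gap"]),
            )
    raise ValueError(f"unsupported stack format: {fmt!r}")


def _normalized(data, thickness, seed, desc, gap=0) -> SliceStack:
    scale = float(data.max())
    if scale > 0 and (scale > 1 or data.min() < 0):
        data = np.clip(data, 0, None) / scale
        desc = f"{desc} [rescaled by 1/{scale:g}]"
    return SliceStack(
        data=data,
        slice_thickness=thickness,
        interslice_gap=gap,
        seed=seed,
        description=desc,
    )


def _infer_format(path: str | os.PathLike) -> str:
    name = os.fspath(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "npz"
    raise ValueError(f"cannot infer stack format from path {name!r}")
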