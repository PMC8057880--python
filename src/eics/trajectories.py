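"""Radial k-space trajectories: spoke budgets, angle schedules, mask triples, DCF.

Conventions shared by the whole package:

* spoke angles are reduced modulo 180° (a spoke is a full diameter, so the
  angle θ and θ+180° index the same line);
* k-space coordinates are in cycles/pixel; a spoke with ``n_readout = N``
  samples covers the diameter on the grid ``(-N/2 … N/2-1)/N`` ⊂ [-0.5, 0.5),
  which contains the exact DC point when ``n_readout`` is even;
* image coordinates are 0-based pixel indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0
#: Golden-angle azimuthal increment, 180°/φ ≈ 111.246°.
GOLDEN_ANGLE_DEG = 180.0 / GOLDEN_RATIO

_SCHEMES = ("uniform", "golden")


def _round_half_away(x: float) -> int:
    """Round half away from zero (the convention used for spoke budgets)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class RadialTrajectory:
    """An ordered set of radial spokes through the k-space origin.

    Parameters
    ----------
    angles_deg
        Spoke angles in degrees, each in [0, 180), pairwise distinct.
    n_readout
        Samples per spoke (a full diameter).
    matrix_size
        Side N of the target N×N image.
    scheme
        ``"uniform"`` or ``"golden"``.
    spoke_ids
        Stable integer identity per spoke (acquisition order).
    """

    angles_deg: np.ndarray
    n_readout: int
    matrix_size: int
    scheme: str
    spoke_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("angles_deg must be a non-empty 1-D sequence")
        if np.any(angles < 0) or np.any(angles >= 180.0):
            raise ValueError("spoke angles must lie in [0, 180)")
        if np.unique(angles).size != angles.size:
            raise ValueError("spoke angles must be pairwise distinct")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {_SCHEMES}")
        if int(self.n_readout) < 2:
            raise ValueError("n_readout must be >= 2")
        if int(self.matrix_size) < 2:
            raise ValueError("matrix_size must be >= 2")
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "n_readout", int(self.n_readout))
        object.__setattr__(self, "matrix_size", int(self.matrix_size))
        ids = self.spoke_ids
        if ids is None:
            ids = np.arange(angles.size)
        ids = np.asarray(ids, dtype=int)
        if ids.shape != angles.shape:
            raise ValueError("spoke_ids must match angles_deg in length")
        object.__setattr__(self, "spoke_ids", ids)

    @property
    def n_spokes(self) -> int:
        return int(self.angles_deg.size)

    @property
    def n_samples(self) -> int:
        return self.n_spokes * self.n_readout

    @property
    def radii(self) -> np.ndarray:
        """Signed radial positions along one spoke, in cycles/pixel."""
        n = self.n_readout
        return (np.arange(n) - n // 2) / float(self.matrix_size)

    @property
    def coords(self) -> np.ndarray:
        """Per-sample (kx, ky), shape (n_spokes*n_readout, 2), cycles/pixel."""
        theta = np.deg2rad(self.angles_deg)[:, None]
        r = self.radii[None, :]
        kx = r * np.cos(theta)
        ky = r * np.sin(theta)
        return np.stack([kx.ravel(), ky.ravel()], axis=-1)

    @property
    def sample_spoke_ids(self) -> np.ndarray:
        """Spoke id of every sample, aligned with :attr:`coords`."""
        return np.repeat(self.spoke_ids, self.n_readout)


@dataclass(frozen=True)
class MaskTriple:
    """Three radial masks with equal spoke counts and pairwise disjoint angles."""

    masks: tuple[RadialTrajectory, RadialTrajectory, RadialTrajectory]

    def __post_init__(self) -> None:
        if len(self.masks) != 3:
            raise ValueError("a MaskTriple holds exactly three masks")
        a, b, c = self.masks
        if not (a.n_spokes == b.n_spokes == c.n_spokes):
            raise ValueError("the three masks must have equal spoke counts")
        if not (a.n_readout == b.n_readout == c.n_readout):
            raise ValueError("the three masks must share n_readout")
        if not (a.matrix_size == b.matrix_size == c.matrix_size):
            raise ValueError("the three masks must share matrix_size")
        if not (a.scheme == b.scheme == c.scheme):
            raise ValueError("the three masks must share the sampling scheme")
        sets = [set(np.round(m.angles_deg, 9)) for m in self.masks]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("mask angle sets must be pairwise disjoint")

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i: int) -> RadialTrajectory:
        return self.masks[i]


@dataclass(frozen=True)
class DensityWeights:
    """Nonnegative density-compensation weight per trajectory sample."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w < 0):
            raise ValueError("density weights must be nonnegative")
        object.__setattr__(self, "weights", w)


def nyquist_spokes(matrix_size: int) -> int:
    """Uniform-spoke count meeting the azimuthal Nyquist criterion.

    For an N×N image with full-diameter readouts of N samples, azimuthal
    Nyquist requires ``round(π/2 · N)`` spokes (402 for N = 256).
    """
    if not float(matrix_size).is_integer() or int(matrix_size) < 2:
        raise ValueError("matrix_size must be an integer >= 2")
    return _round_half_away(math.pi / 2.0 * int(matrix_size))


def spokes_for_ratio(ratio: float, matrix_size: int) -> int:
    """Spoke budget for a target sampling ratio (fraction of Nyquist spokes).

    At N = 256 the ratios 3/5/7/9 % give 12/20/28/36 spokes.
    """
    ratio = float(ratio)
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must lie in (0, 1]")
    return max(1, _round_half_away(ratio * nyquist_spokes(matrix_size)))


def golden_angles(n_spokes: int, start_deg: float = 0.0) -> np.ndarray:
    """Golden-angle schedule: ``(start + i·180/φ) mod 180`` in acquisition order.

    The increment 180°/φ ≈ 111.246° is irrational in units of the half-turn,
    so no spoke is ever acquired twice.
    """
    n_spokes = _check_spoke_count(n_spokes)
    i = np.arange(n_spokes, dtype=float)
    return np.mod(float(start_deg) + i * GOLDEN_ANGLE_DEG, 180.0)


def uniform_angles(n_spokes: int, offset_deg: float = 0.0) -> np.ndarray:
    """Uniformly spaced schedule: ``(offset + i·180/n) mod 180``."""
    n_spokes = _check_spoke_count(n_spokes)
    i = np.arange(n_spokes, dtype=float)
    return np.mod(float(offset_deg) + i * (180.0 / n_spokes), 180.0)


def _check_spoke_count(n_spokes: int) -> int:
    if not float(n_spokes).is_integer() or int(n_spokes) < 1:
        raise ValueError("n_spokes must be a positive integer")
    return int(n_spokes)


def make_trajectory(
    n_spokes: int,
    scheme: str,
    matrix_size: int,
    offset_or_start: float = 0.0,
    n_readout: int | None = None,
) -> RadialTrajectory:
    """Build a single radial trajectory with ``n_readout = matrix_size`` default."""
    if scheme == "uniform":
        angles = uniform_angles(n_spokes, offset_or_start)
    elif scheme == "golden":
        angles = golden_angles(n_spokes, offset_or_start)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    return RadialTrajectory(
        angles_deg=angles,
        n_readout=matrix_size if n_readout is None else n_readout,
        matrix_size=matrix_size,
        scheme=scheme,
    )


def make_mask_triple(
    n_spokes: int,
    scheme: str,
    matrix_size: int,
    offset_or_start: float = 0.0,
) -> MaskTriple:
    """Three nonoverlapping masks by round-robin split of one 3n-angle schedule.

    A single schedule of ``3·n_spokes`` angles is generated by the chosen
    scheme and angle i is assigned to mask ``i mod 3``, so the three masks
    sample pairwise disjoint locations while each inherits the scheme's
    angular statistics (for golden angles, per-mask temporal incoherence).
    """
    n_spokes = _check_spoke_count(n_spokes)
    if scheme == "uniform":
        all_angles = uniform_angles(3 * n_spokes, offset_or_start)
    elif scheme == "golden":
        all_angles = golden_angles(3 * n_spokes, offset_or_start)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    all_ids = np.arange(3 * n_spokes)
    masks = []
    for j in range(3):
        sel = slice(j, None, 3)
        masks.append(
            RadialTrajectory(
                angles_deg=all_angles[sel],
                n_readout=matrix_size,
                matrix_size=matrix_size,
                scheme=scheme,
                spoke_ids=all_ids[sel],
            )
        )
    return MaskTriple(masks=tuple(masks))


def ramp_dcf(traj: RadialTrajectory) -> DensityWeights:
    """Ram-Lak ramp density compensation for a radial trajectory.

    Each sample's weight is the polar area element of its k-space cell,
    scaled by N² so that density-compensated adjoint gridding of a
    full-Nyquist acquisition approximates the identity:

    ``w = π·N·|k| / n_spokes``,

    with the DC sample (shared by all full-diameter spokes) given a quarter
    of the first nonzero-|k| weight, the area of the central disc of radius
    half a radial step.
    """
    return DensityWeights(weights=ramp_dcf_for_coords(
        traj.coords, traj.matrix_size, traj.n_spokes
    ))


def ramp_dcf_for_coords(
    coords: np.ndarray, matrix_size: int, n_spokes_eff: float
) -> np.ndarray:
    """Ramp DCF for arbitrary radial-sample coordinates.

    ``n_spokes_eff`` is the (possibly non-integer) effective number of full
    diameters represented, used for interpolated sample sets that merge
    several masks.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0 or coords.shape[1] != 2:
        raise ValueError("coords must be a non-empty (n, 2) array")
    if n_spokes_eff <= 0:
        raise ValueError("effective spoke count must be positive")
    N = int(matrix_size)
    k = np.hypot(coords[:, 0], coords[:, 1])
    w = math.pi * N * k / float(n_spokes_eff)
    dc = k < 0.5 / N  # only the exact DC sample can be this close
    if np.any(dc):
        w[dc] = 0.25 * (math.pi / float(n_spokes_eff))
    return w


def export_table(traj: RadialTrajectory, dcf: DensityWeights | None = None) -> "np.ndarray":
    """Plain-text-friendly table: one row per sample (spoke_id, kx, ky, weight)."""
    coords = traj.coords
    w = ramp_dcf(traj).weights if dcf is None else dcf.weights
    if w.shape[0] != coords.shape[0]:
        raise ValueError("dcf length does not match trajectory sample count")
    return np.column_stack([traj.sample_spoke_ids.astype(float), coords, w])
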