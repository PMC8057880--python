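"""Interslice k-space interpolation by set algebra on sample locations.

Consecutive slices of a multislice acquisition are undersampled with three
nonoverlapping radial masks cycling with period 3.  Because adjacent slices
are strongly correlated, the missing samples of a target slice T can be
approximated by the samples its neighbors L and R acquired at *different*
locations:

    ``L_Tnew = L ⊖ T``        (new information in the left neighbor)
    ``R_Tnew = R ⊖ T``        (new information in the right neighbor)
    ``T_int  = L_Tnew ⊕ T ⊕ R_Tnew``

Sample values are copied verbatim (no averaging); every acquired sample of
the target slice survives intact, so the interpolated slice carries the
maximum possible amount of indigenous information.  The two-neighbor scheme
(eics) roughly triples the per-slice sample count; the one-neighbor baseline
(fics) is ``T ⊕ (L ⊖ T)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from eics.kspace import SampledKSpace
from eics.nufft import build_operator
from eics.trajectories import MaskTriple, ramp_dcf_for_coords

logger = logging.getLogger(__name__)

__all__ = [
    "SampledKSpace",
    "UndersampledStack",
    "undersample_stack",
    "set_difference",
    "set_union",
    "eics_interpolate",
    "fics_interpolate",
    "interpolate_stack",
    "provenance_table",
]

INTERP_METHODS = ("eics", "fics", "none")


@dataclass
class UndersampledStack:
    """Ordered undersampled (or interpolated) k-space slices.

    ``triple_assignment[i] = i mod 3`` records which mask of the triple
    sampled slice i; ``gap`` is the number of source slices skipped between
    retained slices when the source stack was decimated.
    """

    slices: list[SampledKSpace]
    triple: MaskTriple
    ratio: float
    gap: int = 0
    matrix_size: int = 0
    n_readout: int = 0
    method: str = "none"
    triple_assignment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.triple_assignment is None:
            self.triple_assignment = np.arange(len(self.slices)) % 3
        if self.matrix_size == 0:
            self.matrix_size = self.triple[0].matrix_size
        if self.n_readout == 0:
            self.n_readout = self.triple[0].n_readout

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def undersample_stack(stack, triple: MaskTriple, gap: int = 0) -> UndersampledStack:
    """Forward-sample a slice stack with a cycling nonoverlapping mask triple.

    The source stack is first decimated by keeping every (gap+1)-th slice;
    slice i of the retained stack is then sampled with mask ``i mod 3``.
    Acquired samples landing on the same quantized location (the shared DC
    point of full-diameter spokes) are stored once.
    """
    gap = int(gap)
    if gap < 0:
        raise ValueError("gap must be a nonnegative integer")
    data = np.asarray(stack.data, dtype=float)
    data = data[:: gap + 1]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 slices after gap decimation")
    n_spokes = triple[0].n_spokes
    ratio = n_spokes * triple[0].n_readout / float(triple[0].matrix_size ** 2)
    ops = [build_operator(mask) for mask in triple]
    slices = []
    for i in range(data.shape[0]):
        op = ops[i % 3]
        slices.append(op.forward_kspace(data[i], source_mask=f"R{i % 3 + 1}"))
    return UndersampledStack(
        slices=slices,
        triple=triple,
        ratio=ratio,
        gap=gap,
        matrix_size=triple[0].matrix_size,
        n_readout=triple[0].n_readout,
        method="none",
    )


def set_difference(a: SampledKSpace, b: SampledKSpace) -> SampledKSpace:
    """Entries of ``a`` whose locations are absent from ``b`` (``a ⊖ b``)."""
    if len(a) == 0:
        return a
    keep = ~np.isin(a.keys, b.keys, assume_unique=True)
    return a.select(keep)


def set_union(parts: Sequence[SampledKSpace]) -> SampledKSpace:
    """Union of sample sets (``⊕``); parts are expected pairwise disjoint.

    On an unexpected location collision the entry from the *earlier*-listed
    part wins (callers list parts in priority order, target slice first) and
    a warning is logged.
    """
    parts = [p for p in parts if len(p) > 0]
    if not parts:
        raise ValueError("union of no samples is undefined")
    keys = np.concatenate([p.keys for p in parts])
    coords = np.concatenate([p.coords for p in parts])
    values = np.concatenate([p.values for p in parts])
    prov_parts = [
        p.provenance if p.provenance is not None else np.full(len(p), "", "U1")
        for p in parts
    ]
    prov = np.concatenate(prov_parts)
    uniq, first = np.unique(keys, return_index=True)
    if uniq.size != keys.size:
        logger.warning(
            "set_union: %d colliding sample location(s); keeping earlier-listed entries",
            keys.size - uniq.size,
        )
        first.sort()
        keys, coords, values, prov = keys[first], coords[first], values[first], prov[first]
    src = {p.source_mask for p in parts}
    return SampledKSpace(
        coords=coords, values=values, keys=keys, provenance=prov,
        source_mask=src.pop() if len(src) == 1 else "+".join(map(str, sorted(src, key=str))),
    )


def eics_interpolate(
    l: SampledKSpace, t: SampledKSpace, r: SampledKSpace
) -> SampledKSpace:
    """Three-slice interpolation ``(L ⊖ T) ⊕ T ⊕ (R ⊖ T)``.

    The target slice's samples always survive intact; collisions between the
    two neighbor differences (impossible for nonoverlapping full-diameter
    masks, whose only shared location, DC, is removed by ``⊖ T``) resolve in
    favor of the left neighbor.
    """
    l_new = set_difference(l, t).tagged("L")
    r_new = set_difference(r, t).tagged("R")
    return set_union([t.tagged("T"), l_new, r_new])


def fics_interpolate(l: SampledKSpace, t: SampledKSpace) -> SampledKSpace:
    """Two-slice baseline interpolation ``T ⊕ (L ⊖ T)``."""
    return set_union([t.tagged("T"), set_difference(l, t).tagged("L")])


def interpolate_stack(u: UndersampledStack, method: str = "eics") -> UndersampledStack:
    """Interpolate every slice of an undersampled stack.

    Each slice is treated as a target with its two neighbors as L and R.
    Boundary slices have only one neighbor and degrade to the two-slice rule
    with that neighbor (logged once per run); ``method="none"`` passes the
    stack through unchanged apart from provenance tags (the plain-CS path).
    """
    if method not in INTERP_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {INTERP_METHODS}")
    n = u.n_slices
    if method == "none":
        out = [s.tagged("T") for s in u.slices]
    elif method == "fics":
        if n < 2:
            raise ValueError("fics needs at least 2 slices")
        out = [fics_interpolate(u.slices[1], u.slices[0])]
        out += [fics_interpolate(u.slices[i - 1], u.slices[i]) for i in range(1, n)]
        logger.info("fics: first slice interpolated from its right neighbor")
    else:
        if n < 3:
            raise ValueError("eics needs at least 3 slices")
        out = [fics_interpolate(u.slices[1], u.slices[0])]
        out += [
            eics_interpolate(u.slices[i - 1], u.slices[i], u.slices[i + 1])
            for i in range(1, n - 1)
        ]
        out.append(fics_interpolate(u.slices[n - 2], u.slices[n - 1]))
        logger.info("eics: boundary slices degraded to the one-neighbor rule")
    return UndersampledStack(
        slices=out,
        triple=u.triple,
        ratio=u.ratio,
        gap=u.gap,
        matrix_size=u.matrix_size,
        n_readout=u.n_readout,
        method=method,
        triple_assignment=u.triple_assignment.copy(),
    )


def provenance_table(u: UndersampledStack) -> pd.DataFrame:
    """Per-slice sample-provenance accounting.

    For each slice: the percentage of samples copied from the target (T) and
    from the left/right neighbors (L/R), plus the slice's total sample count
    as a fraction of the full N² Cartesian budget.  A final ``mean`` row
    averages the columns.  Percentages are reported unrounded and sum to 100
    per slice.
    """
    rows = []
    for i, s in enumerate(u.slices):
        if s.provenance is None:
            raise ValueError(f"slice {i} has no provenance tags")
        total = len(s)
        frac = {tag: 100.0 * np.count_nonzero(s.provenance == tag) / total
                for tag in ("T", "L", "R")}
        rows.append({
            "slice": i,
            "pct_T": frac["T"],
            "pct_L": frac["L"],
            "pct_R": frac["R"],
            "samples": total,
            "pct_of_grid": 100.0 * total / u.matrix_size**2,
        })
    df = pd.DataFrame(rows).set_index("slice")
    df.loc["mean"] = df.mean(axis=0)
    return df


def save_undersampled(u: UndersampledStack, path) -> None:
    """Serialize an (interpolated) undersampled stack to an ``.npz`` archive."""
    payload = {
        "n_slices": np.int64(u.n_slices),
        "ratio": float(u.ratio),
        "gap": np.int64(u.gap),
        "matrix_size": np.int64(u.matrix_size),
        "n_readout": np.int64(u.n_readout),
        "method": np.str_(u.method),
        "scheme": np.str_(u.triple[0].scheme),
        "triple_assignment": u.triple_assignment,
    }
    for j, mask in enumerate(u.triple):
        payload[f"mask{j}_angles"] = mask.angles_deg
        payload[f"mask{j}_ids"] = mask.spoke_ids
    for i, s in enumerate(u.slices):
        payload[f"slice{i}_coords"] = s.coords
        payload[f"slice{i}_values"] = s.values
        if s.provenance is not None:
            payload[f"slice{i}_prov"] = s.provenance
    np.savez(path, **payload)


def load_undersampled(path) -> UndersampledStack:
    """Load a stack written by :func:`save_undersampled`."""
    from eics.trajectories import RadialTrajectory

    with np.load(path, allow_pickle=False) as f:
        n = int(f["n_slices"])
        N = int(f["matrix_size"])
        n_readout = int(f["n_readout"])
        scheme = str(f["scheme"])
        masks = tuple(
            RadialTrajectory(
                angles_deg=f[f"mask{j}_angles"],
                n_readout=n_readout,
                matrix_size=N,
                scheme=scheme,
                spoke_ids=f[f"mask{j}_ids"],
            )
            for j in range(3)
        )
        slices = []
        for i in range(n):
            prov = f[f"slice{i}_prov"] if f"slice{i}_prov" in f else None
            slices.append(
                SampledKSpace(
                    coords=f[f"slice{i}_coords"],
                    values=f[f"slice{i}_values"],
                    provenance=prov,
                )
            )
        return UndersampledStack(
            slices=slices,
            triple=MaskTriple(masks=masks),
            ratio=float(f["ratio"]),
            gap=int(f["gap"]),
            matrix_size=N,
            n_readout=n_readout,
            method=str(f["method"]),
            triple_assignment=f["triple_assignment"],
        )


def combined_operator(s: SampledKSpace, matrix_size: int, n_readout: int):
    """NUFFT operator for an (interpolated) sample set's own locations.

    The ramp DCF uses the effective diameter count implied by the sample
    total: each full spoke contributes ``n_readout - 1`` unique non-DC
    samples plus the shared DC point.
    """
    n_eff = max((len(s) - 1) / float(n_readout - 1), 1.0)
    dcf = ramp_dcf_for_coords(s.coords, matrix_size, n_eff)
    return build_operator(s.coords, dcf=dcf, matrix_size=matrix_size)
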