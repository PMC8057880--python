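"""Canonical k-space sample sets: the carrier for all interpolation set algebra.

A :class:`SampledKSpace` maps quantized sample locations to complex values.
Location keys are the coordinates quantized to a step of 1e-6 cycles/pixel,
applied identically wherever a set is created, so that the set difference and
union used by interslice interpolation are well defined across masks.  With
full-diameter radial spokes the only cross-mask key collision is the DC point,
which every spoke contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Quantization step for sample locations, cycles/pixel.
QUANT_STEP = 1e-6
_OFF = np.int64(2**20)  # |k|/step <= 5e5 < 2**20
_SPAN = np.int64(2**21)


def quantize_coords(coords: np.ndarray) -> np.ndarray:
    """Map (n, 2) float coordinates to unique int64 location keys."""
    coords = np.asarray(coords, dtype=float)
    q = np.round(coords / QUANT_STEP).astype(np.int64)
    if np.any(np.abs(q) >= _OFF):
        raise ValueError("coordinates exceed the quantizable range [-0.5, 0.5]")
    return (q[:, 0] + _OFF) * _SPAN + (q[:, 1] + _OFF)


@dataclass(frozen=True)
class SampledKSpace:
    """Complex k-space samples keyed by quantized location.

    Attributes
    ----------
    coords
        (n, 2) sample locations in cycles/pixel.
    values
        Complex sample values, aligned with ``coords``.
    keys
        int64 quantized-location keys, unique within one set.
    provenance
        Optional per-sample tag ``"T"``, ``"L"`` or ``"R"`` (empty string if
        untagged) recording which slice a sample came from.
    source_mask
        Identifier of the generating mask (or a composite label).
    """

    coords: np.ndarray
    values: np.ndarray
    keys: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: np.ndarray | None = None
    source_mask: object = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        values = np.atleast_1d(np.asarray(self.values, dtype=complex))
        if coords.shape != (values.size, 2):
            raise ValueError("coords must be (n, 2) aligned with n values")
        keys = self.keys
        if keys is None:
            keys = quantize_coords(coords) if coords.size else np.empty(0, np.int64)
        keys = np.asarray(keys, dtype=np.int64)
        if keys.shape != (values.size,):
            raise ValueError("keys must align with values")
        if keys.size and np.unique(keys).size != keys.size:
            raise ValueError(
                "duplicate sample keys; build sets via from_samples(dedup=True)"
            )
        prov = self.provenance
        if prov is not None:
            prov = np.asarray(prov, dtype="U1")
            if prov.shape != (values.size,):
                raise ValueError("provenance must align with values")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "keys", keys)
        object.__setattr__(self, "provenance", prov)

    @classmethod
    def from_samples(
        cls,
        coords: np.ndarray,
        values: np.ndarray,
        provenance: str | np.ndarray | None = None,
        source_mask: object = None,
        dedup: bool = True,
    ) -> "SampledKSpace":
        """Build a set from raw samples, dropping repeated locations.

        When several acquired samples share a quantized location (full-diameter
        spokes all cross DC), the first occurrence is kept.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        values = np.atleast_1d(np.asarray(values, dtype=complex))
        keys = quantize_coords(coords) if coords.size else np.empty(0, np.int64)
        if dedup and keys.size:
            _, first = np.unique(keys, return_index=True)
            first.sort()
            coords, values, keys = coords[first], values[first], keys[first]
        prov = None
        if provenance is not None:
            if isinstance(provenance, str):
                prov = np.full(values.size, provenance, dtype="U1")
            else:
                prov = np.asarray(provenance, dtype="U1")
                if dedup and prov.size != values.size:
                    raise ValueError("per-sample provenance incompatible with dedup")
        return cls(coords=coords, values=values, keys=keys,
                   provenance=prov, source_mask=source_mask)

    def __len__(self) -> int:
        return int(self.values.size)

    def tagged(self, tag: str) -> "SampledKSpace":
        """Copy with every sample's provenance set to ``tag``."""
        return SampledKSpace(
            coords=self.coords,
            values=self.values,
            keys=self.keys,
            provenance=np.full(len(self), tag, dtype="U1"),
            source_mask=self.source_mask,
        )

    def select(self, mask: np.ndarray) -> "SampledKSpace":
        """Subset by boolean mask, preserving order and metadata."""
        return SampledKSpace(
            coords=self.coords[mask],
            values=self.values[mask],
            keys=self.keys[mask],
            provenance=None if self.provenance is None else self.provenance[mask],
            source_mask=self.source_mask,
        )
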