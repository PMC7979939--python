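"""Thresholding and contour-constrained single-pass binary dilation.

Masks are plain 2-D boolean numpy arrays.  A structuring element is a set of
integer (row, col) offsets centred on the origin; dilation is one Minkowski
addition of the thresholded mask with the element, clipped to the tissue
support so no malignant pixel can appear outside the sample outline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import EmptyRegionError, ValidationError
from .inversion import IndexMap

__all__ = [
    "StructuringElement",
    "make_structuring_element",
    "threshold_map",
    "dilate",
    "tissue_support",
    "fill_enclosed_holes",
]


@dataclass(frozen=True)
class StructuringElement:
    """Origin-symmetric set of (dr, dc) offsets; rank 0 is the identity."""

    offsets: frozenset
    rank: int = -1

    def __post_init__(self) -> None:
        if (0, 0) not in self.offsets:
            raise ValidationError("structuring element must contain the origin")
        for dr, dc in self.offsets:
            if (-dr, -dc) not in self.offsets:
                raise ValidationError(
                    "structuring element must be point-symmetric about the origin")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def footprint(self) -> np.ndarray:
        """Dense boolean footprint centred on the origin (for scipy dilation)."""
        radius = max(max(abs(dr), abs(dc)) for dr, dc in self.offsets)
        fp = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
        for dr, dc in self.offsets:
            fp[dr + radius, dc + radius] = True
        return fp

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rank": self.rank,
                       "offsets": sorted(list(o) for o in self.offsets)}, fh)

    @classmethod
    def from_json(cls, path) -> "StructuringElement":
        with open(path) as fh:
            data = json.load(fh)
        return cls(frozenset((int(r), int(c)) for r, c in data["offsets"]),
                   rank=int(data.get("rank", -1)))


def make_structuring_element(rank: int) -> StructuringElement:
    """Nested family of discrete disks of increasing radius.

    rank 0: {(0,0)} — no dilation; rank 1: 3x3 cross (5 offsets);
    rank 2: Chebyshev-1 square plus axial reach 2 (13 offsets);
    rank 3: Euclidean disk of radius 2.5 (21 offsets).
    """
    if rank not in (0, 1, 2, 3):
        raise ValidationError(f"classifier rank must be in 0..3, got {rank}")
    if rank == 0:
        offs = {(0, 0)}
    elif rank == 1:
        offs = {(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if abs(dr) + abs(dc) <= 1}
    elif rank == 2:
        offs = {(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
        offs |= {(2, 0), (-2, 0), (0, 2), (0, -2)}
    else:
        offs = {(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3)
                if dr * dr + dc * dc <= 2.5 ** 2}
    return StructuringElement(frozenset(offs), rank=rank)


def threshold_map(index_map: IndexMap, t: float) -> np.ndarray:
    """Boolean mask: strictly ``value > t`` and on-support."""
    values = index_map.values
    with np.errstate(invalid="ignore"):
        out = values > t
    return out & index_map.support


def dilate(mask: np.ndarray, se: StructuringElement,
           support: np.ndarray | None = None) -> np.ndarray:
    """One constrained Minkowski dilation: ``(mask ⊕ Λ) ∩ support``.

    Exactly one pass — pixels added by the dilation exert no further
    influence.  Offsets falling outside the image are discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if support is not None:
        support = np.asarray(support, dtype=bool)
        if support.shape != mask.shape:
            raise ValidationError("mask and support must share one shape")
    out = ndimage.binary_dilation(mask, structure=se.footprint, iterations=1,
                                  border_value=0)
    if support is not None:
        out &= support
    return out


def tissue_support(field: np.ndarray, level: float | None = None,
                   invert: bool = False) -> np.ndarray:
    """Filled interior of the isoline at ``level`` in a scalar field.

    ``level=None`` picks Otsu's threshold between the background and tissue
    modes of the histogram.  ``invert=True`` selects pixels *below* the level
    (for amplitude images where tissue reflects less than the bare
    substrate).  Interior holes are filled; the largest connected component
    is returned.
    """
    field = np.asarray(field, dtype=float)
    finite = np.isfinite(field)
    if not finite.all():
        fill = field[finite].min() if finite.any() else 0.0
        field = np.where(finite, field, fill)
    if level is None:
        level = float(threshold_otsu(field))
    inside = field < level if invert else field > level
    if not inside.any():
        raise EmptyRegionError(f"support level {level:g} yields an empty region")
    inside = ndimage.binary_fill_holes(inside)
    labels, count = ndimage.label(inside)
    if count > 1:
        sizes = ndimage.sum_labels(inside, labels, index=np.arange(1, count + 1))
        inside = labels == (1 + int(np.argmax(sizes)))
    return inside


def fill_enclosed_holes(mask: np.ndarray) -> np.ndarray:
    """Optional post-process: mark enclosed benign pockets as malignant.

    Off by default everywhere in the pipeline; provided as a clearly
    labelled extra pass only.
    """
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))
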