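"""Contour-based registration of the reference (pathology) image.

The terahertz frame is never resampled: the pathology side is contoured,
bicubically resized to the terahertz grid, and rotated over an angle grid to
maximize the Pearson correlation between the two contour matrices (filled
interiors by default, outline-only available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .errors import RegistrationError, ValidationError
from .segmentation import tissue_support

__all__ = [
    "Contour",
    "RegistrationResult",
    "default_angle_grid",
    "extract_isoline",
    "contour_mask",
    "resize_bicubic",
    "rotate_mask",
    "rotation_search",
    "register",
]


@dataclass
class Contour:
    """Ordered polyline of (row, col) vertices at a fixed isoline level."""

    polyline: np.ndarray
    closed: bool
    level: float

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.closed and len(self.polyline) < 3:
            raise ValidationError("a closed contour needs at least 3 vertices")

    @property
    def length(self) -> float:
        """Total polyline arc length."""
        return float(np.sum(np.hypot(*np.diff(self.polyline, axis=0).T)))


@dataclass
class RegistrationResult:
    angle: float
    scale: float
    correlation: float
    coarse_angle: float = 0.0

    @property
    def total_angle(self) -> float:
        """Full rotation applied to the moving image (coarse + searched)."""
        return self.coarse_angle + self.angle

    def as_dict(self) -> dict:
        return {"angle": self.angle, "scale": self.scale,
                "correlation": self.correlation, "coarse_angle": self.coarse_angle,
                "total_angle": self.total_angle}


def default_angle_grid(half_range: float = 45.0, step: float = 1.0) -> np.ndarray:
    return np.arange(-half_range, half_range + step / 2, step)


def extract_isoline(field: np.ndarray, level: float) -> Contour:
    """Longest closed isoline at ``level``, marching-squares interpolation."""
    field = np.asarray(field, dtype=float)
    if not np.isfinite(field).all():
        raise ValidationError("field must be finite for contouring")
    lo, hi = field.min(), field.max()
    if not (lo < level < hi):
        raise ValidationError(
            f"level {level:g} must lie strictly inside the field range [{lo:g}, {hi:g}]")
    loops = [c for c in measure.find_contours(field, level)
             if len(c) >= 3 and np.allclose(c[0], c[-1])]
    if not loops:
        raise RegistrationError(f"no closed isoline exists at level {level:g}")
    best = max(loops, key=len)
    return Contour(polyline=best, closed=True, level=float(level))


def contour_mask(field: np.ndarray, level: float | None = None,
                 filled: bool = True, invert: bool = False) -> np.ndarray:
    """Rasterized contour matrix used for correlation.

    Filled interior by default; ``filled=False`` keeps the 1-pixel outline
    (interior minus its erosion).
    """
    inside = tissue_support(field, level=level, invert=invert)
    if filled:
        return inside
    eroded = ndimage.binary_erosion(inside, border_value=0)
    return inside & ~eroded


def resize_bicubic(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic (16-neighbour) resize; identity when the shape already matches."""
    image = np.asarray(image, dtype=float)
    h, w = target_shape
    if h < 2 or w < 2:
        raise ValidationError(f"degenerate target shape {target_shape}")
    if image.shape == (h, w):
        return image
    return transform.resize(image, (h, w), order=3, mode="edge",
                            anti_aliasing=False, preserve_range=True)


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValidationError("cannot rotate an empty mask")
    return float(cols.mean()), float(rows.mean())  # (x, y) for skimage


def rotate_mask(mask: np.ndarray, angle_deg: float,
                center: tuple[float, float] | None = None) -> np.ndarray:
    """Rotate a boolean mask (bilinear resampling, re-binarized at 0.5).

    Positive angles are counter-clockwise; rotation is about the mask
    centroid unless ``center`` (x, y) is given.
    """
    mask = np.asarray(mask, dtype=bool)
    if angle_deg == 0.0:
        return mask.copy()
    if center is None:
        center = _centroid(mask)
    rotated = transform.rotate(mask.astype(float), angle_deg, center=center,
                               order=1, preserve_range=True)
    return rotated >= 0.5


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise RegistrationError("correlation undefined for a constant contour matrix")
    return float(np.corrcoef(a, b)[0, 1])


def rotation_search(fixed: np.ndarray, moving: np.ndarray,
                    angle_grid: np.ndarray | None = None,
                    coarse_angle: float = 0.0) -> RegistrationResult:
    """Best rotation of ``moving`` against ``fixed`` by Pearson correlation.

    Each grid angle is added to ``coarse_angle``; ties resolve to the
    smallest absolute grid angle.
    """
    fixed = np.asarray(fixed, dtype=bool)
    moving = np.asarray(moving, dtype=bool)
    if fixed.shape != moving.shape:
        raise ValidationError("fixed and moving masks must share one shape")
    if angle_grid is None:
        angle_grid = default_angle_grid()
    angle_grid = np.asarray(angle_grid, dtype=float)
    if angle_grid.size == 0:
        raise ValidationError("angle grid must be non-empty")
    center = _centroid(moving)
    best = None
    for angle in sorted(angle_grid, key=abs):
        candidate = rotate_mask(moving, coarse_angle + angle, center=center)
        corr = _pearson(fixed, candidate)
        if best is None or corr > best[1]:
            best = (float(angle), corr)
    return RegistrationResult(angle=best[0], scale=1.0, correlation=best[1],
                              coarse_angle=coarse_angle)


def register(thz_field: np.ndarray, pathology_image: np.ndarray,
             levels: tuple[float | None, float | None] = (None, None),
             angle_grid: np.ndarray | None = None, coarse_angle: float = 0.0,
             filled: bool = True, invert_thz: bool = False,
             payload: np.ndarray | None = None
             ) -> tuple[RegistrationResult, np.ndarray]:
    """Full registration: contour both sides, resize, rotation-search, apply.

    Returns the result and the registered pathology mask on the terahertz
    grid.  ``payload`` (a high-resolution binary mask aligned with
    ``pathology_image``, e.g. the pathologist's malignant contour) is carried
    through the same resize + rotation when given; otherwise the pathology
    contour interior itself is returned.  The terahertz image is never
    resampled.
    """
    thz_field = np.asarray(thz_field, dtype=float)
    pathology_image = np.asarray(pathology_image, dtype=float)
    if thz_field.size == 0 or pathology_image.size == 0:
        raise ValidationError("images must be non-degenerate")
    try:
        fixed = contour_mask(thz_field, level=levels[0], filled=filled,
                             invert=invert_thz)
    except Exception as exc:
        raise RegistrationError(f"terahertz contouring failed: {exc}") from exc

    scale = thz_field.shape[0] / pathology_image.shape[0]
    try:
        resized = resize_bicubic(pathology_image, thz_field.shape)
        moving = contour_mask(resized, level=levels[1], filled=filled)
    except Exception as exc:
        raise RegistrationError(f"pathology resizing/contouring failed: {exc}") from exc

    result = rotation_search(fixed, moving, angle_grid=angle_grid,
                             coarse_angle=coarse_angle)
    result.scale = scale

    if payload is None:
        payload_lowres = tissue_support(resized, level=levels[1])
    else:
        payload = np.asarray(payload, dtype=float)
        if payload.shape != pathology_image.shape:
            raise ValidationError("payload must be aligned with the pathology image")
        payload_lowres = resize_bicubic(payload, thz_field.shape) >= 0.5
    center = _centroid(tissue_support(resized, level=levels[1]))
    registered = rotate_mask(payload_lowres, result.total_angle, center=center) \
        if result.total_angle != 0.0 else payload_lowres.copy()
    return result, registered
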