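"""Synthetic phantom generator standing in for the clinical inputs.

Produces a ground-truth tissue map (adipose / fibrous / tumour regions with
the tumour index highest), a simulated frequency-domain field cube via the
forward optical model, and a higher-resolution, rotated "pathology" truth
mask for the registration stage to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw

from .errors import ValidationError
from .inversion import (DEFAULT_FREQUENCY_HZ, FieldCube, IndexMap, SearchGrid,
                        SpectralTrace, hz_to_omega)
from .optics import AIR, ComplexIndex, SubstrateSpec, candidate_transfer, default_substrate
from .registration import rotate_mask

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomOutput",
    "default_phantom_spec",
    "default_frequency_axis",
    "gaussian_blur",
    "generate_truth",
    "reference_pulse",
    "simulate_cube",
    "make_pathology",
    "generate_phantom",
]

#: FWHM -> Gaussian sigma.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class Region:
    """One painted tissue region.  Later regions override earlier ones.

    kinds: ``ellipse`` params (r, c, r_radius, c_radius);
    ``rect`` params (r0, c0, r1, c1) half-open; ``polygon`` params
    (rows, cols).
    """

    tissue_class: str
    kind: str
    params: tuple

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        if self.kind == "ellipse":
            r, c, rr, cc = self.params
            ii, jj = draw.ellipse(r, c, rr, cc, shape=shape)
            out[ii, jj] = True
        elif self.kind == "rect":
            r0, c0, r1, c1 = (int(v) for v in self.params)
            out[max(r0, 0):min(r1, shape[0]), max(c0, 0):min(c1, shape[1])] = True
        elif self.kind == "polygon":
            rows, cols = self.params
            ii, jj = draw.polygon(rows, cols, shape=shape)
            out[ii, jj] = True
        else:
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if not out.any():
            raise ValidationError(f"region {self.tissue_class}/{self.kind} is empty in-bounds")
        return out


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (48, 48)
    regions: tuple = ()
    class_indices: dict = field(default_factory=lambda: {
        "adipose": ComplexIndex(1.90, 0.150),
        "fibrous": ComplexIndex(2.20, 0.200),
        "tumour": ComplexIndex(2.60, 0.250),
    })
    blur_fwhm: float = 0.0
    snr_db: float = math.inf
    seed: int = 0
    pathology_scale: int = 1
    pathology_angle: float = 0.0
    #: Fraction of tumour-zone pixels that actually carry the tumour index;
    #: the rest keep the fibrous index.  Values < 1 emulate zones sparsely
    #: populated by cancer cells whose response is diluted by the
    #: diffraction-limited blur — the regime dilation is meant to rescue.
    tumour_fill: float = 1.0

    def __post_init__(self) -> None:
        if self.blur_fwhm < 0:
            raise ValidationError("blur_fwhm must be >= 0")
        if not (0.0 < self.tumour_fill <= 1.0):
            raise ValidationError("tumour_fill must lie in (0, 1]")
        if self.pathology_scale < 1:
            raise ValidationError("pathology_scale must be >= 1")
        ci = self.class_indices
        required = {"adipose", "fibrous", "tumour"}
        if not required <= set(ci):
            raise ValidationError(f"class_indices must define {sorted(required)}")
        if not (ci["tumour"].n > ci["fibrous"].n > ci["adipose"].n):
            raise ValidationError("contrast ordering tumour.n > fibrous.n > adipose.n required")
        for region in self.regions:
            if region.tissue_class not in ci:
                raise ValidationError(f"region class {region.tissue_class!r} has no index")


@dataclass
class PhantomOutput:
    cube: FieldCube
    reference: SpectralTrace
    truth_index: IndexMap
    truth_mask: np.ndarray
    pathology_mask: np.ndarray
    pathology_support: np.ndarray
    provenance: PhantomSpec


def default_phantom_spec(**overrides) -> PhantomSpec:
    """48x48 adipose ellipse carrying one fibrous and one tumour blob."""
    regions = (
        Region("adipose", "ellipse", (24, 24, 20, 19)),
        Region("fibrous", "ellipse", (21, 19, 11, 9)),
        Region("tumour", "ellipse", (28, 29, 8, 7)),
    )
    return replace(PhantomSpec(regions=regions), **overrides)


def default_frequency_axis(n_points: int = 73) -> np.ndarray:
    """Angular-frequency axis spanning 0.2-2 THz (includes the 550-GHz bin)."""
    return hz_to_omega(np.linspace(0.2e12, 2.0e12, n_points))


def gaussian_blur(field_2d: np.ndarray, fwhm: float) -> np.ndarray:
    """Gaussian blur of the stated FWHM; reflective boundary conserves mass."""
    if fwhm == 0.0:
        return np.asarray(field_2d, dtype=float).copy()
    return gaussian_filter(np.asarray(field_2d, dtype=float),
                           sigma=fwhm * _FWHM_TO_SIGMA, mode="reflect")


def generate_truth(spec: PhantomSpec, grid: SearchGrid | None = None,
                   frequency: float = DEFAULT_FREQUENCY_HZ
                   ) -> tuple[IndexMap, np.ndarray]:
    """Ground-truth index map (blurred) and the unblurred tumour mask.

    Class indices are snapped onto the search grid so the noise-free
    round trip through the inversion is exact.  The diffraction surrogate
    blurs the (n, kappa) fields inside the tissue footprint only; the truth
    mask stays crisp.
    """
    if not spec.regions:
        raise ValidationError("phantom spec has no regions")
    if grid is None:
        grid = SearchGrid()
    snapped = {name: grid.snap(ci.n, ci.kappa)
               for name, ci in spec.class_indices.items()}

    support = np.zeros(spec.shape, dtype=bool)
    n_map = np.full(spec.shape, snapped["adipose"].n)
    k_map = np.full(spec.shape, snapped["adipose"].kappa)
    tumour = np.zeros(spec.shape, dtype=bool)
    for region in spec.regions:
        m = region.mask(spec.shape)
        support |= m
        n_map[m] = snapped[region.tissue_class].n
        k_map[m] = snapped[region.tissue_class].kappa
        if region.tissue_class == "tumour":
            tumour |= m
        else:
            tumour &= ~m

    if spec.tumour_fill < 1.0 and tumour.any():
        # Sparse cancer-cell clusters: decimate the painted tumour pixels
        # (truth mask keeps the full zone, as a pathologist would mark it).
        rng = np.random.default_rng([spec.seed, 0xFEED])
        keep = rng.random(spec.shape) < spec.tumour_fill
        thin_out = tumour & ~keep
        n_map[thin_out] = snapped["fibrous"].n
        k_map[thin_out] = snapped["fibrous"].kappa

    n_map = gaussian_blur(n_map, spec.blur_fwhm)
    k_map = gaussian_blur(k_map, spec.blur_fwhm)
    n_map[~support] = np.nan
    k_map[~support] = np.nan
    truth = IndexMap(values=n_map, frequency=hz_to_omega(frequency),
                     support=support, kappa=k_map)
    return truth, tumour


def reference_pulse(frequencies: np.ndarray, delay: float = 5e-12,
                    amplitude: float = 1.0) -> SpectralTrace:
    """Smooth synthetic reference spectrum: raised-cosine magnitude over the
    band with a linear phase (group delay ``delay``)."""
    frequencies = np.asarray(frequencies, dtype=float)
    lo, hi = frequencies[0], frequencies[-1]
    x = (frequencies - lo) / (hi - lo)
    # keep a small pedestal so every in-band bin passes the SNR floor
    mag = amplitude * (0.05 + 0.95 * 0.5 * (1.0 - np.cos(2.0 * np.pi * x)))
    return SpectralTrace(frequencies, mag * np.exp(-1j * frequencies * delay))


def simulate_cube(truth: IndexMap, substrate: SubstrateSpec | None = None,
                  frequencies: np.ndarray | None = None,
                  snr_db: float = math.inf, seed: int = 0
                  ) -> tuple[FieldCube, SpectralTrace]:
    """Forward-simulate the per-pixel sample fields from the truth map.

    ``E^s = T_candidate(n̂_pixel) · E^r`` per frequency; pixels outside the
    tissue support see air behind the substrate.  Additive i.i.d. complex
    Gaussian noise is scaled so the per-pixel SNR at the operating-frequency
    bin equals ``snr_db``; the draw is deterministic given ``seed``.
    """
    if substrate is None:
        substrate = default_substrate()
    if frequencies is None:
        frequencies = default_frequency_axis()
    frequencies = np.asarray(frequencies, dtype=float)
    if not (frequencies[0] <= truth.frequency <= frequencies[-1]):
        raise ValidationError("truth map frequency lies outside the simulated band")

    reference = reference_pulse(frequencies)
    h, w = truth.shape
    nhat = np.where(truth.support,
                    np.nan_to_num(truth.values, nan=AIR.n)
                    - 1j * np.nan_to_num(0.0 if truth.kappa is None else truth.kappa,
                                         nan=AIR.kappa),
                    AIR.nhat)
    field = np.empty((h, w, frequencies.size), dtype=complex)
    for fi, omega in enumerate(frequencies):
        field[:, :, fi] = candidate_transfer(nhat, substrate, float(omega)) \
            * reference.field[fi]

    if np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        op_bin = int(np.argmin(np.abs(frequencies - truth.frequency)))
        sigma = np.abs(field[:, :, op_bin]) * 10.0 ** (-snr_db / 20.0)
        noise = rng.standard_normal(field.shape) + 1j * rng.standard_normal(field.shape)
        field = field + sigma[:, :, np.newaxis] * noise / math.sqrt(2.0)
    return FieldCube(frequencies, field), reference


def make_pathology(truth_mask: np.ndarray, scale: int, angle: float) -> np.ndarray:
    """Nearest-neighbour upscale then rotation about the centroid.

    Quarter-turn angles on a square grid use an exact lattice rotation;
    everything else is bilinear + re-binarize.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if scale < 1:
        raise ValidationError("scale must be >= 1")
    up = np.kron(truth_mask, np.ones((scale, scale), dtype=bool))
    if angle == 0.0:
        return up
    if angle % 90.0 == 0.0 and up.shape[0] == up.shape[1]:
        return np.rot90(up, k=int(angle // 90) % 4)
    return rotate_mask(up, angle)


def generate_phantom(spec: PhantomSpec, substrate: SubstrateSpec | None = None,
                     frequencies: np.ndarray | None = None,
                     grid: SearchGrid | None = None) -> PhantomOutput:
    """Full phantom: truth map, simulated cube, and distorted pathology pair."""
    truth, tumour = generate_truth(spec, grid=grid)
    cube, reference = simulate_cube(truth, substrate=substrate,
                                    frequencies=frequencies,
                                    snr_db=spec.snr_db, seed=spec.seed)
    pathology_mask = make_pathology(tumour, spec.pathology_scale, spec.pathology_angle)
    pathology_support = make_pathology(truth.support, spec.pathology_scale,
                                       spec.pathology_angle)
    return PhantomOutput(cube=cube, reference=reference, truth_index=truth,
                         truth_mask=tumour, pathology_mask=pathology_mask,
                         pathology_support=pathology_support, provenance=spec)
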