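"""Per-pixel extraction of the complex refractive index by grid search.

The inverse problem is solved by exhaustively scanning a rectangular grid of
candidate ``(n, kappa)`` pairs and minimizing the squared log-magnitude
discrepancy between the measured and candidate transfer functions at a single
operating frequency.  Two objective modes are provided:

``magnitude``
    squared log ratio of magnitudes only — the printed method; at a single
    frequency one magnitude constrains two unknowns, so the minimizer is
    degenerate and ties are broken deterministically (smallest kappa, then
    smallest n).
``complex`` (default)
    the magnitude objective augmented with the squared wrapped phase
    difference, which makes the single-frequency problem well posed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyBandError, ValidationError
from .optics import AIR, ComplexIndex, SubstrateSpec, TransferSpectrum, candidate_transfer
from . import optics

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralTrace",
    "FieldCube",
    "SearchGrid",
    "IndexMap",
    "DEFAULT_FREQUENCY_HZ",
    "hz_to_omega",
    "transfer_from_fields",
    "discrepancy",
    "objective",
    "grid_search_pixel",
    "extract_map",
    "characterize_substrate",
]

#: Operating frequency used for classification, in Hz.
DEFAULT_FREQUENCY_HZ = 550e9


def hz_to_omega(f_hz: float) -> float:
    return 2.0 * math.pi * f_hz


@dataclass
class SpectralTrace:
    """Complex electric field sampled on an angular-frequency axis (rad/s)."""

    frequencies: np.ndarray
    field: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.field = np.asarray(self.field, dtype=complex)
        if self.frequencies.shape != self.field.shape:
            raise ValidationError("frequencies and field must have equal length")
        if self.frequencies.ndim != 1 or np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency axis must be 1-D and strictly increasing")


@dataclass
class FieldCube:
    """Per-pixel frequency-domain fields on a shared angular-frequency axis.

    ``field`` has shape (height, width, n_frequencies).
    """

    frequencies: np.ndarray
    field: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.ndim != 3:
            raise ValidationError("cube field must be 3-D (h, w, f)")
        if self.field.shape[2] != self.frequencies.size:
            raise ValidationError("cube frequency axis does not match field depth")
        if self.field.shape[0] * self.field.shape[1] == 0:
            raise ValidationError("cube must contain at least one pixel")

    @property
    def height(self) -> int:
        return self.field.shape[0]

    @property
    def width(self) -> int:
        return self.field.shape[1]

    def trace(self, row: int, col: int) -> SpectralTrace:
        return SpectralTrace(self.frequencies, self.field[row, col])


@dataclass(frozen=True)
class SearchGrid:
    """Inclusive candidate grid for the (n, kappa) search.

    Defaults: n in [1.5, 3] step 0.01 (151 values) and kappa in [0, 1]
    step 0.001 (1001 values).
    """

    n_min: float = 1.5
    n_max: float = 3.0
    n_step: float = 0.01
    kappa_min: float = 0.0
    kappa_max: float = 1.0
    kappa_step: float = 0.001

    def __post_init__(self) -> None:
        if self.n_step <= 0 or self.kappa_step <= 0:
            raise ValidationError("grid steps must be > 0")
        if self.n_max < self.n_min or self.kappa_max < self.kappa_min:
            raise ValidationError("grid ranges must be non-empty")

    @property
    def n_values(self) -> np.ndarray:
        count = int(round((self.n_max - self.n_min) / self.n_step)) + 1
        return np.linspace(self.n_min, self.n_max, count)

    @property
    def kappa_values(self) -> np.ndarray:
        count = int(round((self.kappa_max - self.kappa_min) / self.kappa_step)) + 1
        return np.linspace(self.kappa_min, self.kappa_max, count)

    def snap(self, n: float, kappa: float) -> ComplexIndex:
        """Nearest grid candidate — used to place synthetic truth on-grid."""
        nv, kv = self.n_values, self.kappa_values
        return ComplexIndex(
            float(nv[np.argmin(np.abs(nv - n))]),
            float(kv[np.argmin(np.abs(kv - kappa))]),
        )

    def as_dict(self) -> dict:
        return {
            "n_min": self.n_min, "n_max": self.n_max, "n_step": self.n_step,
            "kappa_min": self.kappa_min, "kappa_max": self.kappa_max,
            "kappa_step": self.kappa_step,
        }


@dataclass
class IndexMap:
    """Real refractive-index map at a single angular frequency.

    ``values`` is NaN off-support; ``kappa`` carries the companion extinction
    map (same masking) when available.
    """

    values: np.ndarray
    frequency: float
    support: np.ndarray
    kappa: np.ndarray | None = None
    mode: str = "complex"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.values.shape != self.support.shape:
            raise ValidationError("values and support must share one shape")
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if self.kappa.shape != self.values.shape:
                raise ValidationError("kappa map must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def transfer_from_fields(sample: SpectralTrace, reference: SpectralTrace,
                         floor: float | None = None,
                         floor_rel: float = 1e-6) -> TransferSpectrum:
    """Experimental transfer function: pointwise ratio sample/reference field.

    Restricted to frequencies where the reference magnitude exceeds the SNR
    floor (``floor`` absolute, else ``floor_rel`` times the reference peak).
    """
    if sample.frequencies.shape != reference.frequencies.shape or \
            not np.allclose(sample.frequencies, reference.frequencies):
        raise ValidationError("sample and reference must share one frequency axis")
    ref_mag = np.abs(reference.field)
    if floor is None:
        floor = floor_rel * float(ref_mag.max(initial=0.0))
    keep = ref_mag > floor
    if not keep.any():
        raise EmptyBandError("no frequency passes the reference SNR floor")
    return TransferSpectrum(sample.frequencies[keep],
                            sample.field[keep] / reference.field[keep])


def discrepancy(ts: complex, tc: complex) -> float:
    """Log-magnitude discrepancy ``ln(|ts|/|tc|)``."""
    mts, mtc = abs(ts), abs(tc)
    if mts == 0.0 or mtc == 0.0:
        raise ValidationError("discrepancy undefined for zero-magnitude transfer")
    return math.log(mts / mtc)


def objective(ts: complex, tc: complex) -> float:
    """Squared log-magnitude discrepancy; >= 0, zero iff magnitudes match."""
    d = discrepancy(ts, tc)
    return d * d


def _transfer_table(grid: SearchGrid, substrate: SubstrateSpec, omega: float,
                    behind: ComplexIndex | None = None) -> np.ndarray:
    """Candidate transfer values on the (kappa, n) grid, vectorized.

    When ``behind`` is given the *substrate* index is the unknown being
    scanned and ``behind`` is the medium behind it (used for bare-substrate
    characterization).
    """
    nv = grid.n_values
    kv = grid.kappa_values
    nhat = nv[np.newaxis, :] - 1j * kv[:, np.newaxis]  # (K, N)
    if behind is None:
        return candidate_transfer(nhat, substrate, omega)
    # Unknown substrate scanned over the grid, known medium behind it.
    t_in = optics.fresnel_transmission(AIR.nhat, nhat)
    t_out = optics.fresnel_transmission(nhat, AIR.nhat)
    r = optics.fresnel_reflection(nhat, behind.nhat)
    p = optics.propagation(nhat, substrate.thickness, omega)
    return t_in * r * t_out * p * p / -1.0


def _argmin_chi(ts_value: complex, table: np.ndarray, mode: str,
                log_mag: np.ndarray, arg: np.ndarray) -> tuple[int, int]:
    """Index of the minimizing grid candidate, C-order tie-breaking.

    The (kappa, n) layout makes ``argmin`` resolve exact ties to the
    smallest kappa first, then the smallest n.
    """
    chi = (math.log(abs(ts_value)) - log_mag) ** 2
    if mode == "complex":
        dphi = np.mod(np.angle(ts_value) - arg + np.pi, 2.0 * np.pi) - np.pi
        chi = chi + dphi * dphi
    if not np.isfinite(chi).any():
        raise ValidationError("every candidate yields a non-finite objective")
    flat = int(np.nanargmin(chi))
    return divmod(flat, chi.shape[1])


def grid_search_pixel(ts: TransferSpectrum, grid: SearchGrid,
                      substrate: SubstrateSpec, omega: float,
                      mode: str = "complex") -> ComplexIndex:
    """Minimizing candidate (n, kappa) at the frequency bin nearest ``omega``."""
    if mode not in ("magnitude", "complex"):
        raise ValidationError(f"unknown objective mode {mode!r}")
    lo, hi = ts.frequencies[0], ts.frequencies[-1]
    if not (lo <= omega <= hi):
        raise ValidationError(f"omega {omega:g} outside transfer band [{lo:g}, {hi:g}]")
    value = complex(ts.values[ts.nearest_index(omega)])
    if abs(value) == 0.0:
        raise ValidationError("zero-magnitude transfer at the operating frequency")
    table = _transfer_table(grid, substrate, omega)
    ki, ni = _argmin_chi(value, table, mode, np.log(np.abs(table)), np.angle(table))
    return ComplexIndex(float(grid.n_values[ni]), float(grid.kappa_values[ki]))


def extract_map(cube: FieldCube, reference: SpectralTrace,
                substrate: SubstrateSpec, frequency: float = DEFAULT_FREQUENCY_HZ,
                grid: SearchGrid | None = None, mode: str = "complex",
                support: np.ndarray | None = None,
                floor_rel: float = 1e-6) -> IndexMap:
    """Refractive-index map at ``frequency`` (Hz) by per-pixel grid search.

    Pixels outside ``support`` (or whose trace fails the SNR floor at the
    operating bin) are masked with NaN and excluded downstream; the number of
    failed pixels is logged.
    """
    if grid is None:
        grid = SearchGrid()
    if mode not in ("magnitude", "complex"):
        raise ValidationError(f"unknown objective mode {mode!r}")
    omega = hz_to_omega(frequency)
    freqs = cube.frequencies
    if not (freqs[0] <= omega <= freqs[-1]):
        raise ValidationError(
            f"operating frequency {frequency:g} Hz outside the cube band")
    if not np.allclose(freqs, reference.frequencies):
        raise ValidationError("cube and reference must share one frequency axis")
    if support is None:
        support = np.ones(cube.field.shape[:2], dtype=bool)
    support = np.asarray(support, dtype=bool)
    if support.shape != cube.field.shape[:2]:
        raise ValidationError("support mask must match the cube grid")

    bin_idx = int(np.argmin(np.abs(freqs - omega)))
    ref_value = complex(reference.field[bin_idx])
    floor = floor_rel * float(np.abs(reference.field).max(initial=0.0))
    if abs(ref_value) <= floor:
        raise EmptyBandError("reference fails the SNR floor at the operating frequency")

    table = _transfer_table(grid, substrate, omega)
    log_mag = np.log(np.abs(table))
    arg = np.angle(table)

    h, w = cube.height, cube.width
    n_map = np.full((h, w), np.nan)
    k_map = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    failed = 0
    plane = cube.field[:, :, bin_idx]
    for r in range(h):
        for col in range(w):
            if not support[r, col]:
                continue
            es = plane[r, col]
            if not np.isfinite(es) or abs(es) == 0.0:
                failed += 1
                continue
            ts_value = es / ref_value
            ki, ni = _argmin_chi(ts_value, table, mode, log_mag, arg)
            n_map[r, col] = grid.n_values[ni]
            k_map[r, col] = grid.kappa_values[ki]
            valid[r, col] = True
    if failed:
        logger.warning("extract_map: %d pixel(s) failed the SNR/finite check and were masked",
                       failed)
    return IndexMap(values=n_map, frequency=omega, support=valid, kappa=k_map, mode=mode)


def characterize_substrate(bare_trace: SpectralTrace, reference: SpectralTrace,
                           nominal: SubstrateSpec, grid: SearchGrid | None = None,
                           mode: str = "complex") -> SubstrateSpec:
    """Fit the substrate index spectrum from a bare-substrate measurement.

    Runs the same grid-search minimization per frequency with the unknown
    medium being the substrate itself and air behind it; the nominal spec
    supplies the thickness.
    """
    if grid is None:
        grid = SearchGrid()
    ts = transfer_from_fields(bare_trace, reference)
    n_out = np.empty(ts.frequencies.size)
    k_out = np.empty(ts.frequencies.size)
    for i, omega in enumerate(ts.frequencies):
        table = _transfer_table(grid, nominal, float(omega), behind=AIR)
        ki, ni = _argmin_chi(complex(ts.values[i]), table, mode,
                             np.log(np.abs(table)), np.angle(table))
        n_out[i] = grid.n_values[ni]
        k_out[i] = grid.kappa_values[ki]
    return SubstrateSpec(thickness=nominal.thickness, n=n_out, kappa=k_out,
                         frequencies=ts.frequencies.copy())
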