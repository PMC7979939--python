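"""Forward electromagnetic model for a tissue layer probed through a substrate.

Normal-incidence Fresnel coefficients, single-pass propagation through the
substrate, and the candidate transfer function of the substrate–tissue echo
referenced to an ideal metal-plate reflection.

All coefficient functions accept either :class:`ComplexIndex` instances or
bare complex numbers / numpy arrays (interpreted as the composite index
``n - j*kappa``), so the same code path serves scalar physics checks and
vectorized grid searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as C_VACUUM

from .errors import DegenerateMediaError, ValidationError

__all__ = [
    "ComplexIndex",
    "SubstrateSpec",
    "TransferSpectrum",
    "AIR",
    "fresnel_transmission",
    "fresnel_reflection",
    "propagation",
    "candidate_transfer",
    "default_substrate",
]


@dataclass(frozen=True)
class ComplexIndex:
    """Complex refractive index, composite convention ``n̂ = n - j·kappa``."""

    n: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValidationError(f"kappa must be >= 0, got {self.kappa}")

    @property
    def nhat(self) -> complex:
        return complex(self.n, -self.kappa)


#: Ambient medium on both outer sides of the substrate.
AIR = ComplexIndex(1.0, 0.0)


def _nhat(medium) -> complex | np.ndarray:
    """Coerce a medium description to its composite complex index."""
    if isinstance(medium, ComplexIndex):
        return medium.nhat
    return np.asarray(medium, dtype=complex) if isinstance(medium, np.ndarray) else complex(medium)


@dataclass(frozen=True)
class SubstrateSpec:
    """Substrate geometry and (possibly dispersive) optical response.

    ``frequencies`` is an angular-frequency axis (rad/s).  When it is None the
    index is treated as frequency independent; otherwise ``n``/``kappa`` are
    sampled per frequency and looked up by linear interpolation.
    """

    thickness: float
    n: float | np.ndarray = 3.07
    kappa: float | np.ndarray = 0.0
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValidationError(f"substrate thickness must be > 0, got {self.thickness}")
        if self.frequencies is not None:
            freqs = np.asarray(self.frequencies, dtype=float)
            n = np.asarray(self.n, dtype=float)
            kappa = np.asarray(self.kappa, dtype=float)
            if not (freqs.shape == n.shape == kappa.shape):
                raise ValidationError("frequencies, n and kappa must share one shape")
            if freqs.ndim != 1 or freqs.size == 0 or np.any(np.diff(freqs) <= 0):
                raise ValidationError("frequency axis must be 1-D, non-empty, strictly increasing")
            object.__setattr__(self, "frequencies", freqs)
            object.__setattr__(self, "n", n)
            object.__setattr__(self, "kappa", kappa)

    def index_at(self, omega: float) -> ComplexIndex:
        """Substrate index at angular frequency ``omega``."""
        if self.frequencies is None:
            return ComplexIndex(float(self.n), float(self.kappa))
        lo, hi = self.frequencies[0], self.frequencies[-1]
        if not (lo <= omega <= hi):
            raise ValidationError(
                f"omega {omega:g} outside substrate characterization band [{lo:g}, {hi:g}]"
            )
        return ComplexIndex(
            float(np.interp(omega, self.frequencies, self.n)),
            float(np.interp(omega, self.frequencies, self.kappa)),
        )


@dataclass
class TransferSpectrum:
    """Complex transfer values on an angular-frequency axis."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequencies.shape != self.values.shape:
            raise ValidationError("frequencies and values must have equal length")
        if self.frequencies.ndim != 1 or np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency axis must be 1-D and strictly increasing")

    def nearest_index(self, omega: float) -> int:
        return int(np.argmin(np.abs(self.frequencies - omega)))


def _check_denominator(den) -> None:
    if np.any(np.abs(np.asarray(den)) == 0.0):
        raise DegenerateMediaError("degenerate media: n̂_a + n̂_b = 0")


def fresnel_transmission(a, b):
    """Normal-incidence amplitude transmission from medium ``a`` into ``b``.

    ``2·n̂_a / (n̂_a + n̂_b)``.
    """
    na, nb = _nhat(a), _nhat(b)
    den = na + nb
    _check_denominator(den)
    return 2.0 * na / den


def fresnel_reflection(a, b):
    """Normal-incidence amplitude reflection at the a→b interface.

    ``(n̂_a − n̂_b) / (n̂_a + n̂_b)``.
    """
    na, nb = _nhat(a), _nhat(b)
    den = na + nb
    _check_denominator(den)
    return (na - nb) / den


def propagation(a, d: float, omega: float):
    """Single-pass propagation factor ``exp(−j·ω·d·n̂_a/c)`` through medium ``a``."""
    if d < 0:
        raise ValidationError(f"path length must be >= 0, got {d}")
    if omega <= 0:
        raise ValidationError(f"angular frequency must be > 0, got {omega}")
    return np.exp(-1j * omega * d * _nhat(a) / C_VACUUM)


def candidate_transfer(tissue, substrate: SubstrateSpec, omega: float,
                       reference_sign: float = -1.0):
    """Transfer function of the substrate–tissue echo relative to the reference.

    Product of transmission into the substrate, reflection at the
    substrate–tissue interface, transmission back out, and a double pass
    through the substrate — normalized by the metal-plate reference modelled
    as an ideal reflector of coefficient ``reference_sign`` (−1 by default;
    the sign only flips a global phase).

    ``tissue`` may be a :class:`ComplexIndex` or an array of composite
    indices, in which case the result is computed elementwise.
    """
    ns = substrate.index_at(omega)
    t_in = fresnel_transmission(AIR, ns)
    t_out = fresnel_transmission(ns, AIR)
    r = fresnel_reflection(ns, tissue)
    p = propagation(ns, substrate.thickness, omega)
    return t_in * r * t_out * p * p / reference_sign


def default_substrate(thickness: float = 2e-3, n: float = 3.07,
                      kappa: float = 0.0) -> SubstrateSpec:
    """Nominal 2-mm sapphire-like substrate with a flat index."""
    return SubstrateSpec(thickness=thickness, n=n, kappa=kappa)
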