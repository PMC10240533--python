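"""Electronic circular dichroism spectra from transition-level data.

A CD-active electronic transition is described by its excitation energy
``E`` (eV) and rotatory strength ``R`` (units of 1e-40 cgs, i.e. 1e-40
erg.esu.cm/Gauss), with ``R = Im(mu . m)`` for electric and magnetic
transition dipole moments ``mu`` and ``m``.  A stick spectrum of such
transitions is converted to the molar CD signal
``delta_eps = eps_L - eps_R`` (L mol^-1 cm^-1) by Gaussian broadening on
the energy axis.

The amplitude convention follows the standard CD sum rule: integrating
``delta_eps(nu)/nu`` over wavenumber recovers ``R / 22.97`` when the units
above are used.  Concretely each transition contributes

    delta_eps(E) = (R / 22.97) * E * N(E; E0, sigma)

with ``N`` a unit-area Gaussian in energy (eV) and ``sigma`` the line-width
parameter ``lw``.  Because wavenumber is proportional to energy the
1 eV = 8065.54 cm^-1 factor cancels in the sum-rule integral, so the
formula can live entirely on the eV axis.  ``lw`` is interpreted as the
Gaussian standard deviation (not FWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DimensionError,
    EmptyInputError,
    GridMismatchError,
    ParameterError,
)

__all__ = [
    "HC_EV_NM",
    "CD_SUM_RULE_CONSTANT",
    "ROTATORY_DOT_SCALE",
    "Transition",
    "TransitionDipoles",
    "SpectralGrid",
    "CDSpectrum",
    "rotatory_strength_from_dipoles",
    "gaussian_broaden",
    "ensemble_average",
]

#: Planck constant times speed of light, eV.nm (lambda = HC_EV_NM / E).
HC_EV_NM = 1239.841

#: Sum-rule constant: R[1e-40 cgs] = 22.97 * integral(delta_eps/nu dnu).
CD_SUM_RULE_CONSTANT = 22.97

#: Scale applied to Im(mu . m).  Dipole components are assumed to be given in
#: units whose product is already in the 1e-40 cgs convention, so the factor
#: is unity; it is kept as an explicit, documented module constant so a user
#: feeding raw atomic-unit dipoles can see exactly where a conversion belongs.
ROTATORY_DOT_SCALE = 1.0


@dataclass(frozen=True)
class Transition:
    """One electronic transition: excitation energy (eV) and rotatory
    strength (1e-40 cgs)."""

    energy_ev: float
    rotatory: float

    def __post_init__(self):
        if not np.isfinite(self.energy_ev) or self.energy_ev <= 0.0:
            raise ParameterError(
                f"excitation energy must be finite and > 0, got {self.energy_ev}"
            )
        if not np.isfinite(self.rotatory):
            raise ParameterError("rotatory strength must be finite")

    @property
    def wavelength_nm(self) -> float:
        return HC_EV_NM / self.energy_ev


@dataclass(frozen=True)
class TransitionDipoles:
    """Electric and magnetic transition dipole vectors (length-3, complex)."""

    electric: tuple
    magnetic: tuple

    def __post_init__(self):
        for name in ("electric", "magnetic"):
            v = np.asarray(getattr(self, name), dtype=complex)
            if v.shape != (3,):
                raise DimensionError(
                    f"{name} transition dipole must be a 3-vector, got shape {v.shape}"
                )
            if not np.all(np.isfinite(v.view(float))):
                raise ParameterError(f"{name} transition dipole must be finite")


class SpectralGrid:
    """A strictly increasing wavelength grid in nm.

    The default grid covers the 240-380 nm band region of the provitamin /
    previtamin system with 1 nm spacing.
    """

    __slots__ = ("wavelengths_nm",)

    def __init__(self, wavelengths_nm):
        w = np.asarray(wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ParameterError("grid needs at least 2 wavelengths")
        if not np.all(np.isfinite(w)) or np.any(w <= 0.0):
            raise ParameterError("grid wavelengths must be finite and positive")
        if np.any(np.diff(w) <= 0.0):
            raise ParameterError("grid wavelengths must be strictly increasing")
        self.wavelengths_nm = w
        self.wavelengths_nm.setflags(write=False)

    @classmethod
    def default(cls, lo_nm: float = 240.0, hi_nm: float = 380.0, num: int = 141):
        return cls(np.linspace(lo_nm, hi_nm, num))

    @property
    def energies_ev(self) -> np.ndarray:
        """Photon energies at the grid points (decreasing, eV)."""
        return HC_EV_NM / self.wavelengths_nm

    def __len__(self):
        return self.wavelengths_nm.size

    def __eq__(self, other):
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.wavelengths_nm, other.wavelengths_nm
        )

    def __repr__(self):
        w = self.wavelengths_nm
        return f"SpectralGrid({w[0]:g}..{w[-1]:g} nm, {w.size} points)"


@dataclass
class CDSpectrum:
    """Molar CD ``delta_eps`` (L mol^-1 cm^-1) on a :class:`SpectralGrid`."""

    grid: SpectralGrid
    delta_epsilon: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.delta_epsilon = np.asarray(self.delta_epsilon, dtype=float)
        if self.delta_epsilon.shape != (len(self.grid),):
            raise DimensionError(
                "delta_epsilon length must match the grid "
                f"({self.delta_epsilon.shape} vs {len(self.grid)})"
            )
        if not np.all(np.isfinite(self.delta_epsilon)):
            raise ParameterError("delta_epsilon must be finite")

    # -- small algebra, used pervasively by the TRCD assembly -------------
    def _check(self, other: "CDSpectrum"):
        if self.grid != other.grid:
            raise GridMismatchError("spectra are on different wavelength grids")

    def __add__(self, other):
        self._check(other)
        return CDSpectrum(self.grid, self.delta_epsilon + other.delta_epsilon)

    def __sub__(self, other):
        self._check(other)
        return CDSpectrum(self.grid, self.delta_epsilon - other.delta_epsilon)

    def __neg__(self):
        return CDSpectrum(self.grid, -self.delta_epsilon)

    def __mul__(self, s: float):
        return CDSpectrum(self.grid, self.delta_epsilon * float(s))

    __rmul__ = __mul__

    def integral_nm(self, lo_nm: float | None = None, hi_nm: float | None = None) -> float:
        """Trapezoidal integral of delta_eps over wavelength (nm), optionally
        restricted to [lo_nm, hi_nm].  Used for band-sign diagnostics."""
        w = self.grid.wavelengths_nm
        mask = np.ones_like(w, dtype=bool)
        if lo_nm is not None:
            mask &= w >= lo_nm
        if hi_nm is not None:
            mask &= w <= hi_nm
        return float(np.trapezoid(self.delta_epsilon[mask], w[mask]))


def rotatory_strength_from_dipoles(d: TransitionDipoles) -> float:
    """Rotatory strength ``R = Im(mu . m)`` in 1e-40 cgs units.

    The scalar product is element-wise (no conjugation), matching the
    convention in which a real electric dipole and a purely imaginary
    magnetic dipole give a real, signed R.  The output is scaled by
    :data:`ROTATORY_DOT_SCALE`.
    """
    mu = np.asarray(d.electric, dtype=complex)
    m = np.asarray(d.magnetic, dtype=complex)
    return float(np.imag(np.dot(mu, m)) * ROTATORY_DOT_SCALE)


def _broaden_arrays(
    energies_ev: np.ndarray,
    rotatories: np.ndarray,
    grid: SpectralGrid,
    lw_ev: float,
) -> np.ndarray:
    """Vectorised kernel: sum of Gaussian bands evaluated on the grid.

    ``energies_ev`` and ``rotatories`` are flat arrays of equal length.
    Returns the delta_eps array (len(grid),).
    """
    if lw_ev <= 0.0 or not np.isfinite(lw_ev):
        raise ParameterError(f"line width must be > 0, got {lw_ev}")
    e0 = np.asarray(energies_ev, dtype=float).ravel()
    rr = np.asarray(rotatories, dtype=float).ravel()
    if e0.size == 0:
        return np.zeros(len(grid))
    eg = grid.energies_ev  # (G,)
    gauss = np.exp(-((eg[None, :] - e0[:, None]) ** 2) / (2.0 * lw_ev**2))
    norm = 1.0 / (lw_ev * np.sqrt(2.0 * np.pi))
    amp = rr / CD_SUM_RULE_CONSTANT  # (T,)
    return (amp[:, None] * gauss).sum(axis=0) * (eg * norm)


def gaussian_broaden(
    transitions, grid: SpectralGrid, lw_ev: float
) -> CDSpectrum:
    """Broaden a stick spectrum of :class:`Transition` into delta_eps.

    Each transition contributes one Gaussian band (standard deviation
    ``lw_ev``) centred at its excitation energy; contributions add
    linearly.  An empty transition list yields the zero spectrum.

    Raises
    ------
    ParameterError
        If ``lw_ev <= 0``.
    """
    transitions = list(transitions)
    e0 = np.array([t.energy_ev for t in transitions], dtype=float)
    rr = np.array([t.rotatory for t in transitions], dtype=float)
    return CDSpectrum(grid, _broaden_arrays(e0, rr, grid, lw_ev))


def ensemble_average(spectra) -> CDSpectrum:
    """Point-wise arithmetic mean of spectra sharing one grid."""
    spectra = list(spectra)
    if not spectra:
        raise EmptyInputError("cannot average an empty list of spectra")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridMismatchError("spectra are on different wavelength grids")
    stack = np.stack([s.delta_epsilon for s in spectra])
    return CDSpectrum(grid, stack.mean(axis=0))
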