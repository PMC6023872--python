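"""Closed-form Förster resonance energy transfer (FRET) computations.

Everything here is analytic: FRET efficiency from donor quenching
(steady-state intensity or excited-state lifetime), the sixth-power
distance law ``E = 1 / (1 + (r/R0)**6)`` and its inverse, the spectral
overlap integral ``J = \\int f_D(lam) eps_A(lam) lam**4 dlam`` over
area-normalized donor emission, and the Förster radius

    R0**6 = (9 ln10 / 128 pi**5 N_A) * (kappa**2 Q_D / n**4) * J.

Units follow the single-molecule FRET convention: wavelengths in nm,
extinction coefficients in M^-1 cm^-1, J in M^-1 cm^-1 nm^4, distances
in nm.  The nm-unit prefactor below is derived by dimensional analysis:
1 M^-1 = 1e24 nm^3/mol and 1 cm^-1 = 1e-7 nm^-1, so J carries a factor
of 1e17 nm^6/mol and R0 comes out directly in nm.  The resulting
constant, (8.785e-11)**(1/6) = 0.02108 nm, matches the textbook
0.211 Angstrom form of the Förster equation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "FluorophorePair",
    "FretResult",
    "efficiency_from_intensity",
    "efficiency_from_lifetime",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "overlap_integral",
    "forster_radius",
    "analyze_pair",
]

_AVOGADRO = 6.02214076e23  # 1/mol (CODATA exact)

#: R0^6 [nm^6] = _R0_PREFACTOR_NM6 * kappa^2 * Q_D / n^4 * J[M^-1 cm^-1 nm^4]
_R0_PREFACTOR_NM6 = 9.0 * math.log(10.0) * 1e17 / (128.0 * math.pi**5 * _AVOGADRO)


@dataclass(frozen=True)
class Spectrum:
    """A tabulated spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        Non-negative values; dimensionless for emission spectra,
        M^-1 cm^-1 for absorption/extinction spectra.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_text(cls, path) -> "Spectrum":
        """Read a two-column (wavelength_nm, value) whitespace- or
        comma-separated text file."""
        from .io import read_two_column

        wl, vals = read_two_column(path)
        return cls(wl, vals)

    def scaled_to_peak(self, peak: float) -> "Spectrum":
        """Return a copy rescaled so that max(values) == peak."""
        vmax = float(self.values.max())
        if vmax <= 0:
            raise ValueError("cannot rescale an all-zero spectrum")
        return Spectrum(self.wavelengths, self.values * (peak / vmax))


@dataclass(frozen=True)
class FluorophorePair:
    """A donor/acceptor FRET pair with the constants entering R0.

    ``acceptor_absorption`` may be supplied as an arbitrary-scaled shape;
    it is rescaled so its maximum equals ``acceptor_eps_max`` before the
    overlap integral is evaluated.
    """

    donor_qy: float
    acceptor_eps_max: float
    donor_emission: Spectrum
    acceptor_absorption: Spectrum
    kappa_sq: float = 2.0 / 3.0
    refractive_index: float = 1.33

    def __post_init__(self):
        if not 0 < self.donor_qy <= 1:
            raise ValueError("donor quantum yield must lie in (0, 1]")
        if not 0 <= self.kappa_sq <= 4:
            raise ValueError("kappa^2 must lie in [0, 4]")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.acceptor_eps_max <= 0:
            raise ValueError("acceptor extinction maximum must be positive")

    def overlap_integral(self) -> float:
        eps = self.acceptor_absorption.scaled_to_peak(self.acceptor_eps_max)
        return overlap_integral(self.donor_emission, eps)

    def forster_radius(self) -> float:
        return forster_radius(
            self.overlap_integral(),
            self.donor_qy,
            kappa_sq=self.kappa_sq,
            refractive_index=self.refractive_index,
        )


@dataclass(frozen=True)
class FretResult:
    """Bundle of FRET quantities for one pair/measurement."""

    efficiency: float
    distance: float  # nm
    forster_radius: float  # nm
    overlap: float  # M^-1 cm^-1 nm^4


def efficiency_from_intensity(
    donor_alone: float, donor_with_acceptor: float, *, clip: bool = True
) -> float:
    """FRET efficiency from donor quenching: E = 1 - I_D'/I_D.

    ``donor_alone`` (I_D) is the donor-only intensity and
    ``donor_with_acceptor`` (I_D') the donor intensity in the presence of
    the acceptor.  Noise can push I_D' above I_D in single-molecule data;
    the resulting small negative E is clipped to 0 with a warning
    (``clip=False`` returns the raw value instead).
    """
    if donor_alone <= 0:
        raise ValueError("donor-alone intensity must be positive")
    if donor_with_acceptor < 0:
        raise ValueError("donor-with-acceptor intensity must be non-negative")
    e = 1.0 - donor_with_acceptor / donor_alone
    if e < 0 and clip:
        warnings.warn(
            "donor intensity increased in the presence of the acceptor; "
            "clipping FRET efficiency to 0",
            stacklevel=2,
        )
        return 0.0
    return float(e)


def efficiency_from_lifetime(tau_donor: float, tau_donor_acceptor: float) -> float:
    """FRET efficiency from lifetime quenching: E = 1 - tau_DA/tau_D.

    Both lifetimes are amplitude-weighted mean excited-state lifetimes in
    ns (any common unit works).  A tau_DA exceeding tau_D is clipped to
    E = 0 with a warning, mirroring the intensity clip policy.
    """
    if tau_donor <= 0 or tau_donor_acceptor <= 0:
        raise ValueError("lifetimes must be positive")
    e = 1.0 - tau_donor_acceptor / tau_donor
    if e < 0:
        warnings.warn(
            "donor lifetime increased in the presence of the acceptor; "
            "clipping FRET efficiency to 0",
            stacklevel=2,
        )
        return 0.0
    return float(e)


def efficiency_from_distance(r: float, r0: float) -> float:
    """E = 1 / (1 + (r/R0)**6) for separation r and Förster radius R0 (nm)."""
    if r <= 0 or r0 <= 0:
        raise ValueError("distance and Förster radius must be positive")
    return float(1.0 / (1.0 + (r / r0) ** 6))


def distance_from_efficiency(efficiency: float, r0: float) -> float:
    """Invert the distance law: r = R0 * ((1-E)/E)**(1/6), in nm."""
    if not 0 < efficiency < 1:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if r0 <= 0:
        raise ValueError("Förster radius must be positive")
    return float(r0 * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0))


def overlap_integral(donor_emission: Spectrum, acceptor_absorption: Spectrum) -> float:
    """Spectral overlap integral J = int f_D(lam) eps_A(lam) lam^4 dlam.

    The donor emission is area-normalized to unit integral over the
    common wavelength range (the standard convention that gives J units
    of M^-1 cm^-1 nm^4 when eps_A is in M^-1 cm^-1 and lam in nm).
    Both spectra are linearly interpolated onto the union of their grid
    points inside the common range and integrated by the trapezoid rule.

    Raises ``ValueError`` if the spectra do not overlap or if the donor
    emission vanishes on the common range.
    """
    lo = max(donor_emission.wavelengths[0], acceptor_absorption.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_absorption.wavelengths[-1])
    if hi <= lo:
        raise ValueError("donor emission and acceptor absorption do not overlap")
    grid = np.union1d(donor_emission.wavelengths, acceptor_absorption.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise ValueError("fewer than two wavelength points in the overlap range")
    f_d = np.interp(grid, donor_emission.wavelengths, donor_emission.values)
    eps_a = np.interp(grid, acceptor_absorption.wavelengths, acceptor_absorption.values)
    area = np.trapezoid(f_d, grid)
    if area <= 0:
        raise ValueError("donor emission is zero over the overlap range")
    return float(np.trapezoid((f_d / area) * eps_a * grid**4, grid))


def forster_radius(
    j: float,
    donor_qy: float,
    kappa_sq: float = 2.0 / 3.0,
    refractive_index: float = 1.33,
) -> float:
    """Förster radius in nm from the overlap integral.

    ``j`` must be in M^-1 cm^-1 nm^4.  kappa^2 defaults to 2/3 (freely
    rotating dipoles) and the refractive index to 1.33 (aqueous medium).
    kappa^2 = 0 is geometrically degenerate and returns R0 = 0 with a
    warning.
    """
    if j <= 0:
        raise ValueError("overlap integral must be positive")
    if not 0 < donor_qy <= 1:
        raise ValueError("donor quantum yield must lie in (0, 1]")
    if not 0 <= kappa_sq <= 4:
        raise ValueError("kappa^2 must lie in [0, 4]")
    if refractive_index < 1:
        raise ValueError("refractive index must be >= 1")
    if kappa_sq == 0:
        warnings.warn("kappa^2 = 0: orthogonal dipoles give R0 = 0", stacklevel=2)
        return 0.0
    r0_6 = _R0_PREFACTOR_NM6 * kappa_sq * donor_qy * j / refractive_index**4
    return float(r0_6 ** (1.0 / 6.0))


def analyze_pair(pair: FluorophorePair, efficiency: float) -> FretResult:
    """Compute J, R0 and the donor-acceptor distance for a measured E."""
    j = pair.overlap_integral()
    r0 = pair.forster_radius()
    r = distance_from_efficiency(efficiency, r0)
    return FretResult(efficiency=efficiency, distance=r, forster_radius=r0, overlap=j)
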