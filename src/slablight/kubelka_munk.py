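"""Two-flux Kubelka-Munk model for a turbid slab.

This module converts integrating-sphere measurements of diffuse reflectance
``R_d`` and diffuse transmittance ``T_d`` of a slab of known thickness into
the two-flux coefficients ``S`` (scattering per unit length) and ``K``
(absorption flux loss per unit length), and from those into the transport
coefficients ``mu_a`` and ``mu_s`` used by radiative-transfer codes.

The inversion is closed form.  With

    x = (1 - T_d^2 + R_d^2) / (2 R_d),        y = sqrt(x^2 - 1),

the scattering flux coefficient is

    S = (1 / (y t)) * ln[(1 - R_d (x - y)) / T_d],

and then ``K = S (x - 1)``, ``mu_a = K / 2`` and
``mu_s = (4 S + mu_a) / (3 (1 - g))`` with ``g`` the scattering anisotropy.
The bracket in the ``S`` expression is the argument of a natural logarithm:
this is the standard hyperbolic two-flux solution, and it is what makes the
forward model below an exact inverse (see :func:`km_forward`).

The forward model is the matching closed-form solution of the two-flux
system ``dI/dz = -(S+K) I + S J``, ``dJ/dz = (S+K) J - S I`` with a unit
downward flux at the top surface and no upward flux entering the bottom:

    a = (S + K) / S,   b = sqrt(a^2 - 1),
    R_d = sinh(b S t) / (a sinh(b S t) + b cosh(b S t)),
    T_d = b           / (a sinh(b S t) + b cosh(b S t)).

All lengths are in cm and coefficients in cm^-1; wavelength is metadata
only, since the model treats each wavelength independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConversionDomainError,
    DegenerateInversionError,
    InvalidMeasurementError,
)

#: Default scattering anisotropy for UHMWPE: strongly forward-directed.
DEFAULT_G = 0.9

#: Default refractive index of polyethylene (literature value); used only
#: for Fresnel boundary handling in the Monte Carlo simulator.
DEFAULT_N = 1.54

#: Tolerance on y = sqrt(x^2 - 1) below which the inversion is treated as
#: the degenerate non-absorbing case.
_Y_DEGENERATE_TOL = 1e-9

#: Slack allowed on the energy bound r_d + t_d <= 1 before a measurement
#: pair is rejected outright.
_ENERGY_TOL = 1e-12

__all__ = [
    "DEFAULT_G",
    "DEFAULT_N",
    "MeasuredSpectrum",
    "KMCoefficients",
    "OpticalProperties",
    "km_auxiliaries",
    "km_invert",
    "km_forward",
]


@dataclass(frozen=True)
class MeasuredSpectrum:
    """Wavelength-indexed diffuse reflectance/transmittance of one sample.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    r_d, t_d : array of float
        Diffuse reflectance and transmittance as fractions in (0, 1),
        with ``r_d + t_d <= 1`` at every wavelength.
    thickness : float
        Slab thickness in cm.
    label : str
        Free-text sample label, e.g. a dose group such as ``"P-0"``.
    """

    wavelengths: np.ndarray
    r_d: np.ndarray
    t_d: np.ndarray
    thickness: float
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.r_d, dtype=float)
        t = np.asarray(self.t_d, dtype=float)
        if not (wl.shape == r.shape == t.shape) or wl.ndim != 1:
            raise InvalidMeasurementError(
                "wavelengths, r_d and t_d must be 1-d arrays of equal length"
            )
        if wl.size and np.any(np.diff(wl) <= 0):
            raise InvalidMeasurementError("wavelengths must be strictly increasing")
        if np.any(r <= 0) or np.any(r >= 1) or np.any(t <= 0) or np.any(t >= 1):
            raise InvalidMeasurementError("r_d and t_d must lie strictly in (0, 1)")
        bad = r + t > 1 + _ENERGY_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise InvalidMeasurementError(
                f"r_d + t_d > 1 at {wl[i]:g} nm "
                f"(r_d={r[i]:.6g}, t_d={t[i]:.6g})"
            )
        if not self.thickness > 0:
            raise InvalidMeasurementError("thickness must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "r_d", r)
        object.__setattr__(self, "t_d", t)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class KMCoefficients:
    """Two-flux coefficients per wavelength.

    ``s`` and ``k`` are the scattering and absorption flux coefficients in
    cm^-1; ``x`` and ``y`` are the dimensionless auxiliaries of the
    inversion, with ``x >= 1`` and ``y = sqrt(x^2 - 1)``.
    """

    s: np.ndarray
    k: np.ndarray
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class OpticalProperties:
    """Transport optical properties: mu_a, mu_s (cm^-1), anisotropy g, index n.

    ``mu_a`` and ``mu_s`` may be scalars or per-wavelength arrays; ``g`` and
    ``n`` are scalars.  ``n`` only matters for boundary physics in the
    Monte Carlo simulator.
    """

    mu_a: float | np.ndarray
    mu_s: float | np.ndarray
    g: float = DEFAULT_G
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.mu_a) < 0) or np.any(np.asarray(self.mu_s) < 0):
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("refractive index n must be >= 1")

    def with_(self, **changes) -> "OpticalProperties":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def km_auxiliaries(r_d, t_d):
    """Compute the two-flux auxiliaries x and y from one (R_d, T_d) pair.

    x = (1 - T_d^2 + R_d^2) / (2 R_d) and y = sqrt(x^2 - 1).  Values of x
    marginally below 1 (within 1e-9, from measurement rounding at the
    non-absorbing limit) are clamped to 1.

    Accepts scalars or equal-shaped arrays; raises
    :class:`InvalidMeasurementError` for any pair with x < 1 beyond
    tolerance, which signals an unphysical measurement such as
    ``r_d + t_d > 1``.
    """
    r = np.asarray(r_d, dtype=float)
    t = np.asarray(t_d, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise InvalidMeasurementError("r_d must lie strictly in (0, 1)")
    if np.any(t < 0) or np.any(t >= 1):
        raise InvalidMeasurementError("t_d must lie in [0, 1)")
    x = (1.0 - t**2 + r**2) / (2.0 * r)
    bad = x < 1.0 - 1e-9
    if np.any(bad):
        i = np.argmax(bad)
        rb = float(np.ravel(r)[i] if r.ndim else r)
        tb = float(np.ravel(t)[i] if t.ndim else t)
        raise InvalidMeasurementError(
            f"invalid measurement pair r_d={rb:.6g}, t_d={tb:.6g}: "
            "x < 1 (r_d + t_d likely exceeds 1)"
        )
    x = np.maximum(x, 1.0)
    y = np.sqrt(x**2 - 1.0)
    if np.isscalar(r_d) and np.isscalar(t_d):
        return float(x), float(y)
    return x, y


def km_invert(
    spectrum: MeasuredSpectrum, g: float = DEFAULT_G, n: float = DEFAULT_N
) -> tuple[KMCoefficients, OpticalProperties]:
    """Invert measured R_d/T_d into two-flux and transport coefficients.

    Returns per-wavelength ``KMCoefficients`` (S, K, x, y) and
    ``OpticalProperties`` (mu_a, mu_s) for the given anisotropy ``g``.

    Raises
    ------
    DegenerateInversionError
        If any wavelength has ``y ~ 0`` (r_d + t_d = 1, the non-absorbing
        limit); the two-flux system then has K = 0 and S is not recoverable
        from this formula.
    InvalidMeasurementError
        If the argument of the logarithm is non-positive for some pair.
    """
    if not -1 < g < 1:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    x, y = km_auxiliaries(spectrum.r_d, spectrum.t_d)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    degenerate = y < _Y_DEGENERATE_TOL
    if np.any(degenerate):
        i = int(np.argmax(degenerate))
        raise DegenerateInversionError(
            f"non-absorbing measurement at {spectrum.wavelengths[i]:g} nm "
            "(r_d + t_d = 1): the inversion degenerates; treat as K = 0"
        )
    log_arg = (1.0 - spectrum.r_d * (x - y)) / spectrum.t_d
    if np.any(log_arg <= 0):
        i = int(np.argmax(log_arg <= 0))
        raise InvalidMeasurementError(
            f"non-positive logarithm argument at {spectrum.wavelengths[i]:g} nm; "
            "the measurement pair is outside the two-flux domain"
        )
    s = np.log(log_arg) / (y * spectrum.thickness)
    k = s * (x - 1.0)
    mu_a = k / 2.0
    mu_s = (4.0 * s + mu_a) / (3.0 * (1.0 - g))
    coeffs = KMCoefficients(s=s, k=k, x=x, y=y)
    props = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)
    return coeffs, props


def transport_to_flux(mu_a, mu_s, g: float = DEFAULT_G):
    """Map transport coefficients (mu_a, mu_s, g) to two-flux (S, K).

    K = 2 mu_a and S = (3 (1 - g) mu_s - mu_a) / 4, the inverse of the
    relations used by :func:`km_invert`.  Raises
    :class:`ConversionDomainError` when S would be non-positive (absorption
    too strong relative to reduced scattering for a two-flux description).
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s = np.asarray(mu_s, dtype=float)
    k = 2.0 * mu_a
    s = (3.0 * (1.0 - g) * mu_s - mu_a) / 4.0
    if np.any(s <= 0):
        raise ConversionDomainError(
            "mu_a too large relative to (1 - g) mu_s: two-flux S <= 0"
        )
    return s, k


def km_forward(
    props: OpticalProperties, thickness: float
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Forward two-flux model: predict (R_d, T_d) for a slab.

    Converts (mu_a, mu_s, g) to flux coefficients via
    :func:`transport_to_flux` and evaluates the hyperbolic closed form.
    The non-absorbing limit K = 0 is taken analytically:
    ``R_d = S t / (1 + S t)``, ``T_d = 1 / (1 + S t)``, so that
    ``R_d + T_d = 1`` exactly.

    This function is the exact inverse of :func:`km_invert` and also serves
    as the reference that Monte Carlo runs are validated against.
    """
    if not thickness > 0:
        raise ValueError("thickness must be positive")
    s, k = transport_to_flux(props.mu_a, props.mu_s, props.g)
    s = np.atleast_1d(s)
    k = np.atleast_1d(k)
    a = (s + k) / s
    # the K -> 0 limit is taken analytically: below ~1e-12 relative
    # absorption, a^2 - 1 underflows and the hyperbolic form becomes 0/0
    absorbing = k > 1e-12 * s
    b = np.sqrt(np.maximum(a**2 - 1.0, 0.0))
    bst = b * s * thickness
    denom = a * np.sinh(bst) + b * np.cosh(bst)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_d = np.where(absorbing, np.sinh(bst) / denom, s * thickness / (1 + s * thickness))
        t_d = np.where(absorbing, b / denom, 1.0 / (1 + s * thickness))
    scalar = np.isscalar(props.mu_a) and np.isscalar(props.mu_s)
    if scalar:
        return float(r_d[0]), float(t_d[0])
    return r_d, t_d
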