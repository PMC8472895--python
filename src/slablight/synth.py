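"""Synthetic integrating-sphere spectra for the three gamma-dose groups.

No raw reflectance/transmittance spectra are published for the UHMWPE
samples, so this module emulates them: smooth per-dose coefficient curves
are interpolated through the packaged reference table (monotone piecewise
cubic, so the steep 630-700 nm drop of the irradiated samples does not
overshoot), pushed through the forward two-flux model to obtain noise-free
R_d/T_d, and multiplied by independent Gaussian measurement noise.  The
default relative noise is 3%, the stated upper bound on the measurement
standard deviation of the original campaign; noise is independent across
wavelengths and between R_d and T_d because no replicate-level correlation
information exists.

Every generated spectrum is deterministic given its seed and carries its
ground-truth curves, enabling parameter-recovery tests of the inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .derived import load_reference_table
from .errors import ConfigError, InvalidMeasurementError
from .kubelka_munk import DEFAULT_G, MeasuredSpectrum, OpticalProperties, km_forward

__all__ = [
    "SyntheticSpec",
    "default_dose_curves",
    "generate_spectrum",
    "DOSE_LABELS",
]

DOSE_LABELS = ("P-0", "P-30", "P-100")

#: Default slab thickness in cm (the molded sheets are 500 um).
DEFAULT_THICKNESS = 0.05

#: Upper bound on the relative measurement noise (3%).
DEFAULT_NOISE_REL_SD = 0.03

_MAX_RESAMPLE = 100


def default_dose_curves(dose_label: str):
    """Smooth mu_a(lambda), mu_s(lambda) interpolants for one dose group.

    Returns a pair of callables (cm^-1 as a function of wavelength in nm)
    that pass exactly through the reference-table knots at the 18 printed
    wavelengths (630-800 nm).  Monotone piecewise-cubic interpolation keeps
    the curves free of overshoot between knots.
    """
    if dose_label not in DOSE_LABELS:
        raise ConfigError(
            f"unknown dose label {dose_label!r}; expected one of {DOSE_LABELS}"
        )
    table = load_reference_table()
    sub = table[table["dose"] == dose_label].sort_values("wavelength_nm")
    wl = sub["wavelength_nm"].to_numpy(dtype=float)
    mu_a = PchipInterpolator(wl, sub["mu_a"].to_numpy(dtype=float))
    mu_s = PchipInterpolator(wl, sub["mu_s"].to_numpy(dtype=float))
    return mu_a, mu_s


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic measured spectrum.

    ``mu_a_curve``/``mu_s_curve`` default to the dose group's reference
    interpolants; custom callables (wavelength nm -> cm^-1) may be
    supplied.  ``noise_rel_sd`` is the relative standard deviation of the
    multiplicative Gaussian measurement noise, at most 10%.
    """

    dose_label: str = "P-0"
    wavelength_range: tuple[float, float] = (630.0, 800.0)
    n_points: int = 18
    g: float = DEFAULT_G
    thickness: float = DEFAULT_THICKNESS
    noise_rel_sd: float = DEFAULT_NOISE_REL_SD
    seed: int = 0
    mu_a_curve: object = None
    mu_s_curve: object = None

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rel_sd <= 0.1:
            raise ConfigError("noise_rel_sd must lie in [0, 0.1]")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ConfigError("wavelength_range must be increasing")
        if self.mu_a_curve is None or self.mu_s_curve is None:
            mu_a, mu_s = default_dose_curves(self.dose_label)
            if self.mu_a_curve is None:
                object.__setattr__(self, "mu_a_curve", mu_a)
            if self.mu_s_curve is None:
                object.__setattr__(self, "mu_s_curve", mu_s)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_points)

    def true_properties(self) -> OpticalProperties:
        wl = self.wavelengths
        mu_a = np.asarray(self.mu_a_curve(wl), dtype=float)
        mu_s = np.asarray(self.mu_s_curve(wl), dtype=float)
        if np.any(mu_a <= 0) or np.any(mu_s <= 0):
            raise ConfigError("coefficient curves must be positive over the range")
        return OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=self.g)


def generate_spectrum(spec: SyntheticSpec) -> MeasuredSpectrum:
    """Generate one measurement-like spectrum from a :class:`SyntheticSpec`.

    The noise-free R_d/T_d come from the forward two-flux model at the
    spec's true coefficient curves; each value is then multiplied by
    ``1 + eps`` with ``eps ~ Normal(0, noise_rel_sd)``, independently per
    wavelength and channel.  Draws that would violate the physical
    invariants (values outside (0, 1) or ``r_d + t_d > 1``) are resampled
    per-wavelength up to a bounded retry count, after which generation
    fails rather than silently truncating the noise distribution.
    """
    wl = spec.wavelengths
    props = spec.true_properties()
    r0, t0 = km_forward(props, spec.thickness)
    r0 = np.atleast_1d(np.asarray(r0))
    t0 = np.atleast_1d(np.asarray(t0))
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.noise_rel_sd == 0:
        r_d, t_d = r0.copy(), t0.copy()
    else:
        r_d = np.full_like(r0, np.nan)
        t_d = np.full_like(t0, np.nan)
        pending = np.ones(wl.size, dtype=bool)
        for _ in range(_MAX_RESAMPLE):
            m = int(pending.sum())
            if m == 0:
                break
            eps_r = rng.normal(0.0, spec.noise_rel_sd, m)
            eps_t = rng.normal(0.0, spec.noise_rel_sd, m)
            cand_r = r0[pending] * (1.0 + eps_r)
            cand_t = t0[pending] * (1.0 + eps_t)
            ok = (
                (cand_r > 0)
                & (cand_r < 1)
                & (cand_t > 0)
                & (cand_t < 1)
                & (cand_r + cand_t < 1)
            )
            idx = np.where(pending)[0][ok]
            r_d[idx] = cand_r[ok]
            t_d[idx] = cand_t[ok]
            pending[idx] = False
        else:
            raise InvalidMeasurementError(
                "could not draw physical noisy measurements within the retry "
                "budget; lower noise_rel_sd"
            )
    return MeasuredSpectrum(
        wavelengths=wl,
        r_d=r_d,
        t_d=t_d,
        thickness=spec.thickness,
        label=spec.dose_label,
    )
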