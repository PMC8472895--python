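"""Derived per-wavelength optical quantities and spectral tables.

From transport coefficients (mu_a, mu_s, g) this module computes the
quantities used to summarise light distribution in a turbid slab:

* total attenuation  ``mu_t = mu_a + mu_s``            [cm^-1]
* effective attenuation ``mu_eff = mu_a + mu_s (1-g)`` [cm^-1]
* penetration depth  ``delta = 1 / mu_eff``            [cm]
* transport albedo   ``mu_s / (mu_a + mu_s)``          [dimensionless]

``mu_eff`` here is the transport attenuation coefficient (absorption plus
reduced scattering); the diffusion-theory effective attenuation
``sqrt(3 mu_a (mu_a + mu_s (1-g)))`` is available separately as
:func:`effective_attenuation_diffusion` but is not used by the pipeline,
because only the transport form reproduces the millimetre-scale
penetration depths observed for gamma-irradiated polyethylene.

The albedo convention here is the ratio of scattering to total attenuation
``mu_s / (mu_a + mu_s)`` (0 = fully absorbing, 1 = no absorption), i.e. the
single-scattering albedo; it is named ``transport_albedo`` to match the
terminology used for these materials.

:class:`SpectralTable` assembles everything into a tidy per-(wavelength,
dose) table serialisable to CSV/JSON.  The packaged reference table of
UHMWPE coefficients (three gamma-dose groups, 630-800 nm) is loaded by
:func:`load_reference_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import TableAssemblyError
from .kubelka_munk import DEFAULT_G, OpticalProperties

__all__ = [
    "DerivedOptics",
    "SpectralTable",
    "total_attenuation",
    "effective_attenuation",
    "effective_attenuation_diffusion",
    "penetration_depth",
    "transport_albedo",
    "derive",
    "build_spectral_table",
    "load_reference_table",
    "reference_spectral_table",
]


def total_attenuation(props: OpticalProperties):
    """Total attenuation coefficient mu_t = mu_a + mu_s, in cm^-1."""
    return props.mu_a + props.mu_s


def effective_attenuation(props: OpticalProperties):
    """Transport attenuation mu_eff = mu_a + mu_s (1 - g), in cm^-1."""
    return props.mu_a + props.mu_s * (1.0 - props.g)


def effective_attenuation_diffusion(props: OpticalProperties):
    """Diffusion-theory effective attenuation sqrt(3 mu_a (mu_a + mu_s(1-g))).

    Provided for comparison only; :func:`effective_attenuation` is the form
    used throughout the pipeline.
    """
    return np.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s * (1.0 - props.g)))


def penetration_depth(mu_eff):
    """1/e penetration depth delta = 1 / mu_eff, in cm.

    Raises ``ValueError`` for non-positive mu_eff.
    """
    mu = np.asarray(mu_eff, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu_eff must be positive")
    out = 1.0 / mu
    return float(out) if np.isscalar(mu_eff) else out


def transport_albedo(props: OpticalProperties):
    """Albedo mu_s / (mu_a + mu_s), in [0, 1].

    Raises ``ValueError`` when mu_a + mu_s = 0 (no interaction at all).
    """
    mu_t = np.asarray(props.mu_a + props.mu_s, dtype=float)
    if np.any(mu_t <= 0):
        raise ValueError("mu_a + mu_s must be positive")
    out = np.asarray(props.mu_s, dtype=float) / mu_t
    return float(out) if np.isscalar(props.mu_a) else out


@dataclass(frozen=True)
class DerivedOptics:
    """Derived quantities for one sample: mu_t, mu_eff (cm^-1), delta (cm), albedo."""

    mu_t: float | np.ndarray
    mu_eff: float | np.ndarray
    delta: float | np.ndarray
    albedo: float | np.ndarray


def derive(props: OpticalProperties) -> DerivedOptics:
    """Compute all derived quantities for one set of optical properties."""
    mu_eff = effective_attenuation(props)
    return DerivedOptics(
        mu_t=total_attenuation(props),
        mu_eff=mu_eff,
        delta=penetration_depth(mu_eff),
        albedo=transport_albedo(props),
    )


_COLUMNS = [
    "wavelength_nm",
    "dose",
    "mu_a",
    "mu_s",
    "mu_t",
    "mu_eff",
    "delta_mm",
    "albedo",
]


@dataclass(frozen=True)
class SpectralTable:
    """Per-(wavelength, dose) table of optical properties and derived optics.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``wavelength_nm, dose, mu_a, mu_s, mu_t, mu_eff, delta_mm, albedo``.
    ``delta_mm`` is the penetration depth in millimetres (internally all
    lengths are cm; the table prints mm for readability).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise TableAssemblyError(f"missing columns: {missing}")
        keys = df[["wavelength_nm", "dose"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise TableAssemblyError(
                f"duplicate (wavelength, dose) key: "
                f"({dup['wavelength_nm']:g} nm, {dup['dose']})"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def doses(self) -> list[str]:
        return list(dict.fromkeys(self.frame["dose"]))

    def select(self, wavelength_nm: float, dose: str) -> pd.Series:
        """Return the single row for one (wavelength, dose) pair."""
        df = self.frame
        m = (df["wavelength_nm"] == wavelength_nm) & (df["dose"] == dose)
        if not m.any():
            raise KeyError(f"no row for ({wavelength_nm:g} nm, {dose})")
        return df[m].iloc[0]

    def properties(
        self, wavelength_nm: float, dose: str, g: float = DEFAULT_G
    ) -> OpticalProperties:
        """OpticalProperties for one (wavelength, dose) row."""
        row = self.select(wavelength_nm, dose)
        return OpticalProperties(mu_a=float(row["mu_a"]), mu_s=float(row["mu_s"]), g=g)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=1)

    @classmethod
    def from_csv(cls, path) -> "SpectralTable":
        return cls(pd.read_csv(path))


def build_spectral_table(
    per_dose_properties: dict[str, tuple[np.ndarray, OpticalProperties]],
) -> SpectralTable:
    """Assemble a SpectralTable from per-dose (wavelengths, properties) pairs.

    ``per_dose_properties`` maps a dose label to a pair of a wavelength
    array (nm) and an :class:`OpticalProperties` with array-valued
    ``mu_a``/``mu_s`` on that grid.  Returns the table with all derived
    quantities populated; an empty input yields an empty table.
    """
    records = []
    for dose, (wavelengths, props) in per_dose_properties.items():
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        mu_a = np.broadcast_to(np.asarray(props.mu_a, dtype=float), wl.shape)
        mu_s = np.broadcast_to(np.asarray(props.mu_s, dtype=float), wl.shape)
        d = derive(OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=props.g, n=props.n))
        for i in range(wl.size):
            records.append(
                {
                    "wavelength_nm": wl[i],
                    "dose": dose,
                    "mu_a": mu_a[i],
                    "mu_s": mu_s[i],
                    "mu_t": np.asarray(d.mu_t)[i],
                    "mu_eff": np.asarray(d.mu_eff)[i],
                    "delta_mm": 10.0 * np.asarray(d.delta)[i],
                    "albedo": np.asarray(d.albedo)[i],
                }
            )
    frame = pd.DataFrame.from_records(records, columns=_COLUMNS)
    return SpectralTable(frame)


def load_reference_table(g: float = DEFAULT_G) -> pd.DataFrame:
    """Load the packaged UHMWPE reference coefficients (630-800 nm, 3 doses).

    Returns the tidy DataFrame with columns ``wavelength_nm, dose, mu_a,
    mu_s, mu_t`` exactly as printed in the source measurement campaign
    (``mu_t`` is the independently printed total attenuation, retained to
    allow consistency checks against ``mu_a + mu_s``).
    """
    with resources.files("slablight.data").joinpath("table1.csv").open() as f:
        return pd.read_csv(f)


def reference_spectral_table(g: float = DEFAULT_G) -> SpectralTable:
    """Full SpectralTable derived from the packaged reference coefficients."""
    raw = load_reference_table()
    per_dose = {}
    for dose, sub in raw.groupby("dose", sort=False):
        props = OpticalProperties(
            mu_a=sub["mu_a"].to_numpy(), mu_s=sub["mu_s"].to_numpy(), g=g
        )
        per_dose[dose] = (sub["wavelength_nm"].to_numpy(), props)
    return build_spectral_table(per_dose)
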