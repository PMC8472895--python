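"""Exception hierarchy for slablight.

All package-specific failures derive from :class:`SlablightError` so callers
can catch one base class at pipeline level while tests discriminate precisely.
"""


class SlablightError(Exception):
    """Base class for all slablight errors."""


class InvalidMeasurementError(SlablightError, ValueError):
    """A reflectance/transmittance pair is physically impossible.

    Raised when the two-flux auxiliaries cannot be formed, e.g. because
    R_d + T_d exceeds 1 beyond tolerance, or the log argument of the
    scattering-coefficient formula is non-positive.
    """


class DegenerateInversionError(SlablightError, ValueError):
    """The inversion is degenerate (non-absorbing limit, y ~ 0).

    When R_d + T_d = 1 there is no absorption and the two-flux system
    collapses; the caller should treat the sample as K = 0 rather than
    divide by y.
    """


class ConversionDomainError(SlablightError, ValueError):
    """Transport coefficients map outside the two-flux domain.

    The K/S <-> mu conversion requires S > 0; a very absorbing, weakly
    scattering medium (mu_a > 3 (1-g) mu_s) has no two-flux equivalent.
    """


class ConfigError(SlablightError, ValueError):
    """A simulation or pipeline configuration value is invalid."""


class TableAssemblyError(SlablightError, ValueError):
    """Duplicate or inconsistent keys while assembling a spectral table."""
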