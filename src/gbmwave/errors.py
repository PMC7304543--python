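"""Exception hierarchy for gbmwave."""


class GbmWaveError(Exception):
    """Base class for all gbmwave errors."""


class DomainError(GbmWaveError, ValueError):
    """An input lies outside its mathematical domain."""


class ProfileError(GbmWaveError):
    """The reduced-system wave profile could not be computed."""


class IdentifiabilityError(GbmWaveError):
    """The measured width ratio lies outside the attainable range of f(rho_hat).

    Attributes
    ----------
    target : float
        The requested L1/L2 ratio.
    attainable : tuple of float
        (min, max) of f over the search bracket.
    """

    def __init__(self, target, attainable, bracket):
        self.target = target
        self.attainable = attainable
        self.bracket = bracket
        super().__init__(
            f"width ratio {target:.6g} outside attainable range "
            f"[{attainable[0]:.6g}, {attainable[1]:.6g}] of f on "
            f"rho_hat bracket [{bracket[0]:g}, {bracket[1]:g}]"
        )


class UndetectableTumorError(GbmWaveError):
    """The point-source tumor is below the imaging threshold at t = t*."""


class EstimationError(GbmWaveError):
    """A protocol equation could not be solved.

    May carry the scanned residual curve for diagnostics in ``residual_curve``
    (array of (rho, residual) pairs).
    """

    def __init__(self, message, residual_curve=None):
        self.residual_curve = residual_curve
        super().__init__(message)


class SolverError(GbmWaveError):
    """The PDE solver failed or produced an inadmissible solution."""


class MeasurementError(GbmWaveError):
    """Wave measurement failed (e.g. the front reached the boundary)."""


class ConfigError(GbmWaveError, ValueError):
    """A configuration file or value is invalid."""
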