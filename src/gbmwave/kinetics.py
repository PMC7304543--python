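"""Growth and death response functions for the two-population GBM model.

The model splits glioma cells into proliferating cells ``p`` and quiescent
(functionally necrotic) cells ``q``; the implicit resource variable
``w = 1 - p - q`` ("growth factor") drives a per-capita birth rate
``rho * g(w)`` and a quiescence (death) rate ``k * delta(w)``.  Biological
admissibility requires

* ``g`` non-decreasing with ``g(0) = 0`` and ``g(1) = 1``,
* ``delta`` non-increasing with ``delta(1) = 0`` and ``delta(0) = 1``,

so that birth dominates at abundant growth factor and only death remains
when the tissue is saturated.  The package realises both responses with the
CDF of the beta distribution: ``g(w) = B(w; alpha_g, beta_g)`` and
``delta(w) = 1 - B(w; alpha_d, beta_d)``, which covers linear, sigmoidal and
concave shapes with two parameters each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betainc

from .errors import DomainError

__all__ = [
    "GrowthDeathModel",
    "ConstraintReport",
    "growth_response",
    "death_response",
    "validate_constraints",
    "SHAPE_PRESETS",
    "CANDIDATE_SHAPES",
    "REFERENCE_SHAPES",
]

#: Named (alpha_g, beta_g, alpha_d, beta_d) shape presets.  ``reference`` is
#: the configuration under which the published six-patient parameterisation
#: is reproduced: sigmoidal birth Beta(2,2) and concave death
#: delta(w) = (1-w)^3 (the Beta(1,3) complement).
SHAPE_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "linear": (1.0, 1.0, 1.0, 1.0),
    "sigmoidal": (2.0, 2.0, 2.0, 2.0),
    "concave_up": (2.0, 1.0, 2.0, 1.0),
    "concave_down": (1.0, 2.0, 1.0, 2.0),
    "reference": (2.0, 2.0, 1.0, 3.0),
}

REFERENCE_SHAPES: tuple[float, float, float, float] = SHAPE_PRESETS["reference"]

#: Shape combinations used in identifiability sweeps: every pairing of a
#: linear / sigmoidal / concave-up / concave-down birth curve with an
#: analogous death curve, plus the reference pair.
CANDIDATE_SHAPES: dict[str, tuple[float, float, float, float]] = {
    "linear": (1, 1, 1, 1),
    "sigmoidal": (2, 2, 2, 2),
    "concave_up": (2, 1, 2, 1),
    "concave_down": (1, 2, 1, 2),
    "g_sig_d_lin": (2, 2, 1, 1),
    "g_lin_d_sig": (1, 1, 2, 2),
    "g_cup_d_cdn": (2, 1, 1, 2),
    "g_cdn_d_cup": (1, 2, 2, 1),
    "reference": REFERENCE_SHAPES,
}


@dataclass(frozen=True)
class GrowthDeathModel:
    """Beta-CDF birth/death response pair with optional dimensional rates.

    Parameters
    ----------
    alpha_g, beta_g : float
        Shape parameters of the birth response ``g(w) = B(w; alpha_g, beta_g)``.
    alpha_d, beta_d : float
        Shape parameters of the death response
        ``delta(w) = 1 - B(w; alpha_d, beta_d)``.
    rho : float, optional
        Maximal proliferation rate (per day), attained at ``w = 1``.
    k : float, optional
        Maximal quiescence/death rate (per day), attained at ``w = 0``.
    """

    alpha_g: float = 2.0
    beta_g: float = 2.0
    alpha_d: float = 1.0
    beta_d: float = 3.0
    rho: float | None = None
    k: float | None = None

    def __post_init__(self):
        for name in ("alpha_g", "beta_g", "alpha_d", "beta_d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be a positive real, got {v!r}")
        for name in ("rho", "k"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be positive when given, got {v!r}")

    @classmethod
    def from_preset(cls, name: str, rho: float | None = None, k: float | None = None):
        try:
            shapes = SHAPE_PRESETS[name]
        except KeyError:
            raise DomainError(
                f"unknown shape preset {name!r}; available: {sorted(SHAPE_PRESETS)}"
            ) from None
        return cls(*shapes, rho=rho, k=k)

    @property
    def shapes(self) -> tuple[float, float, float, float]:
        return (self.alpha_g, self.beta_g, self.alpha_d, self.beta_d)

    @property
    def rho_hat(self) -> float:
        """Dimensionless proliferation-to-death ratio rho/k."""
        if self.rho is None or self.k is None:
            raise DomainError("rho_hat requires both rho and k to be set")
        return self.rho / self.k

    def with_rates(self, rho: float, k: float) -> "GrowthDeathModel":
        return replace(self, rho=rho, k=k)

    # -- response functions -------------------------------------------------

    def g(self, w):
        """Normalised birth response B(w; alpha_g, beta_g) on [0, 1]."""
        w = _check_unit_interval(w)
        return betainc(self.alpha_g, self.beta_g, w)

    def delta(self, w):
        """Normalised death response 1 - B(w; alpha_d, beta_d) on [0, 1]."""
        w = _check_unit_interval(w)
        return 1.0 - betainc(self.alpha_d, self.beta_d, w)


def _check_unit_interval(w):
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise DomainError("growth factor w must lie in [0, 1]")
    return w if w.ndim else float(w)


def growth_response(model: GrowthDeathModel, w):
    """Evaluate the birth response g(w); exact 0 at w=0 and 1 at w=1."""
    return model.g(w)


def death_response(model: GrowthDeathModel, w):
    """Evaluate the death response delta(w); 1 at w=0 and 0 at w=1."""
    return model.delta(w)


@dataclass(frozen=True)
class ConstraintReport:
    """Pass/fail record for the biological admissibility conditions."""

    g_nondecreasing: bool
    delta_nonincreasing: bool
    g_zero_at_empty: bool        # g(0) = 0
    g_one_at_full: bool          # g(1) = 1
    delta_one_at_empty: bool     # delta(0) = 1
    delta_zero_at_full: bool     # delta(1) = 0
    birth_dominates_at_full: bool   # g(1)*rho >= delta(1)*k
    death_dominates_at_empty: bool  # delta(0)*k > g(0)*rho
    n_grid: int = field(default=0, compare=False)

    @property
    def passed(self) -> bool:
        return all(
            getattr(self, f)
            for f in (
                "g_nondecreasing",
                "delta_nonincreasing",
                "g_zero_at_empty",
                "g_one_at_full",
                "delta_one_at_empty",
                "delta_zero_at_full",
                "birth_dominates_at_full",
                "death_dominates_at_empty",
            )
        )


def validate_constraints(model, n_grid: int = 201, atol: float = 1e-9) -> ConstraintReport:
    """Check the admissibility constraints on a uniform w-grid.

    ``model`` may be any object exposing ``g`` and ``delta`` callables (and
    optionally ``rho``/``k``); tests may inject deliberately broken response
    functions.  A report object is always returned, never an exception.
    """
    if n_grid < 2:
        raise DomainError("n_grid must be at least 2")
    w = np.linspace(0.0, 1.0, n_grid)
    gv = np.asarray([float(model.g(x)) for x in w])
    dv = np.asarray([float(model.delta(x)) for x in w])
    rho = getattr(model, "rho", None) or 1.0
    k = getattr(model, "k", None) or 1.0
    return ConstraintReport(
        g_nondecreasing=bool(np.all(np.diff(gv) >= -atol)),
        delta_nonincreasing=bool(np.all(np.diff(dv) <= atol)),
        g_zero_at_empty=bool(abs(gv[0]) <= atol),
        g_one_at_full=bool(abs(gv[-1] - 1.0) <= atol),
        delta_one_at_empty=bool(abs(dv[0] - 1.0) <= atol),
        delta_zero_at_full=bool(abs(dv[-1]) <= atol),
        birth_dominates_at_full=bool(gv[-1] * rho >= dv[-1] * k - atol),
        death_dominates_at_empty=bool(dv[0] * k > gv[0] * rho + atol),
        n_grid=n_grid,
    )
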