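"""Inverse estimation of (D, rho, k) from MRI-derived tumor radii.

A patient record carries three equivalent-sphere radii: the necrotic core
R0, the enhancing-rim edge R1 and the edema extent R2 (mm).  The rim and
edema widths L1 = R1 - R0 and L2 = R2 - R1 are matched to the approximate
traveling-wave widths

    ell_1 = 2 sqrt(D rho)/k * I1(rho_hat),
    ell_2 = 2 sqrt(D rho)/k * I2(rho_hat),

whose ratio depends on rho_hat = rho/k alone, so L1/L2 = f(rho_hat) pins
down rho_hat.  A third equation supplies the absolute scale:

* two-scan protocol — the image-derived front velocity V equals the wave
  speed 2 sqrt(rho D);
* single-scan protocol — the tumor ages inferred by extrapolating R1 and R2
  back to the end of the early exponential growth phase (point source of
  density p0, duration t*) must agree, which reduces to
  R2 - R1 = R*_2 - R*_1 with the exponential-phase radii R*_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DomainError,
    EstimationError,
    IdentifiabilityError,
    UndetectableTumorError,
)
from .kinetics import GrowthDeathModel
from .profile import dimensional_width, profile_metrics

__all__ = [
    "PatientObservation",
    "ImagingConfig",
    "ParameterEstimate",
    "solve_rho_hat_from_ratio",
    "estimate_two_scan",
    "estimate_single_scan",
    "exponential_phase_radius",
    "volumes_to_radii",
]


@dataclass(frozen=True)
class PatientObservation:
    """One patient's MRI-derived radii (mm) and optional front velocity.

    ``velocity_source`` records which radius the velocity was differenced
    from ("R1" or "R2"); the single-scan age estimate depends on the choice,
    so the provenance is kept with the number.
    """

    patient_id: str
    R0: float
    R1: float
    R2: float
    V: float | None = None
    velocity_source: str | None = None

    def __post_init__(self):
        if not (0 < self.R0 < self.R1 < self.R2):
            raise DomainError(
                f"radii must satisfy 0 < R0 < R1 < R2, got "
                f"({self.R0}, {self.R1}, {self.R2})"
            )
        if self.V is not None and not self.V > 0:
            raise DomainError(f"velocity must be positive when present, got {self.V}")
        if self.velocity_source not in (None, "R1", "R2"):
            raise DomainError(f"velocity_source must be 'R1' or 'R2', got {self.velocity_source!r}")

    @property
    def L1(self) -> float:
        """Proliferating-rim width R1 - R0 (mm)."""
        return self.R1 - self.R0

    @property
    def L2(self) -> float:
        """Edematous-rim width R2 - R1 (mm)."""
        return self.R2 - self.R1


@dataclass(frozen=True)
class ImagingConfig:
    """Imaging thresholds and early-growth priors of the protocols.

    a1, a2 : detection-threshold fractions of the peak proliferating density
        for T1 enhancement and T2 edema (0 < a2 < a1 < 1).
    p0 : initial point-source density of the exponential phase
        (dimensionless, cell density scaled to carrying capacity 1).
    t_star : duration of the exponential phase in days.
    threshold_times_pmax : if true, the exponential-phase detectability
        thresholds are a_i * p_max instead of a_i.  The published patient
        table is reproduced with the literal a_i convention (default).
    width_equation : which width anchors the D(rho) substitution in the
        single-scan protocol, "l1" (default) or "l2".
    """

    a1: float = 0.9
    a2: float = 0.1
    p0: float = 0.02
    t_star: float = 60.0
    threshold_times_pmax: bool = False
    width_equation: str = "l1"
    rho_hat_bracket: tuple[float, float] = (0.05, 50.0)
    rho_bracket: tuple[float, float] = (1e-3, 2.0)

    def __post_init__(self):
        if not (0.0 < self.a2 < self.a1 < 1.0):
            raise DomainError(f"need 0 < a2 < a1 < 1, got a1={self.a1}, a2={self.a2}")
        if not self.p0 > 0:
            raise DomainError(f"p0 must be positive, got {self.p0}")
        if not self.t_star > 0:
            raise DomainError(f"t_star must be positive, got {self.t_star}")
        if self.width_equation not in ("l1", "l2"):
            raise DomainError(f"width_equation must be 'l1' or 'l2', got {self.width_equation!r}")
        for name in ("rho_hat_bracket", "rho_bracket"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise DomainError(f"{name} must be an increasing positive interval")


@dataclass(frozen=True)
class ParameterEstimate:
    """Recovered patient-specific parameters with diagnostics."""

    patient_id: str
    D: float          # mm^2 / day
    rho: float        # 1 / day
    k: float          # 1 / day
    rho_hat: float
    c: float          # mm / day, wave speed 2 sqrt(rho D)
    tumor_age: float | None = None   # days since the point source
    residual: float | None = None    # misfit of the closing equation
    bracket_used: tuple[float, float] | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (self.D > 0 and self.rho > 0 and self.k > 0):
            raise DomainError("estimated D, rho, k must all be positive")


def volumes_to_radii(v_necrotic: float, v_enhancing: float, v_edema: float):
    """Map segmentation volumes (mm^3) to equivalent-sphere radii (mm).

    The compartments are nested, so radii come from cumulative volumes.
    """
    vols = (v_necrotic, v_enhancing, v_edema)
    if any(v < 0 for v in vols):
        raise DomainError(f"volumes must be non-negative, got {vols}")
    cum = np.cumsum(vols)
    return tuple(float((3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)) for v in cum)


def solve_rho_hat_from_ratio(
    ratio: float,
    model: GrowthDeathModel | None = None,
    config: ImagingConfig | None = None,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Invert f(rho_hat) = L1/L2 by bracketed root-finding.

    Raises IdentifiabilityError when the target ratio lies outside the range
    of f on the bracket (f is monotone for all admissible shape pairs, so
    the range check at the endpoints is sufficient).
    """
    if not ratio > 0:
        raise DomainError(f"width ratio must be positive, got {ratio}")
    config = config or ImagingConfig()
    model = model or GrowthDeathModel()
    lo, hi = bracket or config.rho_hat_bracket
    a1, a2 = config.a1, config.a2
    f = lambda rh: profile_metrics(rh, model, a1, a2).f_ratio
    f_lo, f_hi = f(lo), f(hi)
    fmin, fmax = min(f_lo, f_hi), max(f_lo, f_hi)
    if not (fmin < ratio < fmax):
        raise IdentifiabilityError(ratio, (fmin, fmax), (lo, hi))
    return float(brentq(lambda rh: f(rh) - ratio, lo, hi, rtol=1e-12, xtol=1e-13))


def exponential_phase_radius(
    D: float,
    rho: float,
    a_i: float,
    config: ImagingConfig | None = None,
    p_max: float | None = None,
) -> float:
    """Detectability radius R*_i at the end of the exponential phase.

    Thresholding the Gaussian point-source solution
    p(r, t) = p0 (4 pi D t)^(-3/2) exp(rho t - r^2/(4 D t)) at level ``thr``
    and t = t* gives

        R*_i = sqrt(4 D rho t*^2 - 4 D t* ln(thr (4 pi D t*)^(3/2) / p0)).

    ``thr`` is a_i, or a_i * p_max when the config requests
    threshold_times_pmax (p_max must then be supplied).
    """
    config = config or ImagingConfig()
    if not (D > 0 and rho > 0):
        raise DomainError("D and rho must be positive")
    if not (0 < a_i < 1):
        raise DomainError(f"threshold fraction must lie in (0, 1), got {a_i}")
    thr = a_i
    if config.threshold_times_pmax:
        if p_max is None:
            raise DomainError("p_max required when threshold_times_pmax is set")
        thr = a_i * p_max
    t = config.t_star
    radicand = 4.0 * D * rho * t * t - 4.0 * D * t * math.log(
        thr * (4.0 * math.pi * D * t) ** 1.5 / config.p0
    )
    if radicand <= 0:
        raise UndetectableTumorError(
            f"tumor below the a={a_i} imaging threshold at t*={t} days "
            f"(D={D:.4g}, rho={rho:.4g})"
        )
    return math.sqrt(radicand)


def estimate_two_scan(
    obs: PatientObservation,
    config: ImagingConfig | None = None,
    model: GrowthDeathModel | None = None,
) -> ParameterEstimate:
    """Estimate (D, rho, k) from widths L1, L2 plus a measured velocity V.

    rho_hat from the width ratio; then ell_1 = L1 with c = V fixes
    k = V I1 / L1, rho = rho_hat k, and c = 2 sqrt(rho D) gives
    D = (V/2)^2 / rho.
    """
    config = config or ImagingConfig()
    model = model or GrowthDeathModel()
    if obs.V is None:
        raise DomainError("two-scan protocol requires a velocity V")
    rho_hat = solve_rho_hat_from_ratio(obs.L1 / obs.L2, model, config)
    m = profile_metrics(rho_hat, model, config.a1, config.a2)
    k = obs.V * m.I1 / obs.L1
    rho = rho_hat * k
    D = (obs.V / 2.0) ** 2 / rho
    c = 2.0 * math.sqrt(rho * D)
    # closing residual: the ell_2 = L2 equation, satisfied by construction
    residual = dimensional_width(m.I2, D, rho, k) - obs.L2
    tumor_age = None
    try:
        r1s = exponential_phase_radius(D, rho, config.a1, config, m.p_max)
        tumor_age = config.t_star + (obs.R1 - r1s) / c
    except UndetectableTumorError:
        pass
    return ParameterEstimate(
        patient_id=obs.patient_id,
        D=D,
        rho=rho,
        k=k,
        rho_hat=rho_hat,
        c=c,
        tumor_age=tumor_age,
        residual=residual,
        bracket_used=config.rho_hat_bracket,
    )


def _detectability_edges(h, lo, hi, n=400):
    """Sign-change boundaries of the R*_1 radicand over [lo, hi] (log grid)."""
    grid = np.geomspace(lo, hi, n)
    vals = np.array([h(r) for r in grid])
    edges = []
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            edges.append(brentq(h, grid[i], grid[i + 1], rtol=1e-12))
    return edges


def estimate_single_scan(
    obs: PatientObservation,
    config: ImagingConfig | None = None,
    model: GrowthDeathModel | None = None,
) -> ParameterEstimate:
    """Estimate (D, rho, k) from a single scan's three radii.

    Steps: (i) rho_hat from L1/L2; (ii) D(rho) = rho s^2 with
    s = L1/(2 rho_hat I1) from ell_1 = L1 (or the analogous L2 form);
    (iii) rho from the age-consistency equation R2 - R1 = R*_2 - R*_1 by
    bracketed root-finding; (iv) k = rho/rho_hat and the tumor age
    t* + (R1 - R*_1)/c.

    The R*_1 radicand can be negative on a middle interval of rho (the
    tumor is then undetectable on T1 at t*); the sign-change scan inserts
    points just inside the detectable region around those edges.  If several
    roots survive, the largest-rho root is returned.
    """
    config = config or ImagingConfig()
    model = model or GrowthDeathModel()
    rho_hat = solve_rho_hat_from_ratio(obs.L1 / obs.L2, model, config)
    m = profile_metrics(rho_hat, model, config.a1, config.a2)
    if config.width_equation == "l1":
        s = obs.L1 / (2.0 * rho_hat * m.I1)
    else:
        s = obs.L2 / (2.0 * rho_hat * m.I2)
    # D(rho) = rho * s^2 makes ell_1 = L1 (resp. ell_2 = L2) hold identically
    s2 = s * s
    t = config.t_star
    thr1 = config.a1 * m.p_max if config.threshold_times_pmax else config.a1
    thr2 = config.a2 * m.p_max if config.threshold_times_pmax else config.a2

    def radicand(rho, thr):
        D = rho * s2
        return 4.0 * D * rho * t * t - 4.0 * D * t * math.log(
            thr * (4.0 * math.pi * D * t) ** 1.5 / config.p0
        )

    def residual(rho):
        q1, q2 = radicand(rho, thr1), radicand(rho, thr2)
        if q1 <= 0 or q2 <= 0:
            return np.nan
        return obs.L2 - (math.sqrt(q2) - math.sqrt(q1))

    lo, hi = config.rho_bracket
    grid = list(np.geomspace(lo, hi, 300))
    # radicand_1 <= radicand_2 (a1 > a2), so T1 detectability is binding
    for edge in _detectability_edges(lambda r: radicand(r, thr1), lo, hi):
        grid.extend(edge * (1.0 + d) for d in (1e-9, 1e-7, 1e-5, 1e-3))
        grid.extend(edge * (1.0 - d) for d in (1e-9, 1e-7, 1e-5, 1e-3))
    grid = sorted(r for r in grid if lo <= r <= hi)
    vals = np.array([residual(r) for r in grid])
    roots = []
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            roots.append(brentq(residual, grid[i], grid[i + 1], rtol=1e-13))
    if not roots:
        raise EstimationError(
            f"no root of the age-consistency equation for patient "
            f"{obs.patient_id!r} in rho bracket [{lo:g}, {hi:g}]",
            residual_curve=np.column_stack([grid, vals]),
        )
    rho = float(max(roots))
    D = rho * s2
    k = rho / rho_hat
    c = 2.0 * math.sqrt(rho * D)
    r1s = exponential_phase_radius(D, rho, config.a1, config, m.p_max)
    return ParameterEstimate(
        patient_id=obs.patient_id,
        D=D,
        rho=rho,
        k=k,
        rho_hat=rho_hat,
        c=c,
        tumor_age=config.t_star + (obs.R1 - r1s) / c,
        residual=float(residual(rho)),
        bracket_used=(lo, hi),
    )
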