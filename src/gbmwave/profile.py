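"""Approximate traveling-wave profile of the reduced phase-plane system.

In the co-moving frame, after the large-speed (Canosa) reduction that drops
the 1/c^2 second-derivative terms, the wave obeys the first-order system

    dp/dz = p (rho_hat g(w) - delta(w)),      dw/dz = -p rho_hat g(w),

where ``z`` increases into the tumor and ``rho_hat = rho / k``.  Dividing
the equations gives a single ODE for the profile as a function of the growth
factor,

    dp/dw = delta(w) / (rho_hat g(w)) - 1,

integrated from the wave head (w = 1, p = 0) downward until p returns to
zero at the necrotic plateau level ``w*``.  The z-spans between density
thresholds follow from dz/dw = -1 / (rho_hat p g(w)); multiplied by the
dimensional prefactor 2*sqrt(D*rho)/k they give the widths of the
proliferating rim (ell_1) and the edematous rim (ell_2) that are matched to
MRI-derived radii.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .errors import DomainError, ProfileError
from .kinetics import GrowthDeathModel

__all__ = [
    "DimensionlessProfile",
    "ProfileMetrics",
    "solve_profile",
    "threshold_crossings",
    "width_integrals",
    "f_of_rho_hat",
    "nondimensional_wave_speed",
    "dimensional_width",
    "profile_table",
]

# Lower integration bound for w.  The plateau level w* can be exponentially
# small in rho_hat (w* ~ e^{-(1+rho_hat)} for linear shapes), so the floor
# must sit far below any practically reachable plateau; the integrator takes
# logarithmically many steps to descend, so the cost is negligible.
_W_FLOOR = 1e-40
_HEAD_EPS = 1e-10     # start offset below w = 1


def nondimensional_wave_speed(rho_hat: float) -> float:
    """Minimum (= asymptotic) dimensionless wave speed, c = 2*sqrt(rho_hat).

    The dimensional speed is 2*sqrt(rho*D).
    """
    if not (np.isfinite(rho_hat) and rho_hat > 0):
        raise DomainError(f"rho_hat must be positive, got {rho_hat!r}")
    return 2.0 * np.sqrt(rho_hat)


@dataclass(frozen=True)
class DimensionlessProfile:
    """The trajectory p(w) connecting (p, w) = (0, 1) to (0, w*).

    Attributes
    ----------
    rho_hat : float
        Proliferation-to-death ratio rho/k.
    model : GrowthDeathModel
        Response-function pair used.
    w_star : float
        Growth-factor level of the necrotic plateau behind the wave.
    w_peak : float
        Location of the density maximum, the root of delta(w) = rho_hat g(w).
    p_max : float
        Peak proliferating-cell density of the wave.
    """

    rho_hat: float
    model: GrowthDeathModel
    w_star: float
    w_peak: float
    p_max: float
    _sol: object  # scipy OdeSolution over [w_star-ish, 1]

    def p(self, w):
        """Evaluate the profile density p(w); clipped to be non-negative."""
        w = np.asarray(w, dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise DomainError("w must lie in [0, 1]")
        lo = min(self._sol.t_min, self._sol.t_max)
        hi = max(self._sol.t_min, self._sol.t_max)
        wc = np.clip(w, lo, hi)
        if w.ndim == 0:
            val = float(np.clip(self._sol(float(wc))[0], 0.0, None))
            return 0.0 if (w <= self.w_star or w >= 1.0) else val
        vals = np.clip(self._sol(wc.ravel())[0], 0.0, None).reshape(w.shape)
        vals[(w <= self.w_star) | (w >= 1.0)] = 0.0
        return vals


def solve_profile(
    rho_hat: float,
    model: GrowthDeathModel | None = None,
    tol: float = 1e-11,
) -> DimensionlessProfile:
    """Integrate dp/dw from the wave head down to the necrotic plateau.

    Parameters
    ----------
    rho_hat : float
        Positive ratio rho/k.
    model : GrowthDeathModel, optional
        Defaults to the reference shape pair.
    tol : float
        Relative tolerance of the stiff-capable adaptive integrator.

    Returns
    -------
    DimensionlessProfile

    Raises
    ------
    DomainError
        For non-positive rho_hat.
    ProfileError
        If p never returns to zero above the w-floor (an inadmissible
        response pair with delta(0) = 0 can cause this).
    """
    if not (np.isfinite(rho_hat) and rho_hat > 0):
        raise DomainError(f"rho_hat must be positive, got {rho_hat!r}")
    if model is None:
        model = GrowthDeathModel()
    return _solve_profile_cached(float(rho_hat), model, float(tol))


@lru_cache(maxsize=512)
def _solve_profile_cached(rho_hat, model, tol):
    g, d = model.g, model.delta

    def rhs(w, p):
        return [d(w) / (rho_hat * g(w)) - 1.0]

    def plateau(w, p):  # p returns to zero behind the peak
        return p[0]

    plateau.terminal = True
    plateau.direction = 0

    sol = solve_ivp(
        rhs,
        (1.0 - _HEAD_EPS, _W_FLOOR),
        [_HEAD_EPS],  # p ~ (1 - w) near the head since dp/dw(1) = -1
        method="LSODA",
        rtol=tol,
        atol=tol * 1e-3,
        dense_output=True,
        events=plateau,
    )
    if not sol.success and not len(sol.t_events[0]):
        raise ProfileError(f"profile integration failed: {sol.message}")
    if len(sol.t_events[0]):
        w_star = float(sol.t_events[0][0])
    else:
        raise ProfileError(
            "p(w) never returned to zero above the w-floor; the response "
            "pair must satisfy delta(0) > 0 = g(0)"
        )

    # density peak: unique root of delta(w) = rho_hat * g(w)
    bal = lambda w: d(w) - rho_hat * g(w)
    w_peak = brentq(bal, _W_FLOOR, 1.0 - 1e-12, xtol=1e-14)
    p_max = float(np.clip(sol.sol(w_peak)[0], 0.0, None))
    if not (w_star < w_peak < 1.0) or p_max <= 0:
        raise ProfileError(
            f"degenerate profile: w_star={w_star:.6g}, w_peak={w_peak:.6g}, "
            f"p_max={p_max:.6g}"
        )
    return DimensionlessProfile(
        rho_hat=rho_hat,
        model=model,
        w_star=w_star,
        w_peak=w_peak,
        p_max=p_max,
        _sol=sol.sol,
    )


def threshold_crossings(profile: DimensionlessProfile, a: float) -> tuple[float, float]:
    """Solve p(w) = a * p_max on both sides of the peak.

    Returns
    -------
    (w_in, w_out)
        ``w_in`` is the tumor-core-side crossing in (w*, w_peak); ``w_out``
        the leading-edge-side crossing in (w_peak, 1).
    """
    return (_crossing_inner(profile, a), _crossing_outer(profile, a))


def _check_threshold(a):
    if not (0.0 < a < 1.0):
        raise DomainError(f"threshold fraction must lie in (0, 1), got {a!r}")


def _crossing_inner(profile, a):
    _check_threshold(a)
    target = a * profile.p_max
    f = lambda w: profile._sol(w)[0] - target
    # w* may be exponentially small, so the bracket edge is multiplicative
    lo = profile.w_star * (1.0 + 1e-10) + 1e-300
    return float(brentq(f, lo, profile.w_peak, xtol=1e-300, rtol=1e-14))


def _crossing_outer(profile, a):
    _check_threshold(a)
    target = a * profile.p_max
    f = lambda w: profile._sol(w)[0] - target
    return float(brentq(f, profile.w_peak, 1.0 - _HEAD_EPS, xtol=1e-15))


@dataclass(frozen=True)
class ProfileMetrics:
    """Threshold crossings and dimensionless width integrals of a profile.

    ``I1`` is the z-span of the proliferating rim {p >= a1 p_max};
    ``I2`` the z-span from the rim's leading edge to the a2 p_max crossing
    (the edematous rim).  Dimensional widths are ell_i = 2*sqrt(D*rho)/k * I_i.
    """

    w_a1_in: float
    w_a1_out: float
    w_a2_out: float
    I1: float
    I2: float
    f_ratio: float
    rho_hat: float
    p_max: float
    w_star: float
    w_peak: float


def width_integrals(
    profile: DimensionlessProfile, a1: float = 0.9, a2: float = 0.1
) -> ProfileMetrics:
    """Compute the rim and edema z-spans by adaptive quadrature.

    dz/dw = -1/(rho_hat p g) from the reduced system; both integrals are
    taken over w-intervals strictly inside (w*, 1), so the integrable
    endpoint singularities of z(w) are never crossed.
    """
    if not (0.0 < a2 < a1 < 1.0):
        raise DomainError(f"thresholds must satisfy 0 < a2 < a1 < 1, got a1={a1}, a2={a2}")
    w_a1_in = _crossing_inner(profile, a1)
    w_a1_out = _crossing_outer(profile, a1)
    w_a2_out = _crossing_outer(profile, a2)
    rh, g = profile.rho_hat, profile.model.g

    def integrand(w):
        return 1.0 / (rh * profile._sol(w)[0] * g(w))

    I1, e1 = quad(integrand, w_a1_in, w_a1_out, epsabs=1e-12, epsrel=1e-10, limit=200)
    I2, e2 = quad(integrand, w_a1_out, w_a2_out, epsabs=1e-12, epsrel=1e-10, limit=200)
    if not (np.isfinite(I1) and np.isfinite(I2)) or e1 > 1e-6 * max(I1, 1) or e2 > 1e-6 * max(I2, 1):
        raise ProfileError(
            f"width quadrature did not converge (I1={I1}, err={e1}; I2={I2}, err={e2})"
        )
    return ProfileMetrics(
        w_a1_in=w_a1_in,
        w_a1_out=w_a1_out,
        w_a2_out=w_a2_out,
        I1=float(I1),
        I2=float(I2),
        f_ratio=float(I1 / I2),
        rho_hat=rh,
        p_max=profile.p_max,
        w_star=profile.w_star,
        w_peak=profile.w_peak,
    )


@lru_cache(maxsize=2048)
def _metrics_cached(rho_hat, model, a1, a2, tol):
    return width_integrals(_solve_profile_cached(rho_hat, model, tol), a1, a2)


def profile_metrics(
    rho_hat: float,
    model: GrowthDeathModel | None = None,
    a1: float = 0.9,
    a2: float = 0.1,
    tol: float = 1e-11,
) -> ProfileMetrics:
    """Profile solve + width integrals, memoised across repeated calls."""
    if not (np.isfinite(rho_hat) and rho_hat > 0):
        raise DomainError(f"rho_hat must be positive, got {rho_hat!r}")
    if model is None:
        model = GrowthDeathModel()
    return _metrics_cached(float(rho_hat), model, float(a1), float(a2), float(tol))


def f_of_rho_hat(
    rho_hat: float,
    model: GrowthDeathModel | None = None,
    a1: float = 0.9,
    a2: float = 0.1,
) -> float:
    """Identifiability ratio f(rho_hat) = I1/I2 = ell_1/ell_2.

    Deterministic for fixed inputs; depends only on rho_hat, the response
    shapes and the two imaging thresholds, which is what makes the width
    ratio L1/L2 invert uniquely for rho_hat when f is monotone.
    """
    return profile_metrics(rho_hat, model, a1, a2).f_ratio


def dimensional_width(I: float, D: float, rho: float, k: float) -> float:
    """Convert a dimensionless z-span into a width in mm.

    ell = 2*sqrt(D*rho)/k * I, the characteristic length sqrt(D/k) times the
    nondimensional front displacement c_hat * I with c_hat = 2*sqrt(rho/k).
    """
    return 2.0 * np.sqrt(D * rho) / k * I


def profile_table(profile: DimensionlessProfile, n: int = 400) -> pd.DataFrame:
    """Dense (w, p, z) table for export/plotting.

    z is measured from the density peak (z = 0 at w_peak, increasing into
    the tumor core); the grid avoids the endpoints where z diverges
    logarithmically.
    """
    span = 1.0 - profile.w_star
    w = np.linspace(profile.w_star + 1e-4 * span, 1.0 - 1e-4 * span, n)
    p = profile.p(w)
    rh, g = profile.rho_hat, profile.model.g
    integrand = lambda x: 1.0 / (rh * profile._sol(x)[0] * g(x))
    z = np.empty_like(w)
    for i, wi in enumerate(w):
        lo, hi = sorted((wi, profile.w_peak))
        val, _ = quad(integrand, lo, hi, epsabs=1e-10, epsrel=1e-8, limit=200)
        z[i] = val if wi < profile.w_peak else -val
    return pd.DataFrame({"w": w, "p": p, "z": z})
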