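"""Method-of-lines solver for the 1-D cross-diffusion growth system.

Nondimensional form (characteristic length sqrt(D/k), time 1/k):

    p_t = [ (p/(p+q)) (p+q)_x ]_x + rho_hat g(w) p - delta(w) p,
    q_t = [ (q/(p+q)) (p+q)_x ]_x + delta(w) p,          w = 1 - p - q.

Both populations share the total-density gradient as the migratory drive,
split by their local fractions (contact-inhibited movement); death converts
p into q, so p + q is changed by birth only.  The solver uses a conservative
second-order flux discretization on a uniform grid with no-flux boundaries
and an adaptive explicit Runge-Kutta integrator; the vacuum region ahead of
the front is regularised by p/(p+q+eps).

Used to validate the phase-plane approximation: measured front speed against
2 sqrt(rho_hat), and measured p_max, L1, L2 against the profile module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, MeasurementError, SolverError
from .kinetics import GrowthDeathModel

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "simulate",
    "measure_wave",
    "comparison_grid",
]

_EPS_VACUUM = 1e-12


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of one nondimensional simulation.

    For a dimensional run construct with ``from_dimensional``; outputs are
    rescaled back by the caller using the returned scales.
    """

    rho_hat: float
    model: GrowthDeathModel = field(default_factory=GrowthDeathModel)
    domain_length: float = 200.0
    n_cells: int = 2000
    t_end: float = 40.0
    n_samples: int = 81
    rtol: float = 1e-8
    atol: float = 1e-13
    initial_amplitude: float = 0.05
    initial_width: float = 1.0

    def __post_init__(self):
        if not self.rho_hat > 0:
            raise DomainError("rho_hat must be positive")
        if self.n_cells < 100:
            raise DomainError("n_cells must be at least 100")
        if not (self.domain_length > 0 and self.t_end > 0):
            raise DomainError("domain_length and t_end must be positive")
        if not (0 < self.initial_amplitude <= 1):
            raise DomainError("initial amplitude must lie in (0, 1]")

    @classmethod
    def from_dimensional(cls, D: float, rho: float, k: float, t_end_days: float, **kw):
        """Build a nondimensional spec from dimensional rates.

        Lengths scale by sqrt(D/k) mm, times by 1/k days; ``t_end_days`` is
        converted accordingly.
        """
        if not (D > 0 and rho > 0 and k > 0):
            raise DomainError("D, rho, k must be positive")
        return cls(rho_hat=rho / k, t_end=t_end_days * k, **kw)


@dataclass
class SimulationResult:
    """Space-time fields and (optional) wave measurements."""

    spec: SimulationSpec
    x: np.ndarray          # cell centres
    times: np.ndarray
    p: np.ndarray          # (n_times, n_cells)
    q: np.ndarray
    front_positions: np.ndarray | None = None
    measured_speed: float | None = None
    measured_pmax: float | None = None
    measured_L1: float | None = None
    measured_L2: float | None = None

    @property
    def total(self) -> np.ndarray:
        return self.p + self.q


def _rhs_factory(spec: SimulationSpec, g, delta, dx):
    rho_hat = spec.rho_hat
    n = spec.n_cells

    def rhs(t, y):
        p = y[:n]
        q = y[n:]
        tot = p + q
        w = np.clip(1.0 - tot, 0.0, 1.0)
        # face fluxes of the total-density gradient, split by fractions
        grad = np.diff(tot) / dx
        denom = tot[:-1] + tot[1:] + _EPS_VACUUM
        flux_p = (p[:-1] + p[1:]) / denom * grad
        flux_q = (q[:-1] + q[1:]) / denom * grad
        div_p = np.empty(n)
        div_q = np.empty(n)
        div_p[0] = flux_p[0] / dx
        div_p[-1] = -flux_p[-1] / dx
        div_p[1:-1] = np.diff(flux_p) / dx
        div_q[0] = flux_q[0] / dx
        div_q[-1] = -flux_q[-1] / dx
        div_q[1:-1] = np.diff(flux_q) / dx
        # reactions act on the non-negative part: tiny solver-level
        # undershoots ahead of the front must not be amplified by growth
        p_pos = np.maximum(p, 0.0)
        death = delta(w) * p_pos
        dp = div_p + rho_hat * g(w) * p_pos - death
        dq = div_q + death
        return np.concatenate([dp, dq])

    return rhs


def simulate(
    spec: SimulationSpec,
    g=None,
    delta=None,
    positivity_tol: float = 1e-6,
) -> SimulationResult:
    """Run the cross-diffusion system and return sampled fields.

    ``g``/``delta`` default to the spec's model responses; experiments may
    override them with arbitrary callables (e.g. delta = 0 collapses the
    system to Fisher-KPP when q starts empty).

    Raises SolverError if densities leave [0, 1 + tol] (positivity under
    cross-diffusion is conjectural and is reported, never clipped).
    """
    g = g if g is not None else spec.model.g
    delta = delta if delta is not None else spec.model.delta
    dx = spec.domain_length / spec.n_cells
    x = (np.arange(spec.n_cells) + 0.5) * dx
    p0 = spec.initial_amplitude * np.exp(-((x / spec.initial_width) ** 2))
    q0 = np.zeros_like(p0)
    times = np.linspace(0.0, spec.t_end, spec.n_samples)
    sol = solve_ivp(
        _rhs_factory(spec, g, delta, dx),
        (0.0, spec.t_end),
        np.concatenate([p0, q0]),
        method="RK45",
        t_eval=times,
        rtol=spec.rtol,
        atol=spec.atol,
    )
    if not sol.success:
        raise SolverError(f"time integration failed: {sol.message}")
    p = sol.y[: spec.n_cells].T.copy()
    q = sol.y[spec.n_cells :].T.copy()
    if p.min() < -positivity_tol or q.min() < -positivity_tol:
        raise SolverError(
            f"negative densities beyond tolerance (min p={p.min():.3g}, "
            f"min q={q.min():.3g})"
        )
    if (p + q).max() > 1.0 + positivity_tol:
        raise SolverError(f"total density exceeds carrying capacity: {(p+q).max():.6g}")
    return SimulationResult(spec=spec, x=x, times=times, p=p, q=q)


def _outer_crossing(x, y, level):
    """Outermost x where y crosses `level`, linearly interpolated."""
    above = y >= level
    if not above.any():
        return None
    i = np.flatnonzero(above)[-1]
    if i == len(y) - 1:
        return float(x[-1])
    x0, x1 = x[i], x[i + 1]
    y0, y1 = y[i], y[i + 1]
    return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def _inner_crossing(x, y, level, i_peak):
    """First upward crossing of `level` left of the peak."""
    seg = y[: i_peak + 1]
    below = seg < level
    if not below.any():
        return float(x[0])
    i = np.flatnonzero(below)[-1]
    x0, x1 = x[i], x[i + 1]
    y0, y1 = y[i], y[i + 1]
    return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def measure_wave(
    result: SimulationResult,
    level: float | None = None,
    fit_window: float = 0.4,
    a1: float = 0.9,
    a2: float = 0.1,
):
    """Measure front speed and profile widths; annotates ``result``.

    Front position = outermost point where p + q crosses ``level`` (default
    a2 times the final peak density); speed = least-squares slope over the
    last ``fit_window`` fraction of sample times.  L1 is the width of
    {p >= a1 pmax} in the final profile, L2 the distance from the outer
    a1-crossing to the outer a2-crossing of p.

    Returns (speed, pmax, L1, L2).
    """
    if not (0 < fit_window <= 1):
        raise DomainError("fit_window must be a fraction in (0, 1]")
    p_final = result.p[-1]
    q_final = result.q[-1]
    pmax = float(p_final.max())
    if level is None:
        level = a2 * pmax
    tot = result.p + result.q
    fronts = np.array(
        [_outer_crossing(result.x, tot[i], level) or np.nan for i in range(len(result.times))]
    )
    dx = result.x[1] - result.x[0]
    x_max = result.x[-1]
    if np.nanmax(fronts) > x_max - 5 * dx:
        raise MeasurementError("front reached the far boundary during the run")
    i0 = int(np.ceil((1.0 - fit_window) * (len(result.times) - 1)))
    tt, ff = result.times[i0:], fronts[i0:]
    ok = np.isfinite(ff)
    if ok.sum() < 3:
        raise MeasurementError("too few valid front positions in the fit window")
    speed = float(np.polyfit(tt[ok], ff[ok], 1)[0])

    i_peak = int(np.argmax(p_final))
    out1 = _outer_crossing(result.x, p_final, a1 * pmax)
    in1 = _inner_crossing(result.x, p_final, a1 * pmax, i_peak)
    out2 = _outer_crossing(result.x, p_final, a2 * pmax)
    if out1 is None or out2 is None:
        raise MeasurementError("threshold crossing not found in final profile")
    L1 = out1 - in1
    L2 = out2 - out1
    result.front_positions = fronts
    result.measured_speed = speed
    result.measured_pmax = pmax
    result.measured_L1 = L1
    result.measured_L2 = L2
    return speed, pmax, L1, L2


def comparison_grid(
    rho_hats,
    model: GrowthDeathModel | None = None,
    a1: float = 0.9,
    a2: float = 0.1,
    dx: float = 0.1,
    rtol: float = 1e-7,
    settle_time: float = 10.0,
    travel_distance: float = 60.0,
):
    """Approximation-vs-simulation sweep over rho_hat.

    For each rho_hat the domain and horizon are scaled with the wave speed
    (t_end = settle_time + travel_distance / c) so the front always settles
    and travels the same distance before measurement.  Returns a DataFrame
    with theoretical and measured speed, p_max, L1, L2 (dimensionless).
    """
    import pandas as pd

    from .profile import nondimensional_wave_speed, profile_metrics

    model = model or GrowthDeathModel()
    rows = []
    for rh in rho_hats:
        c = nondimensional_wave_speed(rh)
        t_end = settle_time + travel_distance / c
        length = c * t_end + 30.0
        spec = SimulationSpec(
            rho_hat=float(rh),
            model=model,
            n_cells=int(round(length / dx)),
            domain_length=length,
            t_end=t_end,
            rtol=rtol,
        )
        result = simulate(spec)
        speed, pmax, L1, L2 = measure_wave(result, a1=a1, a2=a2)
        m = profile_metrics(rh, model, a1, a2)
        rows.append(
            {
                "rho_hat": float(rh),
                "speed_theory": c,
                "speed_measured": speed,
                "pmax_approx": m.p_max,
                "pmax_measured": pmax,
                "L1_approx": c * m.I1,
                "L1_measured": L1,
                "L2_approx": c * m.I2,
                "L2_measured": L2,
                "p_min": float(result.p.min()),
                "q_min": float(result.q.min()),
                "total_max": float(result.total.max()),
            }
        )
    return pd.DataFrame(rows)
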