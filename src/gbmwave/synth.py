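"""Forward-modelled synthetic patients for end-to-end testing.

Given ground-truth (D, rho, k) and a tumor age, the generator composes the
same forward relations the estimators invert: the wave-profile widths give
ell_1 and ell_2, the Gaussian point-source solution gives the T1 radius at
the end of the exponential phase, and linear front motion at c = 2 sqrt(rho D)
carries it to the requested age:

    R1 = R*_1 + c (age - t*),   R2 = R1 + ell_2,   R0 = R1 - ell_1,   V = c.

A "pde" generator variant replaces the approximate widths with values
measured from the full cross-diffusion simulation, so estimator accuracy can
be probed against the approximation error itself.

Note on identifiability: the single-scan estimator consumes only (L1, L2),
so it can recover an arbitrary truth only when that truth satisfies the
age-consistency relation ell_2 = R*_2 - R*_1.  ``consistent_death_rate``
solves that relation for k given (D, rho), yielding truths on which the
single-scan round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, EstimationError
from .estimate import (
    ImagingConfig,
    PatientObservation,
    exponential_phase_radius,
)
from .kinetics import GrowthDeathModel
from .pde import SimulationSpec, measure_wave, simulate
from .profile import dimensional_width, profile_metrics

__all__ = ["SyntheticPatient", "generate_observation", "consistent_death_rate", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticPatient:
    """A generated observation together with its generating truth."""

    truth: dict
    config: ImagingConfig
    observation: PatientObservation
    generator: str
    noise_sd: float | None
    seed: int | None


def consistent_death_rate(
    D: float,
    rho: float,
    config: ImagingConfig | None = None,
    model: GrowthDeathModel | None = None,
) -> float:
    """Death rate k making (D, rho, k) exactly invertible by the single scan.

    Solves ell_2(D, rho, k) = R*_2(D, rho) - R*_1(D, rho) for k within the
    configured rho_hat bracket.
    """
    config = config or ImagingConfig()
    model = model or GrowthDeathModel()
    target = exponential_phase_radius(D, rho, config.a2, config) - exponential_phase_radius(
        D, rho, config.a1, config
    )

    def gap(k):
        m = profile_metrics(rho / k, model, config.a1, config.a2)
        return dimensional_width(m.I2, D, rho, k) - target

    lo = rho / config.rho_hat_bracket[1]
    hi = rho / config.rho_hat_bracket[0]
    # the gap is not monotone in k, so scan for sign changes and take the
    # largest-k (smallest rho_hat) crossing
    grid = np.geomspace(lo, hi, 120)
    vals = np.array([gap(x) for x in grid])
    for i in range(len(grid) - 2, -1, -1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            return float(brentq(gap, grid[i], grid[i + 1], rtol=1e-12))
    raise EstimationError(
        f"no consistent k in [{lo:.3g}, {hi:.3g}] for D={D}, rho={rho}"
    )


def generate_observation(
    D: float,
    rho: float,
    k: float,
    tumor_age: float,
    config: ImagingConfig | None = None,
    model: GrowthDeathModel | None = None,
    generator: str = "approximation",
    noise_sd: float | None = None,
    seed: int | None = None,
    patient_id: str = "synthetic",
    on_invalid: str = "error",
    pde_kwargs: dict | None = None,
) -> SyntheticPatient:
    """Forward-model one patient record from known parameters.

    With ``noise_sd`` unset the record is an exact deterministic function of
    the truth; a recorded seed makes noisy draws reproducible.  ``on_invalid``
    controls what happens when additive noise breaks the radius ordering:
    "error" raises, "retry" redraws (up to 100 times) from the same stream.
    """
    config = config or ImagingConfig()
    model = model or GrowthDeathModel()
    if not (D > 0 and rho > 0 and k > 0):
        raise DomainError("truth parameters must be positive")
    if tumor_age <= config.t_star:
        raise DomainError(f"tumor_age must exceed t* = {config.t_star} days")
    if generator not in ("approximation", "pde"):
        raise DomainError(f"generator must be 'approximation' or 'pde', got {generator!r}")

    rho_hat = rho / k
    c = 2.0 * np.sqrt(rho * D)
    m = profile_metrics(rho_hat, model, config.a1, config.a2)
    if generator == "approximation":
        ell1 = dimensional_width(m.I1, D, rho, k)
        ell2 = dimensional_width(m.I2, D, rho, k)
        V = c
    else:
        kw = dict(n_cells=1200, domain_length=120.0, n_samples=61)
        kw.update(pde_kwargs or {})
        t_end = kw.pop("t_end", min(0.85 * kw["domain_length"] / (2 * np.sqrt(rho_hat)), 60.0))
        spec = SimulationSpec(rho_hat=rho_hat, model=model, t_end=t_end, **kw)
        res = simulate(spec)
        speed_hat, _, L1_hat, L2_hat = measure_wave(res, a1=config.a1, a2=config.a2)
        scale = np.sqrt(D / k)  # mm per characteristic length
        ell1, ell2 = scale * L1_hat, scale * L2_hat
        V = np.sqrt(D * k) * speed_hat

    r1_star = exponential_phase_radius(D, rho, config.a1, config, m.p_max)
    R1 = r1_star + c * (tumor_age - config.t_star)
    R2 = R1 + ell2
    R0 = R1 - ell1

    rng = np.random.default_rng(seed)
    attempts = 100 if (noise_sd and on_invalid == "retry") else 1
    last_err = None
    for _ in range(attempts):
        if noise_sd:
            radii = np.array([R0, R1, R2]) + rng.normal(0.0, noise_sd, size=3)
        else:
            radii = np.array([R0, R1, R2])
        try:
            obs = PatientObservation(
                patient_id=patient_id,
                R0=float(radii[0]),
                R1=float(radii[1]),
                R2=float(radii[2]),
                V=float(V),
                velocity_source="R2",
            )
            break
        except DomainError as err:
            last_err = err
    else:
        raise DomainError(f"could not generate ordered radii: {last_err}")

    return SyntheticPatient(
        truth={"D": D, "rho": rho, "k": k, "tumor_age": tumor_age},
        config=config,
        observation=obs,
        generator=generator,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_cohort(
    n: int,
    seed: int,
    config: ImagingConfig | None = None,
    model: GrowthDeathModel | None = None,
    noise_sd: float | None = None,
    generator: str = "approximation",
    D_range: tuple[float, float] = (0.05, 1.3),
    rho_range: tuple[float, float] = (0.15, 0.27),
    rho_hat_range: tuple[float, float] = (0.5, 5.0),
    age_range: tuple[float, float] = (200.0, 500.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort of synthetic patients; returns (patients, truth) frames.

    Parameter ranges bracket the published six-patient estimates: D and
    rho_hat log-uniform, rho and age uniform.  Determined entirely by seed.
    """
    from .errors import UndetectableTumorError

    config = config or ImagingConfig()
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    for i in range(n):
        # resample truths that would be invisible at t* (large D spreads the
        # point source below the detection threshold)
        for _ in range(100):
            D = float(np.exp(rng.uniform(*np.log(D_range))))
            rho = float(rng.uniform(*rho_range))
            rho_hat = float(np.exp(rng.uniform(*np.log(rho_hat_range))))
            k = rho / rho_hat
            age = float(rng.uniform(*age_range))
            try:
                sp = generate_observation(
                    D,
                    rho,
                    k,
                    age,
                    config,
                    model,
                    generator=generator,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                    patient_id=f"synthetic-{i+1:03d}",
                    on_invalid="retry",
                )
                break
            except UndetectableTumorError:
                continue
        else:
            raise UndetectableTumorError(
                "could not draw a detectable truth; check the cohort ranges"
            )
        o = sp.observation
        rows.append(
            {
                "patient_id": o.patient_id,
                "R0_mm": o.R0,
                "R1_mm": o.R1,
                "R2_mm": o.R2,
                "V_mm_per_day": o.V,
                "velocity_source": o.velocity_source,
            }
        )
        truths.append({"patient_id": o.patient_id, **sp.truth})
    return pd.DataFrame(rows), pd.DataFrame(truths)
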