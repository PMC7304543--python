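# gbmwave

Patient-specific growth parameters for glioblastoma multiforme (GBM) from a
single MRI scan.

GBMs typically present as three nested, roughly spherical compartments on
MRI: a necrotic core (radius `R0`), a contrast-enhancing proliferating rim
(`R1`, T1-gadolinium) and surrounding vasogenic edema (`R2`, T2/FLAIR).
`gbmwave` models the tumor as a two-population reaction–diffusion system with
cross diffusion,

```
p_t = ∇·[ D p/(p+q) ∇(p+q) ] + ρ g(w) p − k δ(w) p
q_t = ∇·[ D q/(p+q) ∇(p+q) ] + k δ(w) p,          w = 1 − p − q,
```

where `p` and `q` are proliferating and quiescent (functionally necrotic)
cell densities, `w` is an implicit growth factor, and the birth/death
responses `g`, `δ` come from the beta-CDF family
(`g(w) = B(w; α_g, β_g)`, `δ(w) = 1 − B(w; α_δ, β_δ)`).  The system
propagates as a traveling wave with speed `c = 2√(ρD)`.  A phase-plane
reduction of the wave equations gives the profile ODE
`dp/dw = δ(w)/(ρ̂ g(w)) − 1` with `ρ̂ = ρ/k`, from which the widths of the
proliferating rim (`ℓ1`) and the edematous rim (`ℓ2`) follow as quadratures.
Because the ratio `f(ρ̂) = ℓ1/ℓ2` is a strictly monotone function of `ρ̂`,
the measured widths `L1 = R1−R0` and `L2 = R2−R1` identify `ρ̂` uniquely;
the absolute scale then comes either from a measured front velocity
(two-scan protocol) or from matching tumor-age estimates based on early
exponential growth from a point source (single-scan protocol).  The result
is a patient-specific triple: diffusivity `D` (mm²/day), proliferation rate
`ρ` (1/day) and death rate `k` (1/day).

The package provides

* `kinetics` — beta-CDF response pairs and admissibility checks,
* `profile` — the reduced-system wave profile, width integrals and `f(ρ̂)`,
* `estimate` — the two inversion protocols,
* `pde` — a conservative method-of-lines solver for the full cross-diffusion
  system, used to validate the approximation (speed, peak density, widths),
* `synth` — forward-modelled synthetic patients for testing,
* a `gbmwave` CLI (`estimate`, `simulate`, `validate`, `synth`,
  `export-profile`).

## Worked example

Estimate parameters for a patient with necrotic/enhancing/edema radii of
14.87 / 20.73 / 27.77 mm from one scan:

```python
from gbmwave import PatientObservation, estimate_single_scan

est = estimate_single_scan(PatientObservation("demo", 14.87, 20.73, 27.77))
print(f"D   = {est.D:.4f} mm^2/day")
print(f"rho = {est.rho:.4f} /day")
print(f"k   = {est.k:.4f} /day")
print(f"rho_hat = {est.rho_hat:.3f}, c = {est.c:.3f} mm/day, "
      f"age ~ {est.tumor_age:.0f} days")
```

prints

```
D   = 0.2853 mm^2/day
rho = 0.2102 /day
k   = 0.0602 /day
rho_hat = 3.492, c = 0.490 mm/day, age ~ 88 days
```

i.e. a tumor whose cells divide about every `ln 2/ρ ≈ 3.3` days at abundant
growth factor, become quiescent on a ~12-day timescale in the depleted core,
and whose front advances half a millimetre per day — roughly 90 days after
initiation at imaging.  The same record routed through a CSV works via
`gbmwave estimate --input patients.csv --out estimates.csv`.

The defaults use imaging thresholds `a1 = 0.9`, `a2 = 0.1`, point-source
density `p0 = 0.02` and exponential-phase duration `t* = 60` days, with the
reference response shapes `g = Beta(2,2)` (sigmoidal) and
`δ(w) = (1−w)³` (concave); all are configurable through a JSON config
(`--config`), see `docs/methods.md`.

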