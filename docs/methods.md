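# Methods

## Model

Two cell populations — proliferating `p` and quiescent `q`, with the maximum
total density scaled to 1 — move with a shared contact-inhibited flux: each
population carries a share of the total migratory flux `−D∇(p+q)`
proportional to its local fraction (cross diffusion).  The implicit resource
variable `w = 1 − p − q` ("growth factor") drives a per-capita birth rate
`ρ g(w)` and a quiescence rate `k δ(w)`.  Quiescent cells never re-enter the
cycle, so `k δ(w)` acts as a functional death rate and `q` accumulates into
the necrotic core.  Admissibility requires `g` non-decreasing with
`g(0) = 0`, `g(1) = 1`, and `δ` non-increasing with `δ(0) = 1`, `δ(1) = 0`:
growth dominates in fresh tissue, only death remains in a saturated core.

Both responses are beta CDFs, `g(w) = B(w; α_g, β_g)` and
`δ(w) = 1 − B(w; α_δ, β_δ)`, evaluated through the regularised incomplete
beta function, which pins the endpoint values exactly and covers linear,
sigmoidal and concave shapes with two parameters each.

### Reference shape choice

The package default is `(α_g, β_g, α_δ, β_δ) = (2, 2, 1, 3)`: a sigmoidal
birth response and the concave cubic death response `δ(w) = (1−w)³`.  This
configuration was recovered by inverse fitting: the published six-patient
parameter table implies, per patient, both the ratio `ρ̂ = ρ/k` and the
dimensionless rim/edema width integrals `I_i = L_i·k / (2√(Dρ))`; a
four-parameter fit of the beta shapes to all twelve integral values
converges to (2.00, 1.99, 1.01, 3.03), and rounding to the exact
`(2, 2, 1, 3)` reproduces the published `(D, ρ, k)` to all four printed
decimals for two patients and to ≲2% for the rest (residuals consistent
with the table's rounding).  The sigmoidal pair `(2, 2, 2, 2)`, the linear
pair and concave variants remain available as presets; identifiability
(monotone `f`, below) holds for all of them.

## Wave profile approximation

In the frame of the traveling wave, rescaling the wave coordinate by the
speed and discarding the `1/c²` second-derivative terms (a large-speed
reduction) leaves the first-order system

    dp/dz = p (ρ̂ g(w) − δ(w)),     dw/dz = −p ρ̂ g(w),

whose admissible trajectory leaves `(p, w) = (0, 1)` at the wave head and
terminates at `(0, w*)`, the necrotic plateau.  Dividing the equations gives
`dp/dw = δ/(ρ̂ g) − 1`, integrated from `w = 1 − 1e−10` (with the exact head
slope `dp/dw = −1`) downward by an adaptive stiff-capable integrator
(`LSODA`, rtol `1e−11`) until `p` returns to zero; the plateau `w*` is the
terminal event location.  The density peak `w_peak` is the root of
`δ(w) = ρ̂ g(w)` and `p_max = p(w_peak)`.  Linearising the wave head yields
the minimum speed `c = 2√ρ̂` (dimensionally `2√(ρD)`), which is also the
asymptotic speed; the simulation tests confirm this within a few percent.

Numerical cautions:

* `w*` is exponentially small in `ρ̂` (for linear shapes
  `ln w* ≈ −(1+ρ̂)`), so the integration floor sits at `w = 1e−40` and all
  bracketing near the plateau is multiplicative, never additive.
* Threshold crossings `p(w) = a·p_max` are found by bracketed root-finding
  on either side of the peak.
* The rim and edema z-spans `I1 = ∫ dw/(ρ̂ p g)` over
  `[w_a1_in, w_a1_out]` and `I2` over `[w_a1_out, w_a2_out]` use adaptive
  quadrature (`epsrel 1e−10`); the integrable endpoint singularities of
  `z(w)` at `w → 1` and `w → w*` lie strictly outside these intervals.
  Dimensional widths are `ℓ_i = 2√(Dρ)/k · I_i`.

Orientation: `z` increases into the tumor, `w` falls monotonically from 1
(ahead of the front) to `w*` (core), and the imaging geometry
`R2 > R1 > R0` maps the edema span to the leading-edge side
(`w_a1_out` to `w_a2_out`).

## Estimation protocols

Both protocols first invert `f(ρ̂) = I1/I2 = L1/L2` by Brent root-finding
over a configurable bracket (default `[0.05, 50]`).  `f` is strictly
monotone for every shape preset (verified on a grid by the test suite), so
the inverse is unique; a target outside the attainable range raises an
identifiability error naming that range.

* **Two scans:** with the image-derived velocity `V` taken as the wave
  speed, `ℓ1 = L1` gives `k = V·I1/L1`, then `ρ = ρ̂ k` and
  `D = (V/2)²/ρ`.  This inversion is exact on forward-modelled data for any
  truth.
* **Single scan:** `ℓ1 = L1` expresses `D(ρ) = ρ·(L1/(2ρ̂ I1))²` (a config
  switch `width_equation` selects the `ℓ2 = L2` form instead).  Early
  growth is modelled as exponential from a point source of density `p0`
  until `t*`, with the Gaussian solution
  `p(r,t) = p0 (4πDt)^{-3/2} exp(ρt − r²/(4Dt))`; thresholding at `a_i`
  gives the phase-transition radii
  `R*_i = sqrt(4Dρt*² − 4Dt*·ln(a_i (4πDt*)^{3/2}/p0))`.  Equating the
  tumor ages inferred from `R1` and `R2` reduces (the wave speeds cancel)
  to `R2 − R1 = R*_2 − R*_1`, solved for `ρ` by a sign-change scan over a
  log grid on `[1e−3, 2]` /day followed by Brent refinement.  The tumor age
  is then `t* + (R1 − R*_1)/c`.

The thresholds in `R*_i` use `a_i` literally rather than `a_i·p_max`; this
convention reproduces the published table exactly (the printed `(D, ρ)`
values satisfy `R*_2 − R*_1 = L2` to the printed precision under it) and a
config flag `threshold_times_pmax` switches to the other reading.

Degenerate structure of the age equation: the `R*_1` radicand is positive at
tiny `ρ`, can turn negative on a middle interval (tumor invisible on T1 at
`t*`) and positive again; the physical root may sit just above the upper
detectability edge.  The solver therefore locates the radicand's sign
changes first and inserts grid points just inside the detectable region
before scanning.  If several roots survive, the largest-`ρ` root is
returned — the branch continuous with the published parameterisation.

Identifiability caveat: the single-scan protocol consumes only `(L1, L2)` —
the absolute radii enter the age estimate alone.  It therefore maps a
two-dimensional observation to three parameters using the early-growth
priors `(p0, t*)` for scale, and an arbitrary truth is recovered exactly
only if it satisfies the consistency relation `ℓ2 = R*_2 − R*_1`.
`synth.consistent_death_rate` constructs such truths; round-trip tests use
them.  Real estimates always satisfy the relation by construction.

## Full-system simulation

The nondimensional system (characteristic length `√(D/k)`, time `1/k`) is
discretised on a uniform grid with conservative second-order fluxes: the
face flux of each population is the face-averaged fraction `p/(p+q)` (with a
`1e−12` vacuum regularisation) times the central total-density gradient;
boundaries are no-flux.  Reactions are pointwise and act on the non-negative
part of `p`, so tiny integrator-level undershoots ahead of the front cannot
be amplified by the growth term; undershoots beyond `1e−6` abort the run
rather than being clipped (positivity under cross diffusion is conjectural).
Time stepping is adaptive explicit Runge–Kutta (rtol `1e−8`,
atol `1e−13` — the tight absolute tolerance keeps the vacuum region exactly
clean).  The default seed is `p = 0.05·exp(−x²)`, `q = 0`.

Wave measurement: the front position is the outermost crossing of `p+q`
through `a2` times the final peak density (linear interpolation between
cells); the speed is the least-squares slope over the last 40% of sample
times; `L1`/`L2` are threshold widths of the final `p` profile.  Validation
sweeps scale the horizon and domain with the speed
(`t_end = 10 + 60/c`, length `c·t_end + 30`, `dx = 0.1`), so every run
settles and travels the same distance before measurement; these sizes keep
a ten-point `ρ̂` sweep under a minute while measured speeds sit within
2.5% of `2√ρ̂` (the residual bias is the classical logarithmic front-speed
correction) and grid halving moves the speed by under 1%.

Agreement between the approximation and the simulation (peak density within
5%, rim width within 10%, edema width within 20%, worst at small `ρ̂` where
`1/c²` is not small) is what justifies using the cheap profile inside the
estimators.

## Synthetic patients

The generator forward-composes exactly the relations above:
`R1 = R*_1 + c·(age − t*)`, `R0 = R1 − ℓ1`, `R2 = R1 + ℓ2`, `V = c`.  The
"pde" variant replaces `ℓ1, ℓ2, c` with simulation-measured values, so
estimates on such patients carry the approximation error and are only
envelope-accurate.  Optional noise is additive independent Gaussian on each
radius (the simplest perturbation; no claim of realistic segmentation error
models), with seeded, bit-reproducible draws; draws that break the radius
ordering can be rejected or retried per configuration.  Default cohort
ranges (`D ∈ [0.05, 1.3]` mm²/day log-uniform, `ρ ∈ [0.15, 0.27]` /day,
`ρ̂ ∈ [0.5, 5]` log-uniform, age 200–500 days) bracket the published patient
estimates; truths invisible at `t*` (large `D`, small `ρ`) are resampled.
Synthetic data exercise the estimation pipeline end to end but do not
emulate real segmentation variability, registration error or non-spherical
geometry — passing round trips show self-consistency of the protocols, not
clinical accuracy.

## Defaults and limitations

| parameter | default | meaning |
|---|---|---|
| `a1`, `a2` | 0.9, 0.1 | T1/T2 detection thresholds as fractions of peak `p` |
| `p0` | 0.02 | point-source density seeding the exponential phase |
| `t*` | 60 days | duration of the exponential phase |
| shapes | (2, 2, 1, 3) | reference beta-CDF responses (see above) |
| `ρ̂` bracket | [0.05, 50] | search interval for the ratio inversion |
| `ρ` bracket | [1e−3, 2] /day | search interval for the age equation |

Known limitations: one-dimensional waves (no curvature correction, valid
once the radius is large compared to the front width); point estimates only,
no uncertainty quantification; the single-scan scale rests on the
hypothetical `(p0, t*)` priors; no radial simulation, treatment effects or
MRI processing — radii/volumes are upstream inputs.
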