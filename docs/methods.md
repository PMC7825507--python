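# Methods

`rhizograd` models the accumulation gradient of a single low-molecular-
weight exudate around one cylindrical fine-root segment embedded in
saturated peat, and the resulting equilibrium exudation budget. This
note states the model, its assumptions, the numerical scheme, the
calibration procedure and the sensitivity analysis, and records the
deliberate limitations.

## 1. Model overview

A root segment of radius `r0` (cm) sits at the axis of a radially
symmetric soil domain. The soil is divided into `n` concentric annuli of
equal width `dr` (production grid: `n = 500`, `dr = 0.02` cm, giving a
10 cm potential rhizosphere radius). All quantities are per cm of root
length. Each annulus `i` is homogeneous with volume
`V_i = π(r_out² − r_in²)` and interface area `A_i = 2π·r_out`.

The state evolves by four processes:

1. **Rhizoplane exchange** (innermost annulus only): efflux out of the
   root and, for uncharged solutes, carrier-mediated recapture influx.
2. **Radial diffusion** between adjacent annuli (optionally retarded by
   sorption), plus an optional advective water flux.
3. **Sorption**: instantaneous Langmuir equilibrium between dissolved
   and sorbed phase in each annulus.
4. **Mineralization**: first-order decay of the dissolved phase.

The outer boundary is closed (zero flux); the domain is sized so the
gradient dies out well before the last annulus, and the result flags
(`outer_boundary_clean`) whether that held. The simulation is stepped to
an equilibrium defined by a maximum relative concentration change per
step below `eq_rel_tol` (default `1e−7`).

**Units.** Internally: cm, seconds for stepping, hours for rate
constants, µmol for mass (so concentrations are µmol cm⁻³ ≡ mM).
Reported outputs follow field conventions: concentrations in
nmol cm⁻³, fluxes in nmol cm⁻¹ hr⁻¹, extent in mm. A single conversion
layer (×10³ µmol→nmol, ×10 cm→mm) sits between the solver and the
reported `SimResult` fields.

## 2. Rhizoplane flux laws

For uncharged solutes (sugars, amino acids), with `A = 2π·r0` the root
surface area per cm length and `C` the solution concentration at the
wall:

- passive efflux: `J_out = A·P·(Ccyto − C)` — leakage down the
  cytoplasm-to-soil gradient through a membrane of permeability `P`
  (cm hr⁻¹), from a cytosolic pool `Ccyto` (µmol cm⁻³) held constant
  (the plant replenishes it);
- Michaelis–Menten influx: `J_in = Imax·C/(KI + C)` — proton-coupled
  sugar/amino-acid transporters recapturing exudate.

For organic-acid anions (charge `Z < 0`) efflux follows the
Goldman–Hodgkin–Katz flux equation. With `u = Z·Em·F/(R·T)` (membrane
potential `Em < 0`, so `u > 0` for anions):

```
J_GHK = A·P·u·(Ccyto·e^u − C) / (e^u − 1)
```

which is positive (outward) until the soil concentration reaches the
reversal value `Ccyto·e^u`, and collapses to the passive law as
`u → 0` (verified to 1e−6 relative in the tests). Anions are not
recaptured (`Imax = 0`): re-entry against the negative interior
potential is energetically unfavorable.

Net exudation is `efflux − influx`; recapture efficiency is
`influx/efflux`.

## 3. Depth laws (ombrotrophic bog profile)

All depth dependence enters through five closed-form laws evaluated at
the layer depth `d` (cm); depth is clamped to ≥ 1 cm inside logarithms
and power laws so the surface is well defined. Defaults describe a
northern ombrotrophic bog (Mer Bleue type) profile:

| quantity | law | default constants |
|---|---|---|
| bulk density ρ (g cm⁻³) | `a·d^b` | `a = 0.0107`, `b = 0.567` |
| porosity ε | `(gs − ρ)/gs` | particle density `gs = 1.5` |
| tortuosity τ | `ε^(−m)` (Archie) | `m = 2.3` |
| temperature T (°C) | `x − y·ln d` | `x = 17.8`, `y = 2.12` |
| microbial factor f_mb | `exp(i + j·d)` | `i = 0.0287`, `j = −0.024` |

The Q10 temperature factor is `f_T = q10^(T/10)` with `q10 = 2.3`,
set to 0 in frozen soil (T ≤ 0 °C). All constants live in a
`SoilProfileParams` dataclass and can be replaced for other sites.

## 4. Transport and soil sinks

**Effective diffusion.** `De = D_inf·ε/(τ²·R(C))`, where `D_inf` is the
aqueous diffusivity and `R(C) ≥ 1` the sorption retardation factor,
`R = 1 + (ρ/ε)·dS/dC` with the Langmuir slope
`dS/dC = Smax·Ks/(1 + Ks·C)²` (a secant variant `S(C)/C` is available;
the two agree in the trace limit). Diffusive exchange between annuli
`i` and `i+1` uses the interface area and the center-to-center distance
`dr`; `De` at the interface is evaluated at the mean of the two
concentrations.

**Advection.** An optional radial water flux `v0` (cm³ cm⁻² s⁻¹ at the
root surface, diluted as `v0·r0/r` by cylindrical geometry) represents
transpiration-driven convergence toward the root; it upwinds solute
inward and its mass enters the ledger.

**Sorption.** After each transport step every annulus is restored to
Langmuir equilibrium `S(C) = Smax·Ks·C/(1 + Ks·C)` (g-sorbed per g soil
scaled by `ρ·V_i`) by the exact root of the resulting quadratic —
sorption is treated as fast relative to diffusion.

**Mineralization.** First-order decay of the dissolved phase with
effective rate `k_eff = kd·f_T(d)·f_mb(d)` (hr⁻¹), applied as the exact
exponential decrement `C ← C·exp(−k_eff·dt)` so the step is stable and
positive for any `dt`. With the default profile, `k_eff` at 10 cm is
about 7.7× the value at 80 cm — the driver of deep-soil accumulation.

## 5. Numerical scheme

Time stepping is explicit with `dt = 1 s` by default; `dt` is
automatically reduced to the diffusion stability bound
`0.5·dr²/max(De)` when needed, and a guard raises `StabilityError` if
an unstable step is ever attempted.

Two choices matter for accuracy and were selected after grid-refinement
experiments:

1. **Exponential boundary substep.** Over one substep the innermost
   annulus obeys approximately `dC/dt = (b/V0)·(C∞ − C)` where `b`
   collects the linearized efflux and influx conductances and `C∞` is
   the zero-net-flux concentration. This linear ODE is integrated
   exactly, and the exchanged masses are evaluated at the substep-average
   concentration, so the boundary update is conservative, positive and
   accurate at any `dt`. The boundary substep is applied in two halves
   around the transport update (Strang splitting), making the
   boundary–diffusion splitting error second order in `dt`.

2. **Wall-concentration sampling.** Flux laws must be evaluated at the
   root surface, not at the first annulus center (a first-order error
   of order `q·dr/2` otherwise, amplified when net exudation is a small
   difference of large gross fluxes). The wall value is reconstructed
   log-linearly from the first two annuli, `C_wall = C0·√(C0/C1)`
   (linear fallback when the profile is not decreasing), consistent
   with the near-exponential shape of the true profile. The reported
   rhizoplane concentration is this wall value.

With these choices, halving both `dr` and `dt` from the production
resolution moves every reported equilibrium quantity (rhizoplane
concentration, extent, gross fluxes, net exudation) by less than 1%.

**Reporting.** Equilibrium fluxes are reported from the masses actually
exchanged in the final step (divided by the step length), so the budget
identity `net exudation = mineralization sink` holds to the convergence
residual. A mass ledger (cumulative efflux − influx − mineralized −
advected = dissolved + sorbed) is tracked on every run and must close
to 1e−6 relative; the test suite enforces this throughout.

**Verification oracle.** For pure diffusion + first-order decay with a
constant-conductance boundary, the cylindrical steady state is
`C(r) = B·K0(q·r)` with `q = √(k_eff/De)` and `B` fixed by the flux
balance at the wall (modified Bessel functions). The solver matches
this analytic profile within 2% over the entire resolved gradient.

## 6. Solute parameter sets and validation

`SoluteParams` carries name, class (sugar / amino acid / organic acid),
charge `Z`, `D_inf`, Langmuir `Smax`/`Ks`, `kd`, `Ccyto`, `P`, and the
uptake kinetics `Imax`/`KI`. Class defaults fill the membrane
permeability (organic acids ≫ sugars). A literature-range table
(`PARAM_RANGES`) validates every parameter set on construction and
doubles as the sampling box for the sensitivity analysis; violations
raise a structured error naming the offending field (and CSV row, when
loading a solute table). Built-in fixtures (glucose, sucrose, glycine,
glutamate, malate, citrate) are representative of their class, not
compound-accurate: their unprinted constants are order-of-magnitude
literature values, and glucose is the only compound with enough
published anchors for calibration.

## 7. Calibration

Three measured shallow-soil (10 cm) equilibrium anchors for glucose are
used: gross efflux 2.07320 and recaptured influx 1.431 nmol cm⁻¹ hr⁻¹,
and rhizosphere extent 7.16 mm at the 0.01 nmol cm⁻³ threshold.
`calibrate_glucose` fits, in order:

1. **`r0`** — analytically from the efflux anchor: at the measured
   rhizoplane concentration the passive law gives
   `r0 = J_out/(2π·P·(Ccyto − C))`; since efflux is insensitive to the
   small soil concentration this is done against the anchor directly.
2. **`KI`** — pinned at the geometric mean of the literature range
   (0.002–5.9 µmol cm⁻³); the influx anchor alone cannot separate
   `Imax` from `KI`.
3. **`Imax` and `kd`** — stage A: coarse-grid alternation using an
   analytic `Imax` update and a bracketing root solve for `kd` against
   the extent anchor; stage B: fine-grid multiplicative secant polish
   on the *measured* influx and extent (each iteration rescales `Imax`
   by the influx ratio and `kd` by the squared extent ratio, capped at
   ×2 per step). Calibration raises `CalibrationError` if a parameter
   leaves its literature range or the polish does not converge.

The calibrated values reproduce all three anchors to better than 0.1%.
Calibration takes about one minute on one CPU; no deep-soil information
is used, so the 80 cm run is a genuine prediction.

## 8. Sensitivity analysis

`sobol_design` draws an unscrambled Sobol' low-discrepancy sequence
(the degenerate all-zeros point is skipped) over nine parameters by
default: depth (10–100 cm) plus the eight parameters reported in the
published analysis — `D_inf`, `Smax`, `Ks`, `kd`, `Imax`, `KI` over
their literature ranges, the root water flux `v0`, and the Q10
(2.0–2.7). The cytosol pool `Ccyto` and membrane permeability `P` are
held at the measured sugar-class reference (44.7 µmol cm⁻³,
1.15 × 10⁻⁴ cm hr⁻¹), as in the published analysis; passing explicit
bounds samples them too (they then dominate the output variance and
dilute the depth effect). `run_ensemble` runs each row to equilibrium
on a coarsened grid (250 annuli × 0.04 cm, 60 s steps) and records
rhizoplane concentration, extent and net exudation with a convergence
flag. Advection is off by default (`v0` is carried for the sensitivity
parameter list; the advective transport term must be enabled explicitly
in the numerics/config).

Because the design is an unscrambled deterministic sequence, the
ensemble is bit-for-bit reproducible; random seeds are recorded in run
manifests but do not influence results.

`prcc` computes partial rank correlation coefficients by the standard
residual method (rank-transform, regress out all other parameters from
both the response and the target parameter, correlate residuals); it is
tested against the matrix-inverse partial-correlation oracle and is
invariant under monotone transforms. `depth_regression` reports the
ordinary least-squares slope, p-value and R² of rhizoplane
concentration on depth; `binned_prcc` repeats the PRCC within depth
bins. At n = 1024, depth has a positive, highly significant effect on
rhizoplane concentration with R² ≈ 0.28, and the PRCC
ranking reproduces the published ordering: depth and the influx
kinetics (`KI`, `Imax`) strongest, diffusion and mineralization
moderate, `Q10` and `v0` minor.

## 9. Limitations

- **Single root, radial symmetry.** No inter-root competition, root
  growth, or axial variation; the segment is representative of a
  mid-length fine root.
- **Constant cytosolic pool.** `Ccyto` is held fixed; the model does
  not track plant carbon allocation.
- **Saturated, isothermal layer.** Each run sees one depth's static
  properties; no seasonal temperature or water-table dynamics.
- **Lumped microbial sink.** Mineralization is first order in dissolved
  concentration; no microbial growth, no substrate competition, no
  sorbed-phase decay.
- **Instantaneous sorption.** Kinetic sorption limitation is ignored;
  the retardation factor uses the isotherm slope (or secant) rather
  than a kinetic exchange model.
- **Fixture realism.** Only glucose is anchored to measurements; the
  other fixtures are class-representative. Per-compound output curves
  should be read qualitatively (ordering and depth trends), not
  quantitatively.
- **Closed outer boundary.** Background soil concentration is zero;
  exudate leaving the 10 cm domain is not modeled (flagged if it ever
  reaches the boundary).
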