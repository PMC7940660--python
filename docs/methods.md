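# Methods

## Model

The package treats the longitudinal acoustic-like mode of liquid water
on the length scale of the viscoelastic crossover (wavenumbers
q ≈ 1–3 nm⁻¹, frequencies in the THz range) as a 1-D nonlinear,
damped, thermally forced density wave.  The ingredients:

- **Dispersion.**  ω₀²(q) = k₁q² + k₂q⁴ with k₁, k₂ > 0.  √k₁ is the
  long-wavelength sound speed; the quartic term encodes the positive
  sound dispersion produced by structural (α-)relaxation.  The law is
  meaningful only up to the upper crossover bound q_u (≈3 nm⁻¹ for the
  bundled cases); evaluation beyond it warns.
- **Nonlinearity.**  A cubic term in the free energy with coefficient
  α = ∂²p/∂ρ² = 2c²(β−1)/ρ₀, where β ≈ 3.5 is water's acoustic
  nonlinearity parameter and c the apparent sound velocity ω₀(q*)/q*
  at the crossover wavenumber q*.  Since β grows toward solid-like
  values across the crossover, these α estimates are lower bounds.
- **Damping.**  A longitudinal-viscosity term; its strength enters
  only through the measured damping ratio ν_L′ = 2Γ(q*)/ω₀(q*)
  (0.60 for bulk water, 0.32 for DNA/protein hydration water).
- **Thermal forcing.**  A fluctuating stress δS with variance tied to
  the viscosity and temperature (fluctuation–dissipation); in
  dimensionless variables its correlator is ν_L′² δ(t₁′−t₂′) per grid
  node.
- **Scales.**  x′ = q*x, t′ = ω₀(q*)t, δρ′ = δρ/A*, where
  A* = ρ₀√(k_B T κ_T / V) is the r.m.s. thermal density fluctuation in
  a probe volume V = (1 nm)³ — about 43 kg/m³ at 277 K.

Heat-mode coupling is neglected throughout (isothermal reduction), the
3-D tensor structure of the stress is outside scope, and ω₀²(q) is
never derived from a static structure factor — the dispersion
coefficients always come from fitted dispersion curves.

## Closed-form solitons

The undamped unforced limit is the Boussinesq equation with the
one-soliton family δρ = A sech²((x−vt)/δ), A = −12k₂/(αδ²),
v² = k₁ − 4k₂/δ² (real for δ² ≥ 4k₂/k₁).  Amplitudes are negative —
rarefaction pulses — and velocities strictly subsonic.  The limiting
member δ² = 4k₂/k₁, A = −3k₁/α, v = 0 solves the *damped* equation
exactly and is the reference state for all persistence experiments.
FWHM = 2 arccosh(√2) δ ≈ 1.7627 δ.

The traveling-wave initial velocity field is u′ = v′δρ′ (exact for the
Boussinesq soliton via the continuity equation); the stationary member
starts with u′ = 0.

## Case bundles

| case | medium | k₁ (m²/s²) | k₂ (m⁴/s²) | q* (nm⁻¹) | ω₀(q*) (ps⁻¹) | α (m⁵/kg·s²) | ν_L′ |
|------|--------|-----------|-----------|-----------|----------------|---------------|------|
| I | bulk water ≈278 K (IXS) | 3.9e6 | 4.8e-13 | 2.0 | 4.9 | 3.0e4 | 0.60 |
| II | SPC/E D₂O at density maximum (MD) | 3.2e6 | 7.7e-13 | 2.5 | 6.8 | 3.7e4 | 0.60 |
| III | supercooled water 250 K | 1.8e6 | 1.2e-12 | — | — | — | — |
| hydration | DNA/protein hydration water | as case I | | | | | 0.32 |

q* is a per-case input fixed at the inflection point of the measured
dispersion curve, not auto-detected, and ω₀(q*) is the printed
measured value, not one recomputed from the rounded (k₁, k₂) — the two
differ by ~1.5% and all downstream estimates use the printed value.
A* enters the dimensionless nonlinearity as the rounded 43 kg/m³.
κ_T is not part of the published inputs; the default 4.9e-10 Pa⁻¹ (a
standard value for water near 277 K) reproduces A* ≈ 43 kg/m³ and is
overridable.

Case III is defined by two reference points (c = 1.3 km/s at
q = 0.023 nm⁻¹; 3.5 km/s at 3 nm⁻¹).  The exact 2×2 solve gives
k₁ = 1.69e6, k₂ = 1.17e-12; the literature rounding of the same
estimate is k₁ ≈ 1.8e6, k₂ ≈ 1.2e-12.  The bundle stores both and the
reproduction report flags the k₁ gap rather than forcing agreement.
Similar documented rounding gaps: α′ computes to 0.215 (printed 0.22)
and the case-II stationary width to 0.981 nm (printed 0.97 nm).

## Dispersion fitting

Fits are linear least squares of ω₀² on the regressors (q², q⁴) —
the problem is linear in ω₀²-space, and for two points every variant
interpolates exactly.  A nonlinear ω₀-space fit is available as a
switch.  Negative fitted coefficients are rejected, never clipped: the
law with k₁, k₂ > 0 is the physical model, and data that contradict it
should fail loudly.  I/O uses the literature units (nm⁻¹, ps⁻¹) with
conversion at the boundary; everything internal is SI.

## Numerical scheme

The first-order system

    ∂δρ′/∂t′ = −∂u′/∂x′,
    ∂u′/∂t′  = −∂g′/∂x′ + h′,
    g′ = k₁′δρ′ − k₂′∂²ₓδρ′ + (α′/2)(δρ′)² + ν_L′ ∂δρ′/∂t′

is integrated by a MacCormack predictor/corrector: one-sided
differences forward in the predictor and backward in the corrector (or
vice versa), with the direction alternating every step to avoid
directional bias.  Design choices:

- The mixed term ν_L′∂ₜδρ′ inside the flux is replaced by −ν_L′∂ₓu′
  using the continuity equation exactly, keeping the scheme explicit
  and flux-local; ∂²ₓδρ′ uses central second differences.
- **Forcing.**  hᵢⁿ = ν_L′ ξᵢⁿ/√Δt′ with ξ i.i.d. standard normal over
  nodes and steps, drawn from `np.random.default_rng(seed)`; the same
  realization enters predictor and corrector (Euler–Maruyama
  weighting), so the per-step velocity increment is exactly Δt′·hⁿ.
  Runs replay bit-exactly from (config, seed).  When a run is
  coarsened below the production spacing, `noise_correlation_length`
  pins the per-node variance to ν_L′²·(x_corr/Δx′)/Δt′ — the correct
  coarse-graining of node-independent forcing defined on the
  production lattice (x_corr = 10⁻²).
- **Grid and steps.**  Production lattice: L′ = 120 (60 nm at case-I
  scales), Δx′ = 10⁻² (12001 nodes), Δt′ = 2.5×10⁻⁵.  Stability is
  checked by a von Neumann estimate Δt′·ω_max ≤ 1 with
  ω_max² = k₁′λ + k₂′λ², λ = 4/Δx′² the extreme discrete Laplacian
  eigenvalue; the production pair sits at Δt′·ω_max ≈ 0.57 for case I.
  Violations warn rather than error (marginally unstable settings can
  still be useful for short scans).
- **Boundaries.**  Default: absorbing sponge layers (fields multiplied
  each step by exp(−σ(x)Δt′), σ a cubic ramp up to 4/unit-t′ over
  6 length units, shrunk proportionally on small test domains).
  Alternatives: first-order characteristic outflow on u′ ± √k₁′ δρ′,
  and periodic wrap (used by conservation tests; note the wrap period
  is n·Δx′, one spacing beyond the nominal length).  Reflected energy
  of an outgoing pulse is measured in the test suite (< 1% required)
  rather than assumed.
- The hot loop is compiled with numba; a pure-NumPy single-step
  reference implementation is kept and the two are asserted equal to
  machine precision in the tests (independent-path check).

The scheme is second order: Richardson refinement against the exact
traveling soliton shows error ratios of ~4 per halving of (Δx′, Δt′).
Mass (the integrated density deficit) is conserved to roundoff with
periodic boundaries because every update is a difference of fluxes.

## Diagnostics

Pulse tracking locates the extremum of |δρ′| per snapshot with
parabolic sub-grid refinement, measures the width at half maximum
(converted to δ via /1.7627 when reporting), and fits the velocity as
the least-squares slope of position vs time.  Deviation from a
reference profile is the relative L2 norm over the full domain
(co-moving option for traveling references).  The persistence time is
the first crossing of a deviation threshold, linearly interpolated,
+∞ if never crossed.  The threshold default 0.05 operationalizes
"negligible deviation" and is deliberately config-exposed — nothing in
the underlying model singles out a value.  The DHO line shape
2Γω₀²/((ω²−ω₀²)² + 4Γ²ω²) with Γ = (η_L/2ρ₀)q² serves as the linear
spectral diagnostic.

## Synthetic data

Dispersion "measurements" are ω₀(q) evaluated exactly on an equally
spaced grid and multiplied by (1 + σξ), ξ ~ N(0,1) — multiplicative
noise, because scattering dispersion uncertainties scale with the
frequency; σ defaults to 2%.  This emulates the statistical structure
of IXS/MD dispersion data but none of its systematic effects
(instrument resolution, DHO line-shape fitting bias, correlated
errors), so recovery tests demonstrate estimator correctness, not
robustness to real instrument systematics.  Draws that would produce
ω₀ ≤ 0 are redrawn and counted (never triggered at realistic σ).
Recovery experiments (synthesize → fit, replicated) report bias and
RMSE; at σ = 2% with 200 points the ω₀²-space fit is unbiased to
< 1% (the (1+σξ)² mean shift is σ² ≈ 4×10⁻⁴, far below that).

## Persistence experiments

From the case-I stationary soliton, seeded ensembles integrate the
forced system per damping ratio and record the deviation from the
initial profile.  Two presets:

- **production**: Δx′ = 10⁻², Δt′ = 2.5×10⁻⁵ (the full lattice above);
- **reduced**: Δx′ = 2×10⁻², Δt′ = 10⁻⁴, forcing pinned to the
  production spacing — the configuration used by the automated test
  suite, sized so a 2×32-seed experiment to t′ = 9.8 completes in
  ~10 minutes on one CPU.

The reported quantities are the median deviation at t′ = 4.9 (1 ps at
case-I scales) and the median persistence time with bootstrap CIs.
The deviation level is mildly resolution-sensitive (~10% between the
presets) because numerical dissipation trims the highest-frequency
part of the forced band; the reduced preset's deterministic drift
(< 0.1% at t′ = 4.9) is negligible against the stochastic signal.
With the 2 ps window, the hydration-water ensemble (ν_L′ = 0.32)
typically never crosses the 0.05 threshold, so its median persistence
is +∞ and the bulk/hydration ratio is reported as a lower bound; the
ordering itself is unambiguous.

## Known limitations

- The node-independent forcing has no continuum limit (its spatial
  density is tied to the lattice); this follows the source's stated
  correlator.  The `noise_correlation_length` option makes the
  physical forcing density explicit and grid-independent.
- 1-D only; the 3-D stress tensor, shear modes and heat-mode coupling
  are out of scope.
- Soliton interactions and n-soliton solutions are not implemented.
- The sponge layer's absorption profile is tuned for the dispersive
  wave speeds of the water cases (√k₁′ ≈ 0.66–0.81); strongly
  different coefficient sets may need a wider layer.
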