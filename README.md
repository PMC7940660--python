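# aquasoliton

Soliton-like terahertz density pulses in liquid water at the
viscoelastic crossover: dispersion-curve fitting, closed-form sech²
soliton families, and a stochastic nonlinear-wave solver that tests
whether those pulses survive thermal forcing.

## The problem

Water shows transient nanometre-sized low/high-density regions on
sub-picosecond time scales.  On the wavenumber range of the
viscoelastic crossover (q ≈ 1–3 nm⁻¹), the longitudinal acoustic-like
mode disperses as

```
ω₀²(q) = k₁ q² + k₂ q⁴          (valid up to q_u ≈ 3 nm⁻¹)
```

— the positive sound dispersion caused by structural relaxation.
Combining this dispersive stiffening with finite-amplitude
nonlinearity, the 1-D density dynamics reduce to a damped, thermally
forced Boussinesq equation in dimensionless form,

```
∂²δρ′/∂t′² − k₁′ ∂²δρ′/∂x′² + k₂′ ∂⁴δρ′/∂x′⁴
    − α′ ∂/∂x′(δρ′ ∂δρ′/∂x′) − ν_L′ ∂²/∂x′²(∂δρ′/∂t′) + ∂²δS′/∂x′² = 0,
```

whose undamped limit carries the one-soliton family

```
δρ = A sech²((x − vt)/δ),   A = −12 k₂/(α δ²),   v² = k₁ − 4 k₂/δ²,
```

a subsonic rarefaction pulse.  The narrowest member (δ² = 4k₂/k₁,
v = 0, A = −3k₁/α) remains an exact steady solution *with* damping.
The package estimates all parameters from dispersion data, constructs
these solitons, and integrates the stochastic system (MacCormack
scheme, fluctuation–dissipation forcing, non-reflecting boundaries) to
measure how long the pulses persist under thermal noise — for bulk
water (damping ratio ν_L′ = 0.60) and DNA/protein hydration water
(ν_L′ = 0.32).

Audience: researchers in water/hydration dynamics and nonlinear waves
who want a reproducible, tested implementation of this analysis chain.

## Worked example

```python
from aquasoliton import units
from aquasoliton.soliton import stationary_soliton, delta_from_amplitude, soliton_family
from aquasoliton.synthetic import make_case

case = make_case("I")          # bulk water ~278 K: k1=3.9e6, k2=4.8e-13, alpha=3.0e4
st = stationary_soliton(case.coefficients, case.medium.alpha)
print(f"|A| = {abs(st.A):.0f} kg/m^3, delta = {units.length_to_nm(st.delta):.2f} nm, "
      f"FWHM = {units.length_to_nm(st.fwhm):.2f} nm")

d = delta_from_amplitude(43.0, case.coefficients, case.medium.alpha)
tr = soliton_family(d, case.coefficients, case.medium.alpha)
print(f"thermal-amplitude soliton: delta = {units.length_to_nm(d):.2f} nm, "
      f"v = {tr.v:.0f} m/s")
```

prints

```
|A| = 390 kg/m^3, delta = 0.70 nm, FWHM = 1.24 nm
thermal-amplitude soliton: delta = 2.11 nm, v = 1863 m/s
```

The stationary pulse is a ~0.7 nm-wide rarefaction whose depth
(390 kg/m³) matches the expected density contrast between low- and
high-density local structures of water; the thermal-amplitude pulse
(|A| = 43 kg/m³, the r.m.s. density fluctuation in a 1 nm³ volume) is
~2 nm wide and propagates at ~1.9 km/s, just below the long-wavelength
sound speed √k₁ ≈ 2.0 km/s.

More narrative walk-throughs live in `examples/` (dispersion fitting,
case parameter tables, soliton families, numerical soliton
propagation, thermal-persistence ensembles).  A thin CLI mirrors them:
`aquasoliton {fit,params,soliton,synth,simulate,diagnose,reproduce,experiment}`.

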