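"""Fit the terahertz dispersion law to (noisy) measurement-like data.

Generates a synthetic dispersion curve for bulk water near 278 K with
2% multiplicative noise — the statistical structure of inelastic X-ray
scattering dispersion data — and fits omega0^2(q) = k1 q^2 + k2 q^4.
"""

from aquasoliton import units
from aquasoliton.dispersion import fit_dispersion
from aquasoliton.synthetic import SyntheticDispersionSpec, make_case, synth_dispersion

truth = make_case("I").coefficients
spec = SyntheticDispersionSpec(
    k1=truth.k1, k2=truth.k2,
    q_min=units.q_from_invnm(0.1), q_max=truth.q_max_valid,
    n_points=200, relative_noise=0.02, seed=7,
)
points = synth_dispersion(spec)
coeff = fit_dispersion(points, mode="least_squares")

print(f"true      k1 = {truth.k1:.3e} m^2/s^2   k2 = {truth.k2:.3e} m^4/s^2")
print(f"recovered k1 = {coeff.k1:.3e} m^2/s^2   k2 = {coeff.k2:.3e} m^4/s^2")
print(f"long-wavelength sound speed sqrt(k1) = {coeff.sound_speed:.0f} m/s")
# k1 sets the low-q sound speed; k2 the upward bending of omega0/q
# (positive sound dispersion) across the viscoelastic crossover.
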