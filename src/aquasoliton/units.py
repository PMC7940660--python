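"""Unit conversions and physical constants.

Internally everything is SI: wavenumbers in 1/m, angular frequencies in
rad/s, densities in kg/m^3.  Terahertz-scattering literature quotes
wavenumbers in nm^-1 and frequencies in ps^-1 (rad/ps), so conversion
happens once, at the I/O boundary.
"""

from __future__ import annotations

from scipy.constants import k as BOLTZMANN  # J/K, CODATA

#: multiply a wavenumber in nm^-1 by this to get 1/m
PER_NM = 1.0e9
#: multiply an angular frequency in ps^-1 (rad/ps) by this to get rad/s
PER_PS = 1.0e12
#: metres per nanometre
NM = 1.0e-9


def q_from_invnm(q_invnm: float) -> float:
    """Wavenumber nm^-1 -> 1/m."""
    return q_invnm * PER_NM


def q_to_invnm(q: float) -> float:
    """Wavenumber 1/m -> nm^-1."""
    return q / PER_NM


def omega_from_invps(omega_invps: float) -> float:
    """Angular frequency rad/ps -> rad/s."""
    return omega_invps * PER_PS


def omega_to_invps(omega: float) -> float:
    """Angular frequency rad/s -> rad/ps."""
    return omega / PER_PS


def length_to_nm(x: float) -> float:
    """Length m -> nm."""
    return x / NM
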