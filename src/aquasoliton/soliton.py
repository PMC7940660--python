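"""Closed-form sech^2 soliton solutions of the nonlinear wave model.

The undamped, unforced limit of the density-wave equation,

    rho_tt - k1 rho_xx + k2 rho_xxxx - alpha (rho rho_x)_x = 0,

is the Boussinesq equation, with the one-soliton family

    drho(x, t) = A sech^2((x - v t)/delta),
    A = -12 k2 / (alpha delta^2),      v^2 = k1 - 4 k2 / delta^2,

valid for delta^2 >= 4 k2/k1.  The amplitude is negative: the pulse is
a localized rarefaction.  The velocity is strictly subsonic
(v < sqrt(k1)) and decreases with decreasing width.  At the lower
admissible width, delta^2 = 4 k2/k1, the pulse is stationary with
A = -3 k1/alpha — and that particular profile remains an exact steady
solution even with viscous damping switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dispersion import DispersionCoefficients
from .medium import DimensionlessParameters, dimensionless_velocity

__all__ = [
    "SolitonParameters",
    "ImaginaryVelocityError",
    "PulsePlacementError",
    "soliton_family",
    "stationary_soliton",
    "delta_from_amplitude",
    "fwhm",
    "sample_profile",
    "initial_state",
]

#: FWHM of sech^2(x/delta) in units of delta: sech^2(x/delta) = 1/2 at
#: |x| = arccosh(sqrt(2)) delta.
FWHM_FACTOR = 2.0 * float(np.arccosh(np.sqrt(2.0)))


class ImaginaryVelocityError(ValueError):
    """Requested width/amplitude implies v^2 < 0."""


class PulsePlacementError(ValueError):
    """Initial pulse too close to the domain boundary."""


@dataclass(frozen=True)
class SolitonParameters:
    """A (A, delta, v) triple of the one-soliton family.

    ``A`` is stored negative (rarefaction pulse); ``v`` stores the
    non-negative root of the velocity relation, the propagation
    direction being chosen at profile construction.
    """

    A: float
    delta: float
    v: float

    def __post_init__(self) -> None:
        if self.A >= 0:
            raise ValueError("soliton amplitude must be negative (rarefaction)")
        if self.delta <= 0:
            raise ValueError("width must be positive")
        if self.v < 0:
            raise ValueError("stored velocity is the non-negative root")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the sech^2 profile."""
        return FWHM_FACTOR * self.delta


def soliton_family(
    delta: float, coeff: DispersionCoefficients, alpha: float
) -> SolitonParameters:
    """The soliton with width ``delta``: A = -12 k2/(alpha delta^2), v^2 = k1 - 4 k2/delta^2.

    Raises
    ------
    ImaginaryVelocityError
        If delta^2 < 4 k2/k1 (the message names the minimum admissible
        width).
    """
    if delta <= 0 or alpha <= 0:
        raise ValueError("delta and alpha must be positive")
    delta_min = 2.0 * np.sqrt(coeff.k2 / coeff.k1)
    v2 = coeff.k1 - 4.0 * coeff.k2 / delta**2
    if -1e-12 * coeff.k1 < v2 < 0:  # exactly-stationary width up to roundoff
        v2 = 0.0
    if v2 < 0:
        raise ImaginaryVelocityError(
            f"delta = {delta:.4g} m gives imaginary velocity; the minimum "
            f"admissible width is delta_min = {delta_min:.4g} m"
        )
    A = -12.0 * coeff.k2 / (alpha * delta**2)
    return SolitonParameters(A=A, delta=delta, v=float(np.sqrt(v2)))


def stationary_soliton(coeff: DispersionCoefficients, alpha: float) -> SolitonParameters:
    """The v = 0 member: delta = 2 sqrt(k2/k1), A = -3 k1/alpha.

    This profile is an exact steady solution of the *damped*
    deterministic equation as well, which makes it the reference state
    for the persistence experiments.
    """
    delta = 2.0 * float(np.sqrt(coeff.k2 / coeff.k1))
    return SolitonParameters(A=-3.0 * coeff.k1 / alpha, delta=delta, v=0.0)


def delta_from_amplitude(abs_A: float, coeff: DispersionCoefficients, alpha: float) -> float:
    """Width of the soliton with amplitude magnitude ``abs_A``.

    Inverts A = -12 k2/(alpha delta^2):  delta = sqrt(12 k2/(alpha |A|)).
    Amplitudes above the stationary bound 3 k1/alpha would imply an
    imaginary velocity and are rejected.
    """
    if abs_A <= 0:
        raise ValueError("amplitude magnitude must be positive")
    bound = 3.0 * coeff.k1 / alpha
    if abs_A > bound * (1 + 1e-12):
        raise ImaginaryVelocityError(
            f"|A| = {abs_A:.4g} exceeds the stationary bound 3 k1/alpha = "
            f"{bound:.4g} kg/m^3; no real-velocity soliton exists"
        )
    return float(np.sqrt(12.0 * coeff.k2 / (alpha * abs_A)))


def fwhm(delta: float) -> float:
    """FWHM of A sech^2(x/delta): 2 arccosh(sqrt(2)) delta ~ 1.7627 delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return FWHM_FACTOR * delta


def sample_profile(
    sol: SolitonParameters,
    x: np.ndarray,
    t: float = 0.0,
    x0: float = 0.0,
    direction: int = +1,
) -> np.ndarray:
    """Sample drho(x, t) = A sech^2((x - x0 - direction*v t)/delta).

    The spatial integral of the profile is 2 A delta (the pulse carries
    a finite mass deficit).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    arg = (np.asarray(x, dtype=float) - x0 - direction * sol.v * t) / sol.delta
    return sol.A / np.cosh(arg) ** 2


def initial_state(
    sol: SolitonParameters,
    x_primed: np.ndarray,
    dimless: DimensionlessParameters,
    x0_primed: float | None = None,
    direction: int = +1,
    min_clearance_fwhm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a soliton as a dimensionless (drho', u') field pair.

    The density field is the sech^2 profile in primed units
    (delta' = q* delta, A' = A/A*); the velocity field is the exact
    traveling-wave relation u' = v' drho' that follows from the
    continuity equation for a profile moving rigidly at v'
    (identically zero for the stationary member).

    Parameters
    ----------
    sol
        Soliton in SI units.
    x_primed
        Dimensionless grid coordinates.
    dimless
        Scale set used for the reduction.
    x0_primed
        Pulse centre; defaults to the domain midpoint.
    min_clearance_fwhm
        Minimum distance (in FWHM units) from the centre to either
        boundary; closer placement raises ``PulsePlacementError``.
    """
    x = np.asarray(x_primed, dtype=float)
    if x0_primed is None:
        x0_primed = 0.5 * (x[0] + x[-1])
    delta_p = dimless.q_star * sol.delta
    fwhm_p = FWHM_FACTOR * delta_p
    clearance = min(x0_primed - x[0], x[-1] - x0_primed)
    if clearance < min_clearance_fwhm * fwhm_p:
        raise PulsePlacementError(
            f"pulse centre {x0_primed:.3g} leaves {clearance:.3g} to the "
            f"boundary; need >= {min_clearance_fwhm} FWHM = "
            f"{min_clearance_fwhm * fwhm_p:.3g}"
        )
    A_p = sol.A / dimless.A_star
    v_p = dimensionless_velocity(sol.v, dimless)
    rho = A_p / np.cosh((x - x0_primed) / delta_p) ** 2
    u = float(direction) * v_p * rho
    return rho, u
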