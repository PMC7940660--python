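"""Physical parameters of the medium and their dimensionless reduction.

Collects the dimensional inputs of the nonlinear wave model — density,
temperature, acoustic nonlinearity, compressibility, damping — and maps
them onto the dimensionless coefficients (k1', k2', alpha', nu_L') of
the rescaled equation of motion, using the crossover scales

    x' = q* x,   t' = omega0(q*) t,   drho' = drho / A*.

The nonlinearity coefficient alpha (second density derivative of the
pressure) follows from the acoustic nonlinearity parameter beta via
alpha = 2 c^2 (beta - 1) / rho0, with c the apparent sound velocity at
the crossover.  The characteristic thermal density-fluctuation
amplitude A* follows from the isothermal compressibility: the r.m.s.
relative fluctuation of particle number in a probe volume V is
sqrt(kB T kappa_T / V).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dispersion import CrossoverPoint, DispersionCoefficients
from .units import BOLTZMANN

__all__ = [
    "MediumParameters",
    "DimensionlessParameters",
    "nonlinearity_from_beta",
    "thermal_amplitude",
    "nondimensionalize",
    "redimensionalize_length",
    "redimensionalize_time",
    "redimensionalize_density",
    "redimensionalize_velocity",
]


@dataclass(frozen=True)
class MediumParameters:
    """Dimensional physical inputs for one case.

    Attributes
    ----------
    rho0 : float
        Equilibrium mass density, kg/m^3.
    T : float
        Absolute temperature, K.
    beta : float
        Acoustic nonlinearity parameter (dimensionless, > 1 for
        water-like media; ~3.5 for water at low frequency).
    alpha : float
        Nonlinearity coefficient of the cubic free-energy term,
        m^5/(kg s^2); equal to d^2p/drho^2.
    kappa_T : float
        Isothermal compressibility, 1/Pa.
    A_star : float
        Characteristic thermal density-fluctuation magnitude, kg/m^3.
    damping_ratio : float
        Measured 2*Gamma(q*)/omega0(q*); enters the dimensionless
        system directly as nu_L'.
    """

    rho0: float
    T: float
    beta: float
    alpha: float
    kappa_T: float
    A_star: float
    damping_ratio: float

    def __post_init__(self) -> None:
        for name in ("rho0", "T", "beta", "alpha", "kappa_T", "A_star", "damping_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.beta <= 1:
            raise ValueError("beta must exceed 1 for a water-like medium")

    def eta_L_over_rho0(self, cross: CrossoverPoint) -> float:
        """Kinematic longitudinal viscosity eta_L/rho0 (m^2/s).

        Inverts Gamma(q) = eta_L q^2 / (2 rho0) at the crossover, where
        2 Gamma(q*)/omega0(q*) is the stored damping ratio.
        """
        gamma_star = 0.5 * self.damping_ratio * cross.omega0_star
        return 2.0 * gamma_star / cross.q_star**2


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless model coefficients plus the scales that undo them.

    ``k1p + k2p`` is the squared dimensionless frequency at q = q*; for
    the water cases both are O(1).  ``scales`` is (q*, omega0(q*), A*),
    sufficient to map any primed quantity back to SI.
    """

    k1p: float
    k2p: float
    alphap: float
    nuLp: float
    q_star: float
    omega_star: float
    A_star: float

    def __post_init__(self) -> None:
        for name in ("k1p", "k2p", "alphap", "q_star", "omega_star", "A_star"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nuLp < 0:
            raise ValueError("nuLp must be >= 0")

    def with_damping(self, nuLp: float) -> "DimensionlessParameters":
        """Copy with a different damping ratio (e.g. hydration water)."""
        return replace(self, nuLp=nuLp)


def nonlinearity_from_beta(beta: float, c: float, rho0: float) -> float:
    """Nonlinearity coefficient alpha = 2 c^2 (beta - 1) / rho0.

    Parameters
    ----------
    beta : acoustic nonlinearity parameter, >= 1.
    c : apparent sound velocity at the crossover, m/s.
    rho0 : equilibrium density, kg/m^3.

    Returns
    -------
    float
        alpha = d^2p/drho^2 in m^5/(kg s^2); zero for a linear medium
        (beta = 1).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if not (c > 0 and rho0 > 0):
        raise ValueError("c and rho0 must be positive")
    return 2.0 * c**2 * (beta - 1.0) / rho0


def thermal_amplitude(T: float, kappa_T: float, V: float, rho0: float) -> float:
    """Thermal density-fluctuation magnitude A* = rho0 sqrt(kB T kappa_T / V).

    The r.m.s. fluctuation of the number of molecules in a probe volume
    ``V``, relative to its mean, is sqrt(kB T kappa_T / V); multiplied
    by rho0 it gives the characteristic magnitude of the density
    fluctuation on that volume's length scale.  ``V`` defaults to
    (1 nm)^3 in the case bundles — about the smallest volume meaningful
    outside the local structure around individual molecules.
    """
    if min(T, V, rho0) <= 0 or kappa_T < 0:
        raise ValueError("T, V, rho0 must be positive and kappa_T >= 0")
    return rho0 * float(np.sqrt(BOLTZMANN * T * kappa_T / V))


def nondimensionalize(
    coeff: DispersionCoefficients,
    med: MediumParameters,
    cross: CrossoverPoint,
) -> DimensionlessParameters:
    """Reduce dimensional parameters to the primed model coefficients.

        k1' = q*^2 k1 / omega0(q*)^2       k2' = q*^4 k2 / omega0(q*)^2
        alpha' = A* q*^2 alpha / omega0(q*)^2      nu_L' = 2 Gamma(q*)/omega0(q*)

    ``cross.omega0_star`` should be the measured/printed crossover
    frequency, not one recomputed from rounded fit coefficients: the
    two differ at the few-percent level and all downstream estimates
    use the printed value.
    """
    w2 = cross.omega0_star**2
    return DimensionlessParameters(
        k1p=cross.q_star**2 * coeff.k1 / w2,
        k2p=cross.q_star**4 * coeff.k2 / w2,
        alphap=med.A_star * cross.q_star**2 * med.alpha / w2,
        nuLp=med.damping_ratio,
        q_star=cross.q_star,
        omega_star=cross.omega0_star,
        A_star=med.A_star,
    )


def redimensionalize_length(x_primed: float, dimless: DimensionlessParameters) -> float:
    """x = x'/q* (m)."""
    return x_primed / dimless.q_star


def redimensionalize_time(t_primed: float, dimless: DimensionlessParameters) -> float:
    """t = t'/omega0(q*) (s)."""
    return t_primed / dimless.omega_star


def redimensionalize_density(drho_primed: float, dimless: DimensionlessParameters) -> float:
    """drho = A* drho' (kg/m^3)."""
    return drho_primed * dimless.A_star


def redimensionalize_velocity(v_primed: float, dimless: DimensionlessParameters) -> float:
    """v = v' omega0(q*)/q* (m/s)."""
    return v_primed * dimless.omega_star / dimless.q_star


def dimensionless_velocity(v: float, dimless: DimensionlessParameters) -> float:
    """v' = v q*/omega0(q*)."""
    return v * dimless.q_star / dimless.omega_star
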