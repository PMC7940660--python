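"""Low-wavenumber dispersion law of the terahertz longitudinal acoustic-like mode.

Within the viscoelastic crossover region of liquid water the excitation
frequency of the longitudinal acoustic-like mode is well approximated by

    omega0^2(q) = k1 q^2 + k2 q^4,        q <~ q_u,

with constant coefficients ``k1`` (m^2/s^2, the squared long-wavelength
sound speed) and ``k2`` (m^4/s^2, the positive-sound-dispersion term).
The law has no physical meaning above the upper crossover bound ``q_u``.

This module represents dispersion points and coefficient sets, fits the
law to measured (q, omega0) tables, and derives the apparent sound
velocity c(q) = omega0(q)/q and crossover quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd

from . import units

__all__ = [
    "DispersionPoint",
    "DispersionCoefficients",
    "CrossoverPoint",
    "DegenerateInputError",
    "NonPhysicalFitError",
    "fit_dispersion",
    "omega0",
    "apparent_velocity",
    "read_dispersion_csv",
    "write_dispersion_csv",
]


class DegenerateInputError(ValueError):
    """The fit system is singular (e.g. duplicate wavenumbers)."""


class NonPhysicalFitError(ValueError):
    """The fitted law has a non-positive coefficient."""


@dataclass(frozen=True)
class DispersionPoint:
    """One (wavenumber, excitation frequency) sample of the dispersion curve.

    Parameters
    ----------
    q : float
        Wavenumber in 1/m, strictly positive.
    omega0 : float
        Angular excitation frequency in rad/s, non-negative.
    """

    q: float
    omega0: float

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError(f"wavenumber must be positive, got {self.q}")
        if self.omega0 < 0:
            raise ValueError(f"frequency must be >= 0, got {self.omega0}")

    @classmethod
    def from_literature_units(cls, q_invnm: float, omega0_invps: float) -> "DispersionPoint":
        """Build a point from nm^-1 / ps^-1 values."""
        return cls(units.q_from_invnm(q_invnm), units.omega_from_invps(omega0_invps))


@dataclass(frozen=True)
class DispersionCoefficients:
    """Coefficients of omega0^2(q) = k1 q^2 + k2 q^4.

    Attributes
    ----------
    k1 : float
        m^2/s^2; ``sqrt(k1)`` is the long-wavelength sound speed.
    k2 : float
        m^4/s^2; strength of the positive sound dispersion.
    q_max_valid : float
        Upper validity bound q_u in 1/m.  Evaluating the law above this
        wavenumber triggers a warning: the quartic approximation holds
        only up to the crossover region.
    """

    k1: float
    k2: float
    q_max_valid: float

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise NonPhysicalFitError(f"k1 must be positive, got {self.k1}")
        if not self.k2 > 0:
            raise NonPhysicalFitError(f"k2 must be positive, got {self.k2}")
        if not self.q_max_valid > 0:
            raise ValueError("q_max_valid must be positive")

    @property
    def sound_speed(self) -> float:
        """Long-wavelength (q -> 0) sound speed sqrt(k1), m/s."""
        return float(np.sqrt(self.k1))


@dataclass(frozen=True)
class CrossoverPoint:
    """The characteristic wavenumber of the viscoelastic crossover.

    ``q_star`` is fixed by inspection of the inflection point of the
    measured dispersion curve (it is an input, not auto-detected), and
    ``omega0_star`` is the printed excitation frequency there.  The
    apparent sound velocity is c* = omega0*/q* by definition.
    """

    q_star: float
    omega0_star: float

    def __post_init__(self) -> None:
        if not (self.q_star > 0 and self.omega0_star > 0):
            raise ValueError("crossover point must have positive q*, omega0*")

    @property
    def c_star(self) -> float:
        """Apparent sound velocity at the crossover, m/s."""
        return self.omega0_star / self.q_star

    @classmethod
    def from_literature_units(cls, q_star_invnm: float, omega0_star_invps: float) -> "CrossoverPoint":
        return cls(units.q_from_invnm(q_star_invnm), units.omega_from_invps(omega0_star_invps))


FitMode = Literal["least_squares", "exact_two_point"]


def fit_dispersion(
    points: Iterable[DispersionPoint],
    mode: FitMode = "least_squares",
    space: Literal["omega2", "omega"] = "omega2",
) -> DispersionCoefficients:
    """Fit omega0^2 = k1 q^2 + k2 q^4 to dispersion samples.

    Parameters
    ----------
    points
        At least two samples with distinct wavenumbers (exactly two for
        ``exact_two_point``).
    mode
        ``"least_squares"`` solves the linear regression of omega0^2 on
        the regressors (q^2, q^4); ``"exact_two_point"`` solves the 2x2
        linear system through two reference points exactly.
    space
        ``"omega2"`` (default) fits in squared-frequency space, where the
        problem is linear; ``"omega"`` performs a nonlinear fit of omega0
        itself.  For two points both choices interpolate exactly.

    Returns
    -------
    DispersionCoefficients
        Fitted coefficients; ``q_max_valid`` is the largest input q.

    Raises
    ------
    DegenerateInputError
        Fewer than two distinct wavenumbers, or a singular system.
    NonPhysicalFitError
        A fitted coefficient is not strictly positive.
    """
    pts = list(points)
    q = np.array([p.q for p in pts], dtype=float)
    w = np.array([p.omega0 for p in pts], dtype=float)
    if len(pts) < 2 or np.unique(q).size < 2:
        raise DegenerateInputError("need at least two points with distinct q")

    # Condition the system by rescaling q and omega to O(1).
    qs, ws = q.max(), max(w.max(), 1.0)
    X = np.column_stack([(q / qs) ** 2, (q / qs) ** 4])
    y = (w / ws) ** 2

    if mode == "exact_two_point":
        if len(pts) != 2:
            raise DegenerateInputError("exact_two_point requires exactly 2 points")
        try:
            beta = np.linalg.solve(X, y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - dup q caught above
            raise DegenerateInputError("singular two-point system") from exc
    elif mode == "least_squares":
        if space == "omega2":
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            from scipy.optimize import least_squares as _lsq

            beta0, *_ = np.linalg.lstsq(X, y, rcond=None)

            def resid(b):
                m = X @ b
                return np.sqrt(np.clip(m, 0.0, None)) - w / ws

            beta = _lsq(resid, np.clip(beta0, 1e-12, None)).x
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    k1 = float(beta[0]) * ws**2 / qs**2
    k2 = float(beta[1]) * ws**2 / qs**4
    if k1 <= 0 or k2 <= 0:
        raise NonPhysicalFitError(
            f"fitted coefficients must be positive (k1={k1:.3g}, k2={k2:.3g}); "
            "the data do not support the positive-dispersion law"
        )
    return DispersionCoefficients(k1=k1, k2=k2, q_max_valid=float(q.max()))


def omega0(q: Union[float, np.ndarray], coeff: DispersionCoefficients) -> Union[float, np.ndarray]:
    """Evaluate omega0(q) = sqrt(k1 q^2 + k2 q^4), rad/s.

    Warns when evaluated beyond ``coeff.q_max_valid``, where the quartic
    law loses physical meaning.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("wavenumber must be >= 0")
    if np.any(q > coeff.q_max_valid * (1 + 1e-12)):
        warnings.warn(
            f"evaluating dispersion law beyond its validity bound "
            f"q_u = {coeff.q_max_valid:.3g} 1/m",
            stacklevel=2,
        )
    out = np.sqrt(coeff.k1 * q**2 + coeff.k2 * q**4)
    return float(out) if out.ndim == 0 else out


def apparent_velocity(
    q: Union[float, np.ndarray],
    coeff_or_omega0: Union[DispersionCoefficients, float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Apparent sound velocity c(q) = omega0(q)/q, m/s.

    Accepts either fitted coefficients (the frequency is evaluated from
    the law) or an already-known omega0 value, e.g. the printed one.
    Strictly increasing in q when k2 > 0: the upward bending of c(q)
    above sqrt(k1) is the positive sound dispersion.
    """
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0):
        raise ValueError("apparent velocity requires q > 0")
    if isinstance(coeff_or_omega0, DispersionCoefficients):
        w = omega0(qa, coeff_or_omega0)
    else:
        w = np.asarray(coeff_or_omega0, dtype=float)
    out = w / qa
    return float(out) if np.ndim(out) == 0 else out


def read_dispersion_csv(path: Union[str, Path]) -> list[DispersionPoint]:
    """Read a dispersion table with columns ``q_invnm, omega0_invps``."""
    df = pd.read_csv(path)
    missing = {"q_invnm", "omega0_invps"} - set(df.columns)
    if missing:
        raise ValueError(f"dispersion CSV missing columns: {sorted(missing)}")
    return [
        DispersionPoint.from_literature_units(row.q_invnm, row.omega0_invps)
        for row in df.itertuples()
    ]


def write_dispersion_csv(points: Sequence[DispersionPoint], path: Union[str, Path]) -> None:
    """Write points as a ``q_invnm, omega0_invps`` table."""
    df = pd.DataFrame(
        {
            "q_invnm": [units.q_to_invnm(p.q) for p in points],
            "omega0_invps": [units.omega_to_invps(p.omega0) for p in points],
        }
    )
    df.to_csv(path, index=False)
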