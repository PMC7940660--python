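"""End-to-end orchestration: closed-form reproduction and noise experiments.

:func:`reproduce` regenerates, purely from the printed case inputs,
every closed-form estimate of the analysis — stationary and
thermal-amplitude soliton parameters, dimensionless coefficients, the
thermal fluctuation magnitude, and the supercooled two-point fit — and
tabulates them against the source values, flagging the documented
rounding discrepancies.

:func:`persistence_experiment` runs seeded ensembles of the stochastic
solver from the stationary soliton and summarizes how long the profile
persists (deviation below threshold) for different damping ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import units
from .diagnostics import deviation, persistence_time
from .medium import thermal_amplitude
from .soliton import delta_from_amplitude, fwhm, initial_state, soliton_family, stationary_soliton
from .solver import FieldState, Grid1D, SolverConfig, simulate
from .synthetic import A_STAR_PRINTED, PROBE_VOLUME, make_case

__all__ = [
    "ReproductionReport",
    "PersistencePreset",
    "PRESET_PRODUCTION",
    "PRESET_REDUCED",
    "reproduce",
    "persistence_experiment",
]

# source values the report compares against: (case, quantity) -> value
_PRINTED = {
    ("I", "A_stationary_e2_kg_m3"): 3.9,
    ("I", "delta_stationary_nm"): 0.70,
    ("I", "fwhm_stationary_nm"): 1.2,
    ("I", "delta_thermal_nm"): 2.1,
    ("I", "fwhm_thermal_nm"): 3.7,
    ("I", "v_thermal_e3_m_s"): 1.9,
    ("I", "k1p"): 0.65,
    ("I", "k2p"): 0.32,
    ("I", "alphap"): 0.22,
    ("I", "alpha_e4"): 3.0,
    ("I", "A_star_kg_m3"): 43.0,
    ("II", "A_stationary_e2_kg_m3"): 2.6,
    ("II", "delta_stationary_nm"): 0.97,
    ("II", "fwhm_stationary_nm"): 1.7,
    ("II", "delta_thermal_nm"): 2.4,
    ("II", "fwhm_thermal_nm"): 4.2,
    ("II", "v_thermal_e3_m_s"): 1.6,
    ("II", "k1p"): 0.44,
    ("II", "k2p"): 0.65,
    ("II", "alphap"): 0.22,
    ("II", "alpha_e4"): 3.7,
    ("II", "A_star_kg_m3"): 43.0,
    ("III", "k1_twopoint_e6"): 1.8,
    ("III", "k2_twopoint_e-12"): 1.2,
    ("III", "delta_stationary_nm"): 1.6,
}
# quantities where the computed chain is known to disagree with the
# printed rounding (documented, not forced to agree)
_KNOWN_ROUNDING = {
    ("I", "alphap"), ("II", "alphap"), ("II", "delta_stationary_nm"),
    ("III", "k1_twopoint_e6"),
}


@dataclass
class ReproductionReport:
    """Closed-form estimates computed here, next to the source values."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def value(self, case: str, quantity: str) -> float:
        sel = self.table[(self.table.case == case) & (self.table.quantity == quantity)]
        if sel.empty:
            raise KeyError((case, quantity))
        return float(sel.computed.iloc[0])


def _rows_for_case(label: str) -> list[dict]:
    rows = []

    def add(case, quantity, computed, formula):
        printed = _PRINTED.get((case, quantity))
        rows.append(
            dict(
                case=case,
                quantity=quantity,
                computed=computed,
                printed=printed,
                rel_diff=(None if printed is None else computed / printed - 1.0),
                known_rounding_gap=(case, quantity) in _KNOWN_ROUNDING,
                formula=formula,
            )
        )

    if label == "III":
        b = make_case("III")
        f = b.fitted_coefficients
        add("III", "k1_twopoint_e6", f.k1 / 1e6,
            "exact 2x2 solve of omega0^2=k1 q^2+k2 q^4 through (0.023 nm^-1, 1.3e3 m/s), (3 nm^-1, 3.5e3 m/s)")
        add("III", "k2_twopoint_e-12", f.k2 / 1e-12, "same two-point solve")
        delta = 2.0 * math.sqrt(b.coefficients.k2 / b.coefficients.k1)
        add("III", "delta_stationary_nm", units.length_to_nm(delta),
            "2 sqrt(k2/k1) with the printed case-III coefficients")
        return rows

    b = make_case(label)
    coeff, med, dl = b.coefficients, b.medium, b.dimless
    add(label, "alpha_e4", med.alpha / 1e4, "2 c*(q*)^2 (beta-1)/rho0")
    add(label, "A_star_kg_m3",
        thermal_amplitude(med.T, med.kappa_T, PROBE_VOLUME, med.rho0),
        "rho0 sqrt(kB T kappa_T / V), V = 1 nm^3")
    add(label, "k1p", dl.k1p, "q*^2 k1 / omega0(q*)^2")
    add(label, "k2p", dl.k2p, "q*^4 k2 / omega0(q*)^2")
    add(label, "alphap", dl.alphap, "A* q*^2 alpha / omega0(q*)^2, A* = 43")

    st = stationary_soliton(coeff, med.alpha)
    add(label, "A_stationary_e2_kg_m3", abs(st.A) / 1e2, "|A| = 3 k1/alpha")
    add(label, "delta_stationary_nm", units.length_to_nm(st.delta), "delta = 2 sqrt(k2/k1)")
    add(label, "fwhm_stationary_nm", units.length_to_nm(st.fwhm), "2 arccosh(sqrt 2) delta")

    d_th = delta_from_amplitude(A_STAR_PRINTED, coeff, med.alpha)
    fam = soliton_family(d_th, coeff, med.alpha)
    add(label, "delta_thermal_nm", units.length_to_nm(d_th),
        "delta = sqrt(12 k2/(alpha |A|)), |A| = 43 kg/m^3")
    add(label, "fwhm_thermal_nm", units.length_to_nm(fwhm(d_th)), "2 arccosh(sqrt 2) delta")
    add(label, "v_thermal_e3_m_s", fam.v / 1e3, "v = sqrt(k1 - 4 k2/delta^2)")
    return rows


def reproduce(cases: Sequence[str] = ("I", "II", "III")) -> ReproductionReport:
    """Recompute every closed-form estimate for the requested cases.

    Pure arithmetic on the printed inputs: bit-stable across runs and
    essentially instantaneous.  Rows carry the formula used and flag
    the quantities whose computed value is known to differ from the
    source's printed rounding (the report shows both, it never forces
    agreement).
    """
    rows: list[dict] = []
    for label in cases:
        rows.extend(_rows_for_case(label))
    cols = ["case", "quantity", "computed", "printed", "rel_diff",
            "known_rounding_gap", "formula"]
    return ReproductionReport(pd.DataFrame(rows, columns=cols))


@dataclass(frozen=True)
class PersistencePreset:
    """Grid/step sizes and noise handling for a persistence ensemble.

    The reduced preset coarsens the lattice but pins the forcing to the
    production grid spacing through ``noise_correlation_length``, so
    the physical noise density (and hence the deviation level) matches
    the production setup.
    """

    dx: float
    dt: float
    length: float = 120.0
    noise_correlation_length: Optional[float] = None

    def grid(self) -> Grid1D:
        return Grid1D(length=self.length, dx=self.dx)


#: the production lattice of the study
PRESET_PRODUCTION = PersistencePreset(dx=1.0e-2, dt=2.5e-5)
#: coarsened preset for routine testing; noise density pinned to the
#: production spacing
PRESET_REDUCED = PersistencePreset(dx=2.0e-2, dt=1.0e-4, noise_correlation_length=1.0e-2)


def _bootstrap_median_ci(x: np.ndarray, rng: np.random.Generator, n_boot: int = 2000,
                         level: float = 0.95) -> tuple[float, float]:
    meds = np.median(
        x[rng.integers(0, len(x), size=(n_boot, len(x)))], axis=1
    )
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def persistence_experiment(
    case: str = "I",
    nu_values: Sequence[float] = (0.60, 0.32),
    n_seeds: int = 32,
    t_end: float = 4.9,
    t_max: Optional[float] = None,
    threshold: float = 0.05,
    preset: PersistencePreset = PRESET_REDUCED,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Ensembles of noisy runs from the stationary soliton, per damping ratio.

    For each nu_L' value, ``n_seeds`` independent forcing realizations
    are integrated to ``t_max`` (default: 2x ``t_end``); the relative
    L2 deviation of drho' from the initial profile is recorded.
    Reported per nu: the median deviation at ``t_end`` and the median
    persistence time (first threshold crossing, inf if never), with
    bootstrap 95% confidence intervals on the median persistence.

    Returns a DataFrame with one row per nu value.
    """
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    if t_max is None:
        t_max = 2.0 * t_end
    bundle = make_case(case)
    grid = preset.grid()
    st = stationary_soliton(bundle.coefficients, bundle.medium.alpha)
    rows = []
    rng = np.random.default_rng(master_seed)
    for nu in nu_values:
        dl = bundle.dimless.with_damping(nu)
        rho0, u0 = initial_state(st, grid.positions, dl)
        n_steps = int(round(t_max / preset.dt))
        save_every = max(1, n_steps // 100)
        seeds = np.random.SeedSequence(master_seed).spawn(len(nu_values) * n_seeds)
        devs, ptimes = [], []
        for k in range(n_seeds):
            seed = int(seeds[nu_values.index(nu) * n_seeds + k].generate_state(1)[0] % 2**31)
            cfg = SolverConfig(
                dimless=dl, dt=preset.dt, n_steps=n_steps, save_every=save_every,
                noise_enabled=True, seed=seed,
                noise_correlation_length=preset.noise_correlation_length,
            )
            traj = simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid)
            dev = deviation(traj, rho0)
            devs.append(float(np.interp(t_end, dev.times, dev.rel_l2)))
            ptimes.append(persistence_time(dev, threshold))
        devs = np.array(devs)
        ptimes = np.array(ptimes)
        finite = ptimes[np.isfinite(ptimes)]
        if finite.size == ptimes.size and finite.size > 1:
            lo, hi = _bootstrap_median_ci(ptimes, rng)
        else:
            lo, hi = float("nan"), float("nan")
        rows.append(
            dict(
                nu=nu, n_seeds=n_seeds, t_end=t_end, threshold=threshold,
                median_dev_at_t_end=float(np.median(devs)),
                median_persistence=float(np.median(ptimes)),
                persistence_ci_low=lo, persistence_ci_high=hi,
                frac_never_crossed=float(np.mean(~np.isfinite(ptimes))),
            )
        )
    return pd.DataFrame(rows)
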