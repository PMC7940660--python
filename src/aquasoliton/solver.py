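"""Integration of the dimensionless damped stochastic Boussinesq system.

The model solved here is the 1-D first-order system

    drho'/dt' + du'/dx' = 0
    du'/dt' + dg'/dx' - h' = 0
    g' = k1' rho' - k2' rho'_xx + (alpha'/2) rho'^2 + nu_L' drho'/dt'

on a uniform grid, with the mixed damping term rewritten exactly as
-nu_L' u'_x through the continuity equation.  The forcing h' models the
thermal (fluctuation-dissipation) stress: zero-mean Gaussian noise,
white in time with per-node variance nu_L'^2/dt', independent across
grid nodes.  Time integration is an alternating-direction MacCormack
predictor/corrector (second order in space and time for the smooth
part, Euler-Maruyama weighting for the noise).

Default grid and step sizes are the production lattice of the study:
domain length L' = 120, dx' = 1e-2 (12001 nodes), dt' = 2.5e-5.

The heavy loop lives in a compiled kernel (:mod:`._kernel`); a pure
NumPy single step (:func:`step_maccormack`) is kept as an independent
reference implementation and is checked against the kernel in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np

from . import _kernel
from .medium import DimensionlessParameters

__all__ = [
    "Grid1D",
    "SolverConfig",
    "FieldState",
    "ForcingRealization",
    "Trajectory",
    "SolverDivergenceError",
    "flux",
    "make_forcing",
    "step_maccormack",
    "apply_boundary",
    "simulate",
]

_BC_CODES = {
    "periodic": _kernel.BC_PERIODIC,
    "sponge": _kernel.BC_SPONGE,
    "characteristic": _kernel.BC_CHARACTERISTIC,
}


class SolverDivergenceError(RuntimeError):
    """Fields became non-finite during integration."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid on [0, length] in dimensionless units."""

    length: float = 120.0
    dx: float = 1.0e-2

    def __post_init__(self) -> None:
        if self.length <= 0 or self.dx <= 0:
            raise ValueError("length and dx must be positive")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx)) + 1

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)


@dataclass(frozen=True)
class SolverConfig:
    """Everything needed to reproduce a run, except the initial state.

    Attributes
    ----------
    dimless
        Dimensionless model coefficients (k1', k2', alpha', nu_L').
    dt
        Time step; the default is the production value 2.5e-5.
    n_steps, save_every
        Total steps and snapshot cadence.
    noise_enabled
        Toggle for the thermal forcing.
    seed
        Seed for the forcing stream; the same (config, seed) pair
        replays bit-exactly.
    bc
        ``"sponge"`` (default), ``"characteristic"`` or ``"periodic"``.
    sponge_width
        Width of each absorbing layer in *nodes*; ``None`` sizes it to
        cover 6 dimensionless length units.
    sponge_strength
        Peak damping rate (per unit t') of the cubic-ramp taper.
    noise_correlation_length
        Physical spatial correlation length of the forcing.  ``None``
        reproduces the literal node-independent reading (variance
        nu'^2/dt' at whatever dx is in use).  A number ties the noise
        magnitude to a reference length so that coarsened grids carry
        the same physical forcing density: per-node variance is scaled
        by (correlation_length / dx).
    """

    dimless: DimensionlessParameters
    dt: float = 2.5e-5
    n_steps: int = 1000
    save_every: int = 100
    noise_enabled: bool = False
    seed: int = 0
    bc: Literal["sponge", "characteristic", "periodic"] = "sponge"
    sponge_width: Optional[int] = None
    sponge_strength: float = 4.0
    noise_correlation_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 0 or self.save_every <= 0:
            raise ValueError("dt > 0, n_steps >= 0, save_every > 0 required")

    def noise_std(self, dx: float) -> float:
        """Per-node, per-step standard deviation of h'."""
        if not self.noise_enabled or self.dimless.nuLp == 0.0:
            return 0.0
        scale = 1.0
        if self.noise_correlation_length is not None:
            scale = np.sqrt(self.noise_correlation_length / dx)
        return float(self.dimless.nuLp * scale / np.sqrt(self.dt))

    def sponge_nodes(self, grid: Grid1D) -> int:
        if self.sponge_width is not None:
            return self.sponge_width
        # 6 length units on the production lattice, shrinking on small
        # test domains so the layers never collide
        return int(round(min(6.0, grid.length / 8.0) / grid.dx))

    def check_stability(self, grid: Grid1D) -> float:
        """Von Neumann estimate: dt * omega_max for the discrete operator.

        The stiffest discrete mode has Laplacian eigenvalue 4/dx^2, so
        omega_max^2 = k1'(4/dx^2) + k2'(4/dx^2)^2.  Values above ~1
        indicate instability of the explicit scheme and trigger a
        warning.
        """
        lmax = 4.0 / grid.dx**2
        omega_max = np.sqrt(self.dimless.k1p * lmax + self.dimless.k2p * lmax**2)
        cfl = float(self.dt * omega_max)
        if cfl > 1.0:
            warnings.warn(
                f"dt*omega_max = {cfl:.3g} > 1: explicit step likely unstable "
                f"(reduce dt below {1.0 / omega_max:.3g})",
                stacklevel=2,
            )
        return cfl


@dataclass
class FieldState:
    """Discretized (drho', u') pair at one instant."""

    rho: np.ndarray
    u: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.rho.shape != self.u.shape:
            raise ValueError("rho and u must have the same shape")

    def require_finite(self) -> None:
        if not (np.isfinite(self.rho).all() and np.isfinite(self.u).all()):
            raise SolverDivergenceError("non-finite field values")

    def copy(self) -> "FieldState":
        return FieldState(self.rho.copy(), self.u.copy(), self.time)


@dataclass
class ForcingRealization:
    """A stored block of forcing values h'[step, node] with its seed."""

    h: np.ndarray
    seed: int
    dt: float


@dataclass
class Trajectory:
    """Snapshots of a run plus full provenance (config + grid + seed)."""

    times: np.ndarray
    rho: np.ndarray
    u: np.ndarray
    grid: Grid1D
    config: SolverConfig

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def state(self, i: int) -> FieldState:
        return FieldState(self.rho[i], self.u[i], float(self.times[i]))

    def to_hdf5(self, path: Union[str, Path]) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=self.grid.positions)
            f.create_dataset("t", data=self.times)
            f.create_dataset("rho", data=self.rho)
            f.create_dataset("u", data=self.u)
            f.attrs["length"] = self.grid.length
            f.attrs["dx"] = self.grid.dx
            c = self.config
            f.attrs.update(
                dict(
                    dt=c.dt, n_steps=c.n_steps, save_every=c.save_every,
                    noise_enabled=c.noise_enabled, seed=c.seed, bc=c.bc,
                    sponge_strength=c.sponge_strength,
                    k1p=c.dimless.k1p, k2p=c.dimless.k2p,
                    alphap=c.dimless.alphap, nuLp=c.dimless.nuLp,
                    q_star=c.dimless.q_star, omega_star=c.dimless.omega_star,
                    A_star=c.dimless.A_star,
                )
            )

    @classmethod
    def from_hdf5(cls, path: Union[str, Path]) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            a = dict(f.attrs)
            dimless = DimensionlessParameters(
                k1p=float(a["k1p"]), k2p=float(a["k2p"]),
                alphap=float(a["alphap"]), nuLp=float(a["nuLp"]),
                q_star=float(a["q_star"]), omega_star=float(a["omega_star"]),
                A_star=float(a["A_star"]),
            )
            config = SolverConfig(
                dimless=dimless, dt=float(a["dt"]), n_steps=int(a["n_steps"]),
                save_every=int(a["save_every"]),
                noise_enabled=bool(a["noise_enabled"]), seed=int(a["seed"]),
                bc=str(a["bc"]), sponge_strength=float(a["sponge_strength"]),
            )
            grid = Grid1D(length=float(a["length"]), dx=float(a["dx"]))
            return cls(
                times=f["t"][:], rho=f["rho"][:], u=f["u"][:],
                grid=grid, config=config,
            )


def _sponge_multiplier(config: SolverConfig, grid: Grid1D) -> np.ndarray:
    """Per-step field multiplier exp(-sigma(x) dt) of the absorbing layers.

    sigma ramps from 0 at the interior edge of each layer to
    ``sponge_strength`` at the wall with a cubic profile; the smooth
    onset keeps the layer itself from reflecting.
    """
    n = grid.n_nodes
    mult = np.ones(n)
    if config.bc != "sponge":
        return mult
    w = config.sponge_nodes(grid)
    if w >= n // 2:
        raise ValueError("sponge layers overlap: sponge_width too large")
    i = np.arange(w)
    ramp = ((w - i) / w) ** 3
    sigma = config.sponge_strength * ramp
    mult[:w] = np.exp(-sigma * config.dt)
    mult[n - w :] = np.exp(-sigma[::-1] * config.dt)
    return mult


def flux(state: FieldState, config: SolverConfig, grid: Grid1D) -> np.ndarray:
    """The flux g' = k1' rho' - k2' rho'_xx + (alpha'/2) rho'^2 - nu' u'_x.

    Central second differences in the interior; the time derivative in
    the damping term is evaluated as -u'_x via the continuity equation.
    """
    state.require_finite()
    d = config.dimless
    rho, u = state.rho, state.u
    dx = grid.dx
    periodic = config.bc == "periodic"
    if periodic:
        lap = (np.roll(rho, -1) - 2 * rho + np.roll(rho, 1)) / dx**2
        ux = (np.roll(u, -1) - np.roll(u, 1)) / (2 * dx)
    else:
        lap = np.empty_like(rho)
        lap[1:-1] = (rho[2:] - 2 * rho[1:-1] + rho[:-2]) / dx**2
        lap[0] = (rho[2] - 2 * rho[1] + rho[0]) / dx**2
        lap[-1] = (rho[-1] - 2 * rho[-2] + rho[-3]) / dx**2
        ux = np.empty_like(u)
        ux[1:-1] = (u[2:] - u[:-2]) / (2 * dx)
        ux[0] = (u[1] - u[0]) / dx
        ux[-1] = (u[-1] - u[-2]) / dx
    return d.k1p * rho - d.k2p * lap + 0.5 * d.alphap * rho**2 - d.nuLp * ux


def make_forcing(
    config: SolverConfig, grid: Grid1D, n_steps: int, seed: Optional[int] = None
) -> ForcingRealization:
    """Draw a forcing block h'[step, node] for analysis purposes.

    Per-node variance is ``config.noise_std(dx)**2`` (nu'^2/dt' in the
    default node-noise reading); draws are independent across nodes and
    steps.  The integrator draws its own stream inside the compiled
    kernel with the same law.
    """
    if seed is None:
        seed = config.seed
    std = config.noise_std(grid.dx)
    rng = np.random.default_rng(seed)
    h = std * rng.standard_normal((n_steps, grid.n_nodes))
    return ForcingRealization(h=h, seed=seed, dt=config.dt)


def _one_sided(f: np.ndarray, dx: float, forward: bool, periodic: bool) -> np.ndarray:
    out = np.empty_like(f)
    if forward:
        out[:-1] = (f[1:] - f[:-1]) / dx
        out[-1] = (f[0] - f[-1]) / dx if periodic else (f[-1] - f[-2]) / dx
    else:
        out[1:] = (f[1:] - f[:-1]) / dx
        out[0] = (f[0] - f[-1]) / dx if periodic else (f[1] - f[0]) / dx
    return out


def step_maccormack(
    state: FieldState,
    config: SolverConfig,
    grid: Grid1D,
    forcing: Optional[np.ndarray] = None,
    forward_first: bool = True,
) -> FieldState:
    """One MacCormack predictor/corrector step (NumPy reference path).

    The predictor uses one-sided differences in one direction, the
    corrector in the other; production runs alternate ``forward_first``
    each step to avoid directional bias.  The same forcing realization
    enters predictor and corrector (Euler-Maruyama weighting).
    """
    state.require_finite()
    dt, dx = config.dt, grid.dx
    periodic = config.bc == "periodic"
    h = np.zeros_like(state.rho) if forcing is None else forcing

    g = flux(state, config, grid)
    rho_p = state.rho - dt * _one_sided(state.u, dx, forward_first, periodic)
    u_p = state.u - dt * _one_sided(g, dx, forward_first, periodic) + dt * h
    pred = FieldState(rho_p, u_p, state.time + dt)

    g_p = flux(pred, config, grid)
    rho_new = 0.5 * (
        state.rho + rho_p - dt * _one_sided(u_p, dx, not forward_first, periodic)
    )
    u_new = 0.5 * (
        state.u + u_p - dt * _one_sided(g_p, dx, not forward_first, periodic) + dt * h
    )
    new = FieldState(rho_new, u_new, state.time + dt)
    new = apply_boundary(new, config, grid, previous=state)
    if not np.isfinite(new.rho).all():
        raise SolverDivergenceError(f"divergence at t' = {new.time:.6g}")
    return new


def apply_boundary(
    state: FieldState,
    config: SolverConfig,
    grid: Grid1D,
    previous: Optional[FieldState] = None,
) -> FieldState:
    """Apply the configured non-reflecting boundary treatment.

    Sponge mode multiplies both fields by a smooth taper in the
    absorbing layers (interior nodes untouched).  Characteristic mode
    overwrites the two wall nodes with a first-order upwind advection
    of the outgoing Riemann-like variable w = u' -/+ sqrt(k1') rho',
    zeroing the incoming one; it needs the pre-step state.
    """
    if config.bc == "periodic":
        return state
    rho, u = state.rho.copy(), state.u.copy()
    if config.bc == "sponge":
        mult = _sponge_multiplier(config, grid)
        rho *= mult
        u *= mult
    elif config.bc == "characteristic":
        prev = previous if previous is not None else state
        c = np.sqrt(config.dimless.k1p)
        lam = c * config.dt / grid.dx
        wm = (prev.u[0] - c * prev.rho[0]) + lam * (
            (prev.u[1] - c * prev.rho[1]) - (prev.u[0] - c * prev.rho[0])
        )
        rho[0], u[0] = -wm / (2 * c), 0.5 * wm
        wp = (prev.u[-1] + c * prev.rho[-1]) - lam * (
            (prev.u[-1] + c * prev.rho[-1]) - (prev.u[-2] + c * prev.rho[-2])
        )
        rho[-1], u[-1] = wp / (2 * c), 0.5 * wp
    else:
        raise ValueError(f"unknown bc {config.bc!r}")
    return FieldState(rho, u, state.time)


def simulate(initial: FieldState, config: SolverConfig, grid: Grid1D) -> Trajectory:
    """Integrate ``config.n_steps`` steps from ``initial`` (compiled path).

    Snapshots (including the initial state) are taken every
    ``config.save_every`` steps.  The run is bit-exactly reproducible
    from (initial, config, grid): the forcing stream is the plain
    standard-normal sequence of ``np.random.default_rng(config.seed)``
    — the same stream :func:`make_forcing` exposes for analysis.
    """
    initial.require_finite()
    if initial.rho.shape[0] != grid.n_nodes:
        raise ValueError("initial state does not match the grid")
    config.check_stability(grid)

    d = config.dimless
    n = grid.n_nodes
    n_snap = config.n_steps // config.save_every + 1
    out_rho = np.empty((n_snap, n))
    out_u = np.empty((n_snap, n))
    out_t = np.empty(n_snap)
    rho = initial.rho.copy()
    u = initial.u.copy()
    out_rho[0], out_u[0], out_t[0] = rho, u, initial.time
    snap = 1

    noise_std = config.noise_std(grid.dx)
    use_noise = noise_std > 0.0
    rng = np.random.default_rng(config.seed)
    sponge = _sponge_multiplier(config, grid)
    bc_code = _BC_CODES[config.bc]
    zeros = np.zeros((1, n))
    # cap forcing blocks at ~16 MB so memory stays flat on long runs
    chunk_cap = max(1, 2_000_000 // n)

    step = 0
    while step < config.n_steps:
        to_next_save = config.save_every - (step % config.save_every)
        n_chunk = min(to_next_save, chunk_cap, config.n_steps - step)
        if use_noise:
            h_block = noise_std * rng.standard_normal((n_chunk, n))
        else:
            h_block = zeros
        ok = _kernel.run_chunk(
            rho, u, n_chunk, h_block, use_noise, step, config.dt, grid.dx,
            d.k1p, d.k2p, d.alphap, d.nuLp, bc_code, sponge,
        )
        step += n_chunk
        if not ok:
            raise SolverDivergenceError(
                f"fields diverged near step {step} (t' ~ {step * config.dt:.4g}); "
                "check the stability bound via SolverConfig.check_stability"
            )
        if step % config.save_every == 0 and snap < n_snap:
            out_rho[snap], out_u[snap] = rho, u
            out_t[snap] = initial.time + step * config.dt
            snap += 1
    return Trajectory(times=out_t, rho=out_rho, u=out_u, grid=grid, config=config)
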