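"""Explicit 2-D integrator for the stochastic SIRS reaction-diffusion system.

The three fields S, I, R live on a uniform cell-centred grid with mirror
(no-flux) boundaries.  Diffusion uses the 5-point central stencil, time
stepping is forward Euler for S and R and Euler-Maruyama for I, which is
driven by spatiotemporal white noise: per cell and step an independent
Gaussian increment of variance ``2 * C_I * dt``, the lattice form of a
delta-correlated noise of intensity ``D_I = C_I * dx * dy``.

Runs start from the stable endemic equilibrium plus a small seeded uniform
perturbation and integrate either to a fixed final time or until the
infected field stops changing (stationarity), which is how the stationary
Turing patterns are produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import EpidemicParams, SteadyState, reaction_rhs, select_stable_equilibrium

__all__ = [
    "SimConfig",
    "FieldState",
    "SimulationResult",
    "laplacian_no_flux",
    "noise_increments",
    "em_step",
    "run",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of a simulation run.

    Defaults follow the reference setup: a 200x200 grid with unit spacing
    and dt = 0.01.  ``init_amp`` is the amplitude of the uniform initial
    perturbation around the homogeneous equilibrium; ``stationarity_tol``
    stops the run early once the relative L2 change of I per unit time
    falls below it.
    """

    nx: int = 200
    ny: int = 200
    dx: float = 1.0
    dy: float = 1.0
    dt: float = 0.01
    t_end: float = 200.0
    stationarity_tol: float = 1e-6
    seed: int = 0
    init_amp: float = 1e-2
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        for name in ("dx", "dy", "dt", "t_end"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.init_amp < 0 or self.stationarity_tol < 0:
            raise ValueError("init_amp and stationarity_tol must be non-negative")
        if self.dx != self.dy:
            raise ValueError("the 5-point stencil assumes square cells (dx == dy)")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def validate_stability(self, p: EpidemicParams) -> None:
        """Enforce the explicit-scheme diffusion stability bound."""
        dmax = float(np.max(p.diffusivities))
        if dmax > 0:
            h2 = min(self.dx, self.dy) ** 2
            dt_max = h2 / (4.0 * dmax)
            if self.dt > dt_max:
                raise ValueError(
                    f"dt={self.dt} violates the explicit stability bound "
                    f"dt <= h^2/(4*max(D)) = {dt_max:.4g}"
                )


@dataclass
class FieldState:
    """The three population-density fields at one time."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    t: float
    clip_events: int = 0

    def __post_init__(self) -> None:
        if not (self.S.shape == self.I.shape == self.R.shape):
            raise ValueError("S, I, R must share one shape")

    def copy(self) -> "FieldState":
        return FieldState(self.S.copy(), self.I.copy(), self.R.copy(), self.t, self.clip_events)


def laplacian_no_flux(field: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with mirror ghost nodes (zero normal flux).

    The ghost value equals the adjacent interior value (reflection about
    the cell face), so boundary fluxes vanish identically and the stencil
    sums to zero over the grid for any field — discrete mass conservation.
    """
    g = np.pad(field, 1, mode="symmetric")
    return (
        g[2:, 1:-1] + g[:-2, 1:-1] + g[1:-1, 2:] + g[1:-1, :-2] - 4.0 * field
    ) / (h * h)


def noise_increments(
    cfg: SimConfig, C_I: float, rng: np.random.Generator
) -> np.ndarray:
    """One step of Euler-Maruyama noise for the infected field.

    Independent N(0, 2*C_I*dt) per cell; the zero-intensity case returns an
    exact zero array without consuming random numbers.
    """
    if C_I < 0:
        raise ValueError("C_I must be non-negative")
    if C_I == 0.0:
        return np.zeros((cfg.nx, cfg.ny))
    return rng.normal(0.0, np.sqrt(2.0 * C_I * cfg.dt), size=(cfg.nx, cfg.ny))


def em_step(
    state: FieldState,
    p: EpidemicParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> FieldState:
    """Advance the fields one time step in place-free fashion.

    Deterministic forward Euler for S and R; Euler-Maruyama for I with
    ``noise`` (drawn from ``rng`` when not supplied, e.g. pre-averaged
    common random numbers in convergence studies).  Negative densities are
    clipped to zero and the clips counted.
    """
    F, G, H = reaction_rhs(state.S, state.I, state.R, p)
    if noise is None:
        noise = noise_increments(cfg, p.C_I, rng)
    with np.errstate(invalid="ignore", over="ignore"):  # finiteness checked below
        S = state.S + cfg.dt * (F + p.D1 * laplacian_no_flux(state.S, cfg.dx))
        I = state.I + cfg.dt * (G + p.D2 * laplacian_no_flux(state.I, cfg.dx)) + noise
        R = state.R + cfg.dt * (H + p.D3 * laplacian_no_flux(state.R, cfg.dx))
    for name, f in (("S", S), ("I", I), ("R", R)):
        if not np.isfinite(f).all():
            i, j = np.argwhere(~np.isfinite(f))[0]
            raise FloatingPointError(
                f"non-finite {name} at t={state.t + cfg.dt:.4f}, cell ({i}, {j})"
            )
    clips = int((S < 0).sum() + (I < 0).sum() + (R < 0).sum())
    if clips:
        np.clip(S, 0.0, None, out=S)
        np.clip(I, 0.0, None, out=I)
        np.clip(R, 0.0, None, out=R)
    return FieldState(S, I, R, state.t + cfg.dt, state.clip_events + clips)


@dataclass
class SimulationResult:
    """Final fields plus the per-snapshot summary time series."""

    state: FieldState
    summary: pd.DataFrame
    stationary: bool
    params: EpidemicParams
    config: SimConfig


def initial_state(
    p: EpidemicParams, cfg: SimConfig, ss: SteadyState | None = None
) -> tuple[FieldState, np.random.Generator]:
    """Equilibrium plus seeded uniform perturbations in [-init_amp, +init_amp].

    Returns the state together with the generator, whose remaining stream
    drives the noise increments of the run.
    """
    if ss is None:
        ss = select_stable_equilibrium(p)
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.nx, cfg.ny)
    fields = [
        x0 + (rng.uniform(-cfg.init_amp, cfg.init_amp, shape) if cfg.init_amp > 0 else 0.0)
        for x0 in (ss.S0, ss.I0, ss.R0)
    ]
    return FieldState(*(np.asarray(f, dtype=float) + np.zeros(shape) for f in fields), t=0.0), rng


def _snapshot(state: FieldState) -> dict[str, float]:
    return {
        "t": state.t,
        "mean_I": float(state.I.mean()),
        "min_I": float(state.I.min()),
        "max_I": float(state.I.max()),
        "var_I": float(state.I.var()),
        "clip_events": state.clip_events,
    }


def run(
    p: EpidemicParams,
    cfg: SimConfig,
    ss: SteadyState | None = None,
) -> SimulationResult:
    """Integrate from the perturbed equilibrium to t_end or stationarity.

    Stationarity is declared when the relative L2 change of I per unit
    time drops below ``cfg.stationarity_tol``, checked at snapshot times.
    On numerical blow-up the last finite snapshot state is returned with a
    logged error rather than a partial, non-finite field.
    """
    cfg.validate_stability(p)
    state, rng = initial_state(p, cfg, ss)
    records = [_snapshot(state)]
    n_steps = int(round(cfg.t_end / cfg.dt))
    last_check = state.copy()
    stationary = False
    for step in range(1, n_steps + 1):
        try:
            state = em_step(state, p, cfg, rng)
        except FloatingPointError:
            log.exception("blow-up at step %d; returning last finite snapshot", step)
            return SimulationResult(last_check, pd.DataFrame(records), False, p, cfg)
        if step % cfg.record_every == 0 or step == n_steps:
            records.append(_snapshot(state))
            dt_span = state.t - last_check.t
            norm = np.linalg.norm(last_check.I)
            change = np.linalg.norm(state.I - last_check.I) / (norm * dt_span) if norm else np.inf
            last_check = state.copy()
            if change < cfg.stationarity_tol:
                stationary = True
                log.info("stationary at t=%.2f (relative dI/dt %.3e)", state.t, change)
                break
    return SimulationResult(state, pd.DataFrame(records), stationary, p, cfg)
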