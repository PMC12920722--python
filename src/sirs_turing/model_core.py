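"""Reaction kinetics of the SIRS model with reinfection and saturated incidence.

The spatially homogeneous part of the model is

    dS/dt = b - d*S - beta0*S*I^2/(1 + alpha*I^2) + mu*R
    dI/dt =           beta0*S*I^2/(1 + alpha*I^2) - (gamma + d)*I
    dR/dt = gamma*I - (mu + d)*R

with birth rate ``b``, death rate ``d``, transmission rate ``beta0``,
saturation parameter ``alpha``, reinfection rate ``mu`` and recovery rate
``gamma``.  The saturated incidence force ``beta0*S*I^2/(1+alpha*I^2)``
levels off for large infected density, modelling behavioural inhibition of
spread; the ``mu*R`` term returns recovered individuals to the susceptible
pool and closes the S -> I -> R loop.

This module provides the reaction terms, the endemic equilibria (obtained
exactly from a quadratic in the infected density), the Jacobian of the
kinetics, and the second partial derivatives needed by the second-order
moment analysis in :mod:`sirs_turing.moment_stability`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EpidemicParams",
    "SteadyState",
    "SecondOrderCoeffs",
    "NoEndemicEquilibriumError",
    "incidence_force",
    "reaction_rhs",
    "endemic_equilibria",
    "select_stable_equilibrium",
    "jacobian",
    "second_order_coeffs",
]


class NoEndemicEquilibriumError(ValueError):
    """Raised when no (stable) endemic equilibrium exists for the parameters."""


@dataclass(frozen=True)
class EpidemicParams:
    """Model and noise parameters.

    Defaults are the base parameter set used throughout the stability and
    pattern analyses: b=1, d=1, beta0=35, gamma=1.5, D2=1, D3=0.2 with
    D1=10 for the diffusion-driven (Turing) regime.

    Parameters
    ----------
    b, d : float
        Birth rate of susceptibles and (common) death rate, per unit time.
    beta0 : float
        Transmission rate of the saturated incidence force.
    alpha : float
        Saturation parameter (>= 0); alpha = 0 recovers the unsaturated
        ``beta0*S*I^2`` incidence.
    mu : float
        Reinfection rate in [0, 1]: fraction rate at which recovered
        individuals become susceptible again.
    gamma : float
        Recovery rate.
    D1, D2, D3 : float
        Diffusion coefficients of S, I and R (>= 0).
    C_I : float
        Discrete noise intensity of the spatiotemporal white noise driving
        the infected density; equals the continuum intensity divided by the
        cell area of the lattice discretisation.
    """

    b: float = 1.0
    d: float = 1.0
    beta0: float = 35.0
    alpha: float = 0.0
    mu: float = 0.0
    gamma: float = 1.5
    D1: float = 10.0
    D2: float = 1.0
    D3: float = 0.2
    C_I: float = 0.0

    def __post_init__(self) -> None:
        # b, d, beta0, gamma are positive in the epidemic model proper, but
        # zero values are accepted so reduced systems (e.g. pure diffusion
        # in scheme verification) can reuse the integrator; the equilibrium
        # solvers enforce strict positivity where they divide by them.
        for name in ("b", "d", "beta0", "gamma", "alpha", "D1", "D2", "D3", "C_I"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu!r}")

    def with_(self, **kwargs) -> "EpidemicParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.D1, self.D2, self.D3])


@dataclass(frozen=True)
class SteadyState:
    """Homogeneous steady state (S0, I0, R0) with its ODE stability tag.

    ``stable`` refers to the diffusion-free, noise-free kinetics: all
    eigenvalues of the k=0 Jacobian have negative real part.
    """

    S0: float
    I0: float
    R0: float
    stable: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.I0, self.R0])


@dataclass(frozen=True)
class SecondOrderCoeffs:
    """Non-vanishing second partial derivatives of the kinetics at a steady state.

    F and G are linear in S and H is fully linear, so the only curvature
    terms are in the incidence force:  a5 = F_II/2,  a7 = F_SI, and the
    infection equation carries the opposite sign: b5 = -a5, b7 = -a7.
    """

    a5: float
    a7: float

    @property
    def b5(self) -> float:
        return -self.a5

    @property
    def b7(self) -> float:
        return -self.a7


def incidence_force(S, I, p: EpidemicParams):
    """Saturated incidence force ``beta0*S*I^2 / (1 + alpha*I^2)``.

    Accepts scalars or arrays; non-negative, and bounded by ``beta0*S/alpha``
    when ``alpha > 0``.
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("population densities must be non-negative")
    out = p.beta0 * S * I * I / (1.0 + p.alpha * I * I)
    return out if out.ndim else float(out)


def reaction_rhs(S, I, R, p: EpidemicParams):
    """Reaction rates (F, G, H) of the kinetics at (S, I, R).

    The incidence, recovery and reinfection terms cancel pairwise in the
    sum, so F + G + H = b - d*(S + I + R) identically.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("population densities must be non-negative")
    inc = incidence_force(S, I, p)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    F = p.b - p.d * S - inc + p.mu * R
    G = inc - (p.gamma + p.d) * I
    H = p.gamma * I - (p.mu + p.d) * R
    return F, G, H


def _endemic_quadratic(p: EpidemicParams) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of the quadratic A*I^2 + B*I + C = 0 for I0.

    Eliminating S0 = (gamma+d)(1+alpha*I0^2)/(beta0*I0) (from the I
    equation) and R0 = gamma*I0/(mu+d) (from the R equation) from the
    population identity S0 + I0 + R0 = b/d gives an exact quadratic in I0.
    """
    if p.beta0 <= 0 or p.d <= 0 or p.b <= 0 or p.gamma <= 0:
        raise ValueError("endemic equilibria require strictly positive b, d, beta0, gamma")
    A = p.alpha * (p.gamma + p.d) + p.beta0 * (p.mu + p.d + p.gamma) / (p.mu + p.d)
    B = -p.beta0 * p.b / p.d
    C = p.gamma + p.d
    return A, B, C


def _is_stable(p: EpidemicParams, S0: float, I0: float, R0: float) -> bool:
    J = jacobian(p, SteadyState(S0, I0, R0, stable=False))
    return bool(np.max(np.linalg.eigvals(J).real) < 0.0)


def endemic_equilibria(p: EpidemicParams, residual_tol: float = 1e-10) -> list[SteadyState]:
    """All endemic equilibria (I0 > 0), sorted by decreasing I0.

    Returns an empty list when the quadratic for I0 has no positive real
    root (the epidemic cannot sustain itself).  Each returned state
    satisfies the population identity S0 + I0 + R0 = b/d and carries its
    k=0 stability tag.
    """
    A, B, C = _endemic_quadratic(p)
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return []
    roots = sorted({(-B + s * np.sqrt(disc)) / (2.0 * A) for s in (+1.0, -1.0)}, reverse=True)
    states = []
    for I0 in roots:
        if I0 <= 0.0:
            continue
        S0 = (p.gamma + p.d) * (1.0 + p.alpha * I0 * I0) / (p.beta0 * I0)
        R0 = p.gamma * I0 / (p.mu + p.d)
        resid = np.abs(reaction_rhs(S0, I0, R0, p)).max()
        if resid > residual_tol:  # pragma: no cover - algebra guarantees this
            raise ArithmeticError(f"equilibrium residual {resid:.2e} exceeds {residual_tol:.0e}")
        states.append(SteadyState(S0, I0, R0, stable=_is_stable(p, S0, I0, R0)))
    return states


def select_stable_equilibrium(p: EpidemicParams) -> SteadyState:
    """The stable endemic equilibrium used as the base state of the analysis.

    If both endemic roots are stable (bistability) the upper branch
    (larger I0) is chosen and a warning is emitted.

    Raises
    ------
    NoEndemicEquilibriumError
        If there is no endemic root, or none of them is stable.
    """
    states = endemic_equilibria(p)
    if not states:
        raise NoEndemicEquilibriumError("no endemic equilibrium for these parameters")
    stable = [s for s in states if s.stable]
    if not stable:
        raise NoEndemicEquilibriumError("no stable endemic equilibrium for these parameters")
    if len(stable) > 1:
        warnings.warn(
            "both endemic roots are stable; selecting the upper branch (larger I0)",
            stacklevel=2,
        )
    return stable[0]  # endemic_equilibria sorts by decreasing I0


def jacobian(p: EpidemicParams, ss: SteadyState) -> np.ndarray:
    """Jacobian of the kinetics (F, G, H) at a steady state, 3x3.

    Row/column order is (S, I, R).  The last row is exactly
    [0, gamma, -(mu+d)] since H is linear, and G has no R dependence.
    """
    S0, I0 = ss.S0, ss.I0
    sat = 1.0 + p.alpha * I0 * I0
    F_S = -p.d - p.beta0 * I0 * I0 / sat
    F_I = -2.0 * p.beta0 * S0 * I0 / sat**2
    return np.array(
        [
            [F_S, F_I, p.mu],
            [p.beta0 * I0 * I0 / sat, 2.0 * p.beta0 * S0 * I0 / sat**2 - (p.gamma + p.d), 0.0],
            [0.0, p.gamma, -(p.mu + p.d)],
        ]
    )


def second_order_coeffs(p: EpidemicParams, ss: SteadyState) -> SecondOrderCoeffs:
    """Second-order expansion coefficients of the incidence force at ``ss``.

    a5 = (1/2) d^2F/dI^2 = -beta0*S0*(1 - 3*alpha*I0^2) / (1+alpha*I0^2)^3
    a7 = d^2F/dSdI       = -2*beta0*I0 / (1+alpha*I0^2)^2
    """
    S0, I0 = ss.S0, ss.I0
    sat = 1.0 + p.alpha * I0 * I0
    a5 = -p.beta0 * S0 * (1.0 - 3.0 * p.alpha * I0 * I0) / sat**3
    a7 = -2.0 * p.beta0 * I0 / sat**2
    return SecondOrderCoeffs(a5=a5, a7=a7)
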