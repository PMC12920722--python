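"""Second-order (moment-closure) stochastic stability analysis.

Perturbing the homogeneous endemic state to second order, projecting onto a
single lattice mode of squared wavenumber ``k^2``, statistically averaging
and closing the hierarchy at second moments yields a linear system
``dX/dt = A X`` for the nine moments

    X = (<dS>, <dI>, <dR>, <dS^2>, <dI^2>, <dR^2>, <dS dI>, <dS dR>, <dI dR>).

The spatiotemporal white noise driving the infected density enters ``A``
through its discrete intensity ``C_I`` (via the Gaussian noise/functional
correlation identity), coupling the first and second moments.  At
``C_I = 0`` the system is block-triangular: the first-moment block is
exactly the linearised operator ``J - k^2 D`` of classical Turing analysis,
and the second-moment block decouples.

Instability of the homogeneous state at some ``k`` is signalled by a
positive real part of the maximal eigenvalue of ``A(k^2)``; the Turing
threshold is the smallest ``k > 0`` at which the maximal eigenvalue crosses
zero through a purely real value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    EpidemicParams,
    NoEndemicEquilibriumError,
    SteadyState,
    jacobian,
    second_order_coeffs,
    select_stable_equilibrium,
)

__all__ = [
    "MomentMatrix",
    "DispersionCurve",
    "StabilityDiagram",
    "TuringThreshold",
    "OscillatoryCrossingError",
    "moment_coeffs",
    "moment_matrix",
    "linear_dispersion",
    "dispersion_curve",
    "turing_threshold",
    "stability_region",
]


class OscillatoryCrossingError(RuntimeError):
    """The maximal eigenvalue crosses zero with non-zero imaginary part.

    Such a crossing signals an oscillatory (Hopf-like) instability of the
    moment system, not a stationary Turing bifurcation.
    """


def moment_coeffs(p: EpidemicParams, ss: SteadyState, k2) -> dict[str, np.ndarray]:
    """Named coefficients of the moment matrix at squared wavenumber ``k2``.

    ``k2`` may be a scalar or an array; coefficient values broadcast
    accordingly.  ``a1, a2, a3 / b1, b2 / c2, c3`` are the entries of the
    linearised operator (diffusion absorbed into the diagonal ones),
    ``a5, a7`` the curvature terms of the incidence force (``b5 = -a5``,
    ``b7 = -a7``) and ``h1, h2, h3`` pairwise sums of the diagonal entries.
    """
    k2 = np.asarray(k2, dtype=float)
    S0, I0 = ss.S0, ss.I0
    sat = 1.0 + p.alpha * I0 * I0
    so = second_order_coeffs(p, ss)
    a2 = -2.0 * p.beta0 * S0 * I0 / sat**2
    a1 = -(k2 * p.D1 + p.d + p.beta0 * I0 * I0 / sat)
    b2 = -(k2 * p.D2 + p.gamma + p.d + a2)
    c3 = -(p.mu + p.d + k2 * p.D3)
    zeros = np.zeros_like(k2)
    c = {
        "a1": a1,
        "a2": a2 + zeros,
        "a3": p.mu + zeros,
        "a5": so.a5 + zeros,
        "a7": so.a7 + zeros,
        "b1": p.beta0 * I0 * I0 / sat + zeros,
        "b2": b2,
        "b5": so.b5 + zeros,
        "b7": so.b7 + zeros,
        "c2": p.gamma + zeros,
        "c3": c3,
    }
    c["h1"] = c["a1"] + c["b2"]
    c["h2"] = c["a1"] + c["c3"]
    c["h3"] = c["b2"] + c["c3"]
    return c


def _assemble(c: dict[str, np.ndarray], C_I) -> np.ndarray:
    """Stack of 9x9 moment matrices from broadcast coefficient arrays.

    The sparsity pattern is fixed; ``C_I`` appears only in the couplings of
    the noise into <dI^2>, <dS dI> and <dI dR>.
    """
    shape = np.broadcast_shapes(*(np.shape(v) for v in c.values()))
    A = np.zeros(shape + (9, 9))
    a1, a2, a3 = c["a1"], c["a2"], c["a3"]
    a5, a7, b1, b2 = c["a5"], c["a7"], c["b1"], c["b2"]
    b5, b7, c2, c3 = c["b5"], c["b7"], c["c2"], c["c3"]
    h1, h2, h3 = c["h1"], c["h2"], c["h3"]
    A[..., 0, 0], A[..., 0, 1], A[..., 0, 2] = a1, a2, a3
    A[..., 0, 4], A[..., 0, 6] = a5, a7
    A[..., 1, 0], A[..., 1, 1] = b1, b2
    A[..., 1, 4], A[..., 1, 6] = b5, b7
    A[..., 2, 1], A[..., 2, 2] = c2, c3
    A[..., 3, 3], A[..., 3, 6], A[..., 3, 7] = 2 * a1, 2 * a2, 2 * a3
    A[..., 4, 1], A[..., 4, 4], A[..., 4, 6] = 2 * C_I, 2 * b2, 2 * b1
    A[..., 5, 5], A[..., 5, 8] = 2 * c3, 2 * c2
    A[..., 6, 0], A[..., 6, 3], A[..., 6, 4] = C_I, b1, a2
    A[..., 6, 6], A[..., 6, 8] = h1, a3
    A[..., 7, 5], A[..., 7, 6], A[..., 7, 7], A[..., 7, 8] = a3, c2, h2, a2
    A[..., 8, 2], A[..., 8, 4], A[..., 8, 7], A[..., 8, 8] = C_I, c2, b1, h3
    return A


@dataclass(frozen=True)
class MomentMatrix:
    """The 9x9 moment-evolution matrix at one squared wavenumber."""

    entries: np.ndarray
    k2: float
    C_I: float
    coeffs: dict[str, float] = field(repr=False)


def moment_matrix(
    p: EpidemicParams, ss: SteadyState, k2: float, C_I: float | None = None
) -> MomentMatrix:
    """Moment-evolution matrix ``A(k^2)`` at the steady state ``ss``.

    ``C_I`` defaults to ``p.C_I``.
    """
    if k2 < 0:
        raise ValueError("k2 must be non-negative")
    ci = p.C_I if C_I is None else C_I
    if ci < 0:
        raise ValueError("C_I must be non-negative")
    c = moment_coeffs(p, ss, float(k2))
    return MomentMatrix(
        entries=_assemble(c, ci),
        k2=float(k2),
        C_I=float(ci),
        coeffs={k: float(v) for k, v in c.items()},
    )


def linear_dispersion(p: EpidemicParams, ss: SteadyState, k2) -> np.ndarray:
    """Eigenvalues of the linearised operator ``J_D(k^2) = J - k^2 D``.

    ``k2`` may be scalar (returns shape ``(3,)``) or an array (returns
    ``k2.shape + (3,)``).  This is the classical first-order dispersion
    relation, and the exact first-moment spectrum of the 9x9 system at
    ``C_I = 0``.
    """
    k2 = np.asarray(k2, dtype=float)
    J = jacobian(p, ss)
    JD = J - k2[..., None, None] * np.diag(p.diffusivities)
    return np.linalg.eigvals(JD)


def _leading_eig(ev: np.ndarray) -> np.ndarray:
    """Leading eigenvalue per stacked spectrum: maximal real part, ties
    broken by smaller \\|Im\\|, then by smaller Im (selects the conjugate
    with negative imaginary part)."""
    order = np.lexsort((ev.imag, np.abs(ev.imag), -ev.real), axis=-1)
    return np.take_along_axis(ev, order[..., :1], axis=-1)[..., 0]


def _lambda_max(p: EpidemicParams, ss: SteadyState, k2, C_I: float) -> np.ndarray:
    c = moment_coeffs(p, ss, np.asarray(k2, dtype=float))
    ev = np.linalg.eigvals(_assemble(c, C_I))
    return _leading_eig(ev)


@dataclass(frozen=True)
class DispersionCurve:
    """Leading eigenvalue of the moment system along a ``k^2`` grid.

    ``unstable_band`` is the maximal interval of ``k`` (not ``k^2``) with
    positive growth rate, refined by bisection beyond the grid; ``None``
    when the curve never becomes positive.  ``k_threshold`` is the lower
    band edge when the crossing there is purely real.
    """

    k2_grid: np.ndarray
    re_lambda: np.ndarray
    im_lambda: np.ndarray
    unstable_band: tuple[float, float] | None
    k_threshold: float | None


def _bisect_crossing(
    f, k_lo: float, k_hi: float, tol: float = 1e-6
) -> float:
    """Root of ``f`` (a sign change of Re lambda) bracketed in [k_lo, k_hi]."""
    f_lo = f(k_lo)
    while k_hi - k_lo > tol:
        mid = 0.5 * (k_lo + k_hi)
        if (f(mid) > 0) == (f_lo > 0):
            k_lo = mid
        else:
            k_hi = mid
    return 0.5 * (k_lo + k_hi)


def _band_and_threshold(
    p: EpidemicParams,
    ss: SteadyState,
    k_grid: np.ndarray,
    re: np.ndarray,
    C_I: float,
    im_tol: float = 1e-8,
):
    """Refine the first positive-growth band and its lower-edge threshold."""
    pos = re > 0.0
    if not pos.any():
        return None, None

    def re_at(k: float) -> float:
        return float(_lambda_max(p, ss, np.array([k * k]), C_I).real[0])

    i0 = int(np.argmax(pos))
    i1 = i0 + int(np.argmin(pos[i0:])) - 1 if not pos[i0:].all() else len(k_grid) - 1
    k_lo = k_grid[i0] if i0 == 0 else _bisect_crossing(re_at, k_grid[i0 - 1], k_grid[i0])
    k_hi = (
        k_grid[i1]
        if i1 == len(k_grid) - 1
        else _bisect_crossing(re_at, k_grid[i1], k_grid[i1 + 1])
    )
    lam_edge = _lambda_max(p, ss, np.array([k_lo * k_lo]), C_I)[0]
    if abs(lam_edge.imag) > im_tol:
        raise OscillatoryCrossingError(
            f"maximal eigenvalue crosses zero at k={k_lo:.6f} with "
            f"Im lambda={lam_edge.imag:.3e}; oscillatory crossing, not a Turing threshold"
        )
    return (float(k_lo), float(k_hi)), float(k_lo)


def dispersion_curve(
    p: EpidemicParams,
    ss: SteadyState | None = None,
    k2_grid: np.ndarray | None = None,
    C_I: float | None = None,
) -> DispersionCurve:
    """Leading-eigenvalue dispersion relation over a ``k^2`` grid.

    Defaults: the selected stable endemic equilibrium, 400 points with
    ``k`` in (0, 2], and ``C_I = p.C_I``.
    """
    if ss is None:
        ss = select_stable_equilibrium(p)
    if k2_grid is None:
        k2_grid = np.linspace(0.0, 2.0, 400) ** 2
    k2_grid = np.asarray(k2_grid, dtype=float)
    if k2_grid.ndim != 1 or np.any(np.diff(k2_grid) < 0) or np.any(k2_grid < 0):
        raise ValueError("k2_grid must be a sorted, non-negative 1-D array")
    ci = p.C_I if C_I is None else float(C_I)
    lam = _lambda_max(p, ss, k2_grid, ci)
    k_grid = np.sqrt(k2_grid)
    band, k_th = _band_and_threshold(p, ss, k_grid, lam.real, ci)
    return DispersionCurve(
        k2_grid=k2_grid,
        re_lambda=lam.real,
        im_lambda=lam.imag,
        unstable_band=band,
        k_threshold=k_th,
    )


@dataclass(frozen=True)
class TuringThreshold:
    """Lower edge of the instability band, with the full band in ``k``."""

    k_threshold: float | None
    unstable_band: tuple[float, float] | None

    def __iter__(self):
        return iter((self.k_threshold, self.unstable_band))


def turing_threshold(
    p: EpidemicParams,
    C_I: float | None = None,
    k_max: float = 2.0,
    dk: float = 1e-3,
    tol: float = 1e-6,
) -> TuringThreshold:
    """Turing threshold wavenumber of the moment system.

    Scans ``k`` in (0, k_max] with step ``dk``, then bisects the first sign
    change of the leading growth rate to ``|dk| < tol``.  The threshold is
    only reported when the crossing is purely real (zero imaginary part);
    an oscillatory crossing raises :class:`OscillatoryCrossingError`.

    Returns a :class:`TuringThreshold`; both fields are ``None`` when the
    homogeneous state is stable at every scanned wavenumber.
    """
    ss = select_stable_equilibrium(p)
    ci = p.C_I if C_I is None else float(C_I)
    k_grid = np.arange(dk, k_max + 0.5 * dk, dk)
    lam = _lambda_max(p, ss, k_grid * k_grid, ci)
    band, k_th = _band_and_threshold(p, ss, k_grid, lam.real, ci)
    return TuringThreshold(k_threshold=k_th, unstable_band=band)


@dataclass(frozen=True)
class StabilityDiagram:
    """Maximal growth rate over a 2-D parameter plane.

    ``max_re_lambda`` has shape ``(len(y_values), len(x_values))`` (row =
    y).  Grid points without a stable endemic equilibrium are NaN in
    ``max_re_lambda`` and False in ``defined_mask`` — a third state
    distinct from stable and unstable.
    """

    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    max_re_lambda: np.ndarray
    C_I: float

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.max_re_lambda)

    @property
    def unstable_mask(self) -> np.ndarray:
        return np.where(self.defined_mask, self.max_re_lambda > 0.0, False)


def stability_region(
    p: EpidemicParams,
    plane: tuple[str, str],
    x_values: np.ndarray,
    y_values: np.ndarray,
    C_I: float | None = None,
    k_max: float = 2.0,
    n_k: int = 400,
) -> StabilityDiagram:
    """Stability diagram in the ``(k2, D1)`` or ``(alpha, mu)`` plane.

    In the ``(k2, D1)`` plane the equilibrium is fixed by ``p`` and the
    growth rate is evaluated directly at each ``(k^2, D1)`` point.  In the
    ``(alpha, mu)`` plane the endemic equilibrium is re-solved at every
    grid point and the growth rate is maximised over an internal scan of
    ``k`` in (0, k_max] with ``n_k`` points.
    """
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    ci = p.C_I if C_I is None else float(C_I)
    out = np.full((len(y_values), len(x_values)), np.nan)

    if plane == ("k2", "D1"):
        for j, D1 in enumerate(y_values):
            pj = p.with_(D1=float(D1))
            try:
                ss = select_stable_equilibrium(pj)
            except NoEndemicEquilibriumError:
                continue
            out[j, :] = _lambda_max(pj, ss, x_values, ci).real
    elif plane == ("alpha", "mu"):
        k2_scan = np.linspace(k_max / n_k, k_max, n_k) ** 2
        for j, mu in enumerate(y_values):
            for i, alpha in enumerate(x_values):
                pij = p.with_(alpha=float(alpha), mu=float(mu))
                try:
                    ss = select_stable_equilibrium(pij)
                except NoEndemicEquilibriumError:
                    continue
                out[j, i] = _lambda_max(pij, ss, k2_scan, ci).real.max()
    else:
        raise ValueError(f"unsupported plane {plane!r}; use ('k2','D1') or ('alpha','mu')")

    return StabilityDiagram(
        x_name=plane[0],
        y_name=plane[1],
        x_values=x_values,
        y_values=y_values,
        max_re_lambda=out,
        C_I=ci,
    )
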