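"""Analytic fixed points of the propagation model and their stability.

Setting all four density derivatives to zero and eliminating the
infeasible branch gives the unique equilibrium with ``S* = 0``::

    S* = 0
    E* = c*f / D
    I* = f*beta / D
    R* = c*beta / D,      D = c*f + (c + f)*beta

with ``beta = r*delta*b + (1-r)*b``. The branch with ``S* != 0`` forces
``I* = -(d+e)/(a*K) <= 0``, which is not a density, and is therefore
rejected; it is exposed here explicitly so the elimination argument is
testable.

Note the fixed point depends only on ``b, c, f, r, delta`` (through
``beta``): the contact parameters ``a, K`` and the transfer rates
``d, e`` shape the transient but not where the system settles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ModelParameters, effective_infection_rate, jacobian, rhs_array

__all__ = [
    "SteadyState",
    "StabilityReport",
    "analytic_steady_state",
    "infeasible_branch_infectious_density",
    "steady_state_residual",
    "is_locally_stable",
]


class DegenerateParameterError(ValueError):
    """The fixed-point denominator c*f + (c+f)*beta vanishes."""


@dataclass(frozen=True)
class SteadyState:
    """A fixed point (S*, E*, I*, R*) with feasibility metadata."""

    S_star: float
    E_star: float
    I_star: float
    R_star: float
    feasible: bool
    residual_norm: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S_star, self.E_star, self.I_star, self.R_star], dtype=float
        )


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the linear stability check at a fixed point."""

    stable: bool
    eigenvalues: np.ndarray  # reduced (simplex-tangent) spectrum
    full_eigenvalues: np.ndarray  # 4x4 spectrum, incl. the conservation zero


def analytic_steady_state(params: ModelParameters) -> SteadyState:
    """Closed-form feasible fixed point of the system.

    Requires the denominator ``c*f + (c+f)*beta`` to be positive;
    the limits ``f -> 0`` (giving ``(0, 0, 0, 1)``, everything absorbed
    into R with no forgetting) and ``b -> 0`` with ``c*f > 0`` (giving
    ``(0, 1, 0, 0)``) are handled by the same formula and are exact.

    Raises
    ------
    DegenerateParameterError
        If the denominator vanishes (e.g. ``b = 0`` together with
        ``c*f = 0``), in which case the fixed point is not unique.
    """
    beta = effective_infection_rate(params)
    c, f = params.c, params.f
    denom = c * f + (c + f) * beta
    if denom <= 0.0:
        raise DegenerateParameterError(
            f"fixed-point denominator c*f + (c+f)*beta = {denom!r} is not "
            "positive; the equilibrium is degenerate"
        )
    e_star = c * f / denom
    i_star = f * beta / denom
    r_star = c * beta / denom
    point = np.array([0.0, e_star, i_star, r_star])
    residual = float(np.max(np.abs(rhs_array(point, params))))
    return SteadyState(
        S_star=0.0,
        E_star=e_star,
        I_star=i_star,
        R_star=r_star,
        feasible=True,
        residual_norm=residual,
    )


def infeasible_branch_infectious_density(params: ModelParameters) -> float:
    """Infectious density ``-(d+e)/(a*K)`` on the rejected ``S* != 0`` branch.

    The value is always <= 0, and strictly negative whenever ``d + e > 0``:
    a negative density has no physical meaning, which is the argument for
    discarding this branch in favour of the ``S* = 0`` equilibrium.

    Raises
    ------
    ZeroDivisionError
        If ``a*K == 0`` (no contact infection at all).
    """
    aK = params.a * params.K
    if aK == 0.0:
        raise ZeroDivisionError(
            "infeasible-branch density undefined: a*K = 0 (no contact term)"
        )
    return -(params.d + params.e) / aK


def steady_state_residual(point: SteadyState, params: ModelParameters) -> float:
    """Max-abs of the four derivatives at ``point``; ~0 iff a fixed point."""
    return float(np.max(np.abs(rhs_array(point.as_array(), params))))


def _reduced_jacobian(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    # Eliminate R = 1 - S - E - I: the reduced 3x3 Jacobian governs the
    # dynamics restricted to the invariant simplex.
    J = jacobian(y, params)
    Jr = J[:3, :3] - J[:3, 3:4]  # d/dx_k - d/dR for x in (S, E, I)
    return Jr


def is_locally_stable(
    point: SteadyState, params: ModelParameters, tol: float = 1e-10
) -> StabilityReport:
    """Linear stability of a fixed point within the simplex.

    The full 4x4 Jacobian always has a zero eigenvalue along the
    conservation direction (its columns sum to zero). Stability is judged
    on the 3x3 Jacobian of the system reduced by ``R = 1 - S - E - I``:
    the point is reported stable iff every reduced eigenvalue has real
    part below ``tol`` (marginal, zero-real-part directions — which arise
    in degenerate limits such as ``f = 0`` — count as not strictly stable
    only when the real part exceeds ``tol``).
    """
    y = point.as_array()
    reduced = np.linalg.eigvals(_reduced_jacobian(y, params))
    full = np.linalg.eigvals(jacobian(y, params))
    stable = bool(np.all(reduced.real < tol))
    return StabilityReport(stable=stable, eigenvalues=reduced, full_eigenvalues=full)
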