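"""Core compartmental model of unsafe-psychological-state contagion.

Workers in a construction crew are partitioned into four psychological
compartments:

* **S** (susceptible): no unsafe psychological state, but open to influence
  from surrounding workers;
* **E** (exposed): has contacted a carrier of the unsafe state but cannot
  yet propagate it;
* **I** (infectious): holds the unsafe psychological state and spreads it;
* **R** (recovered): temporarily immune through safety awareness or
  external constraint, with relapse possible via forgetting.

Densities ``(S, E, I, R)`` live on the probability simplex and evolve by a
mean-field ODE on a uniform contact network of average degree ``K``::

    dS/dt = -a*K*S*I - d*S - e*S
    dE/dt =  a*K*S*I - beta*E + f*R
    dI/dt =  d*S + beta*E - c*I
    dR/dt =  e*S + c*I - f*R

where ``beta = r*delta*b + (1-r)*b`` is the effective E -> I conversion
rate: a contact is non-intimate with probability ``r`` and converts at the
attenuated rate ``delta*b``, intimate with probability ``1-r`` and converts
at the full rate ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "CompartmentState",
    "BASELINE_PARAMETERS",
    "BASELINE_INITIAL_STATE",
    "effective_infection_rate",
    "rhs",
    "rhs_array",
    "jacobian",
]

#: tolerance for the S+E+I+R=1 normalization check
SIMPLEX_ATOL = 1e-9
#: slack allowed below zero for individual densities (round-off only)
NONNEG_ATOL = 1e-12

_UNIT_FIELDS = ("a", "b", "c", "d", "e", "f", "r", "delta")


@dataclass(frozen=True)
class ModelParameters:
    """The nine rate/probability constants of the propagation model.

    Parameters
    ----------
    a : float
        Exposure rate per infectious contact (per day). Enters the
        mass-action term ``a*K*S*I``.
    b : float
        Infection rate for intimate-contact conversion E -> I (per day).
    c : float
        Improvement rate I -> R (per day), e.g. through supervision or
        accident warnings.
    d : float
        Direct infection rate S -> I (per day), bypassing the exposed stage.
    e : float
        Safety-climate level driving immunization S -> R (per day).
    f : float
        Forgetting rate R -> E (per day): relapse from memory decay or
        work stress.
    r : float
        Probability that a contact is with a *non-intimate* infector,
        in [0, 1].
    delta : float
        Attenuation factor applied to ``b`` for non-intimate contacts,
        in [0, 1].
    K : float
        Network average degree (contacts per worker), positive.

    All rates are restricted to [0, 1] per day, the range in which the
    model is posed; ``K`` may exceed 1.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    r: float
    delta: float
    K: float

    def __post_init__(self) -> None:
        for name in _UNIT_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"parameter {name!r} must lie in [0, 1], got {value!r}"
                )
        if not np.isfinite(self.K) or self.K <= 0.0:
            raise ValueError(f"parameter 'K' must be positive, got {self.K!r}")

    @property
    def beta(self) -> float:
        """Effective E -> I conversion rate ``r*delta*b + (1-r)*b``."""
        return effective_infection_rate(self)

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **updates)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(fld.name for fld in fields(cls))


@dataclass(frozen=True)
class CompartmentState:
    """Densities ``(S, E, I, R)`` on the probability simplex."""

    S: float
    E: float
    I: float
    R: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite compartment density in {arr}")
        if np.any(arr < -NONNEG_ATOL):
            raise ValueError(f"negative compartment density in {arr}")
        total = float(arr.sum())
        if abs(total - 1.0) > SIMPLEX_ATOL:
            raise ValueError(
                f"densities must sum to 1 (got {total!r}); state {arr}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.E, self.I, self.R], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CompartmentState":
        s, e, i, r = (float(x) for x in np.asarray(arr, dtype=float))
        return cls(S=s, E=e, I=i, R=r)


#: baseline parameter set used throughout the numerical experiments
BASELINE_PARAMETERS = ModelParameters(
    a=0.7, b=0.7, c=0.8, d=0.1, e=0.2, f=0.05, r=0.3, delta=0.3, K=4.0
)

#: everyone susceptible at t=0
BASELINE_INITIAL_STATE = CompartmentState(S=1.0, E=0.0, I=0.0, R=0.0)


def effective_infection_rate(params: ModelParameters) -> float:
    """Effective E -> I conversion rate beta = r*delta*b + (1-r)*b.

    A contact is non-intimate with probability ``r`` and converts at the
    attenuated rate ``delta*b``; intimate with probability ``1-r`` at the
    full rate ``b``. Always in ``[delta*b, b] ⊆ [0, b]``.
    """
    return params.r * params.delta * params.b + (1.0 - params.r) * params.b


def rhs_array(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Vector field of the ODE system on a raw (S, E, I, R) array.

    Used directly by the integrator; performs no simplex validation.
    The four components sum to zero identically (every outflow term
    reappears as an inflow), so total density is conserved.
    """
    s, e_, i, r_ = y
    beta = effective_infection_rate(params)
    contact = params.a * params.K * s * i
    dS = -contact - params.d * s - params.e * s
    dE = contact - beta * e_ + params.f * r_
    dI = params.d * s + beta * e_ - params.c * i
    dR = params.e * s + params.c * i - params.f * r_
    return np.array([dS, dE, dI, dR])


def rhs(state: CompartmentState, params: ModelParameters) -> np.ndarray:
    """Time derivative ``(dS, dE, dI, dR)`` at a validated simplex state."""
    return rhs_array(state.as_array(), params)


def jacobian(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """4x4 Jacobian of :func:`rhs_array` at the state ``y``.

    Columns sum to zero (conservation), so the matrix is singular with
    left null vector (1, 1, 1, 1).
    """
    s, _e, i, _r = y
    beta = effective_infection_rate(params)
    aK = params.a * params.K
    return np.array(
        [
            [-aK * i - params.d - params.e, 0.0, -aK * s, 0.0],
            [aK * i, -beta, aK * s, params.f],
            [params.d, beta, -params.c, 0.0],
            [params.e, 0.0, params.c, -params.f],
        ]
    )
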