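"""Stochastic agent-based counterpart of the mean-field model.

Each worker is an agent carrying a label in {S, E, I, R}. Contacts are
either *annealed* — every step, each susceptible samples K agents
uniformly at random, which matches the well-mixed ``a*K*S*I`` closure of
the ODE and makes the ensemble mean a valid independent check of the
mean-field solution — or *quenched*, a fixed uniform random K-regular
simple graph, which is more faithful to a real crew but develops local
correlations the mean-field equations ignore (quenched runs are reported,
not asserted against the ODE).

Time advances in steps of ``dt`` with competing-risk transition sampling:
an agent with total exit hazard ``lam`` leaves its compartment with
probability ``1 - exp(-lam*dt)`` and picks a destination proportionally
to the individual hazards. Per-agent hazards follow the mean-field rates:

* S: ``a * (#infectious among its K contacts)`` to E, ``d`` to I, ``e`` to R;
* E: ``delta*b`` or ``b`` to I, according to whether the contact sampled
  this step is non-intimate (probability ``r``) or intimate (``1 - r``);
* I: ``c`` to R;
* R: ``f`` to E.

All transitions are computed from the pre-step state (synchronous
update). At ``dt = 0.01`` day the discretization error is negligible
next to Monte-Carlo noise at the rates of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np

from .model_core import ModelParameters
from .simulate import Trajectory

__all__ = [
    "NetworkConfig",
    "AgentPopulation",
    "build_network",
    "abm_step",
    "abm_run",
    "S",
    "E",
    "I",
    "R",
]

# integer compartment labels
S, E, I, R = 0, 1, 2, 3


@dataclass(frozen=True)
class NetworkConfig:
    """Population size, contact structure and seed for the stochastic model.

    The default crew size of 15 reflects the construction teams the model
    describes (5-20 workers); it is far too small for mean-field
    agreement, which is why validation against the ODE uses thousands of
    agents.
    """

    n_agents: int = 15
    degree: int = 4
    mode: Literal["annealed", "quenched"] = "annealed"
    seed: int = 0
    #: quenched only: fix each edge's intimacy once (non-intimate w.p. r)
    #: instead of re-sampling intimacy per exposure event
    per_edge_intimacy: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        if not 0 < self.degree < self.n_agents:
            raise ValueError(
                f"degree must satisfy 0 < K < n_agents, got K={self.degree}, "
                f"n={self.n_agents}"
            )
        if self.mode == "quenched" and (self.n_agents * self.degree) % 2 != 0:
            raise ValueError(
                "quenched mode needs n_agents*degree even for a K-regular graph"
            )
        if self.mode not in ("annealed", "quenched"):
            raise ValueError(f"unknown contact mode {self.mode!r}")


@dataclass
class AgentPopulation:
    """Per-agent labels plus (in quenched mode) the fixed contact graph."""

    labels: np.ndarray  # shape (n,), values in {S, E, I, R}
    config: NetworkConfig
    neighbors: np.ndarray | None = None  # (n, K) int array, quenched only
    edge_uniform: np.ndarray | None = None  # (n, K) floats, per-edge variant

    @property
    def n_agents(self) -> int:
        return len(self.labels)

    def fractions(self) -> np.ndarray:
        counts = np.bincount(self.labels, minlength=4)
        return counts / self.n_agents


def _initial_labels(n: int, init_fracs: np.ndarray | None, rng) -> np.ndarray:
    if init_fracs is None:
        return np.full(n, S, dtype=np.int64)  # everyone susceptible
    counts = np.floor(np.asarray(init_fracs, dtype=float) * n).astype(int)
    while counts.sum() < n:  # distribute rounding remainder at random
        counts[rng.integers(0, 4)] += 1
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)
    return labels


def build_network(
    config: NetworkConfig, init_fracs: np.ndarray | None = None
) -> AgentPopulation:
    """Construct the agent population for the configured contact mode.

    Quenched mode draws a uniform random K-regular simple graph
    (``n*K/2`` edges); annealed mode stores labels only, since contacts
    are re-drawn every step. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    labels = _initial_labels(config.n_agents, init_fracs, rng)
    if config.mode == "annealed":
        return AgentPopulation(labels=labels, config=config)
    graph = nx.random_regular_graph(config.degree, config.n_agents, seed=int(rng.integers(2**31)))
    neighbors = np.empty((config.n_agents, config.degree), dtype=np.int64)
    for node in range(config.n_agents):
        neighbors[node] = sorted(graph.neighbors(node))
    edge_uniform = None
    if config.per_edge_intimacy:
        # one symmetric uniform per undirected edge; at step time the edge
        # is non-intimate iff its uniform is below r (so the marginal
        # probability matches the per-event sampling)
        draws: dict[tuple[int, int], float] = {}
        edge_uniform = np.empty((config.n_agents, config.degree))
        for node in range(config.n_agents):
            for j, nbr in enumerate(neighbors[node]):
                key = (min(node, int(nbr)), max(node, int(nbr)))
                if key not in draws:
                    draws[key] = float(rng.random())
                edge_uniform[node, j] = draws[key]
    return AgentPopulation(
        labels=labels, config=config, neighbors=neighbors,
        edge_uniform=edge_uniform,
    )


def _infectious_contact_counts(
    pop: AgentPopulation, rng: np.random.Generator
) -> np.ndarray:
    """Number of infectious agents among each agent's K contacts this step."""
    n = pop.n_agents
    k = pop.config.degree
    infectious = pop.labels == I
    if pop.config.mode == "annealed":
        # K uniform random contacts (with replacement) per agent: the count
        # of infectious contacts is Binomial(K, I-fraction)
        i_frac = infectious.mean()
        return rng.binomial(k, i_frac, size=n)
    return infectious[pop.neighbors].sum(axis=1)


def abm_step(
    pop: AgentPopulation,
    params: ModelParameters,
    dt: float,
    rng: np.random.Generator,
) -> AgentPopulation:
    """Advance the population one synchronous step of length ``dt`` days.

    Agent count is conserved; labels only move along the model's allowed
    transitions (S->E/I/R, E->I, I->R, R->E).
    """
    labels = pop.labels
    new_labels = labels.copy()
    n = len(labels)

    is_s = labels == S
    if is_s.any():
        m = _infectious_contact_counts(pop, rng)[is_s]
        rate_e = params.a * m
        rate_i = np.full(m.shape, params.d)
        rate_r = np.full(m.shape, params.e)
        total = rate_e + rate_i + rate_r
        p_exit = -np.expm1(-total * dt)
        u = rng.random(is_s.sum())
        moving = (u < p_exit) & (total > 0)
        # destination drawn proportionally to the competing hazards
        dest_u = rng.random(is_s.sum()) * np.where(total > 0, total, 1.0)
        dest = np.where(
            dest_u < rate_e, E, np.where(dest_u < rate_e + rate_i, I, R)
        )
        idx = np.flatnonzero(is_s)
        new_labels[idx[moving]] = dest[moving]

    is_e = labels == E
    if is_e.any():
        n_e = int(is_e.sum())
        if pop.config.per_edge_intimacy and pop.edge_uniform is not None:
            # sample a neighbour uniformly; its fixed mark sets the rate
            cols = rng.integers(0, pop.config.degree, size=n_e)
            rows = np.flatnonzero(is_e)
            intimate = pop.edge_uniform[rows, cols] >= params.r
        else:
            intimate = rng.random(n_e) >= params.r
        rate = np.where(intimate, params.b, params.delta * params.b)
        fire = rng.random(n_e) < -np.expm1(-rate * dt)
        idx = np.flatnonzero(is_e)
        new_labels[idx[fire]] = I

    is_i = labels == I
    if is_i.any():
        fire = rng.random(int(is_i.sum())) < -np.expm1(-params.c * dt)
        idx = np.flatnonzero(is_i)
        new_labels[idx[fire]] = R

    is_r = labels == R
    if is_r.any():
        fire = rng.random(int(is_r.sum())) < -np.expm1(-params.f * dt)
        idx = np.flatnonzero(is_r)
        new_labels[idx[fire]] = E

    return AgentPopulation(
        labels=new_labels,
        config=pop.config,
        neighbors=pop.neighbors,
        edge_uniform=pop.edge_uniform,
    )


def abm_run(
    config: NetworkConfig,
    params: ModelParameters,
    t_end: float = 30.0,
    dt: float = 0.01,
    n_reps: int = 1,
    seed: int | None = None,
    init_fracs: np.ndarray | None = None,
    record_every: int = 1,
) -> tuple[Trajectory, np.ndarray]:
    """Ensemble of replicate runs with independent sub-seeds.

    Returns the ensemble-mean trajectory of label fractions plus the full
    per-replicate array of shape ``(n_reps, n_times, 4)``. Fully
    reproducible under a fixed seed; ``record_every`` thins the recorded
    grid (the dynamics always step at ``dt``).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if seed is None:
        seed = config.seed
    n_steps = int(round(t_end / dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    if rec_idx[-1] != n_steps:
        rec_idx = np.append(rec_idx, n_steps)
    times = rec_idx * dt
    per_rep = np.empty((n_reps, len(times), 4))
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        pop = build_network(
            NetworkConfig(
                n_agents=config.n_agents,
                degree=config.degree,
                mode=config.mode,
                seed=int(rng.integers(2**31)),
                per_edge_intimacy=config.per_edge_intimacy,
            ),
            init_fracs=init_fracs,
        )
        rec_set = set(rec_idx.tolist())
        row = 0
        if 0 in rec_set:
            per_rep[rep, row] = pop.fractions()
            row += 1
        for step in range(1, n_steps + 1):
            pop = abm_step(pop, params, dt, rng)
            if step in rec_set:
                per_rep[rep, row] = pop.fractions()
                row += 1
    mean_states = per_rep.mean(axis=0)
    return Trajectory(times=times, states=mean_states, params=params), per_rep
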