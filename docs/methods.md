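# Methods

## Model

`psychseir` models the spread of unsafe psychological states through a
construction crew as a four-compartment contagion on a uniform contact
network. Each worker is susceptible (S), exposed (E), infectious (I) or
recovered (R); densities satisfy `S+E+I+R = 1` and evolve by

```
dS/dt = −aK·S·I − d·S − e·S
dE/dt =  aK·S·I − β·E + f·R
dI/dt =  d·S + β·E − c·I
dR/dt =  e·S + c·I − f·R
```

The mass-action term `aK·S·I` assumes well-mixed contacts: every worker
meets `K` others per unit time, each infectious with probability `I`.
The composite `β = rδb + (1−r)b` averages the E → I conversion over the
two contact types: non-intimate with probability `r` at the attenuated
rate `δb`, intimate otherwise at the full rate `b`.

Assumptions worth keeping in mind:

* the crew size is constant (no hiring or turnover during the episode);
* the network is homogeneous — every worker has the same effective
  degree `K`; heterogeneous-degree variants are out of scope;
* parameters are constant in time; all rates are per day and restricted
  to [0, 1], the range in which the model is posed (`K` may be larger).

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `a` | exposure rate per infectious contact | 0.7 | /day |
| `b` | intimate-contact conversion rate E→I | 0.7 | /day |
| `c` | improvement rate I→R | 0.8 | /day |
| `d` | direct infection rate S→I | 0.1 | /day |
| `e` | safety-climate immunization rate S→R | 0.2 | /day |
| `f` | forgetting (relapse) rate R→E | 0.05 | /day |
| `r` | probability a contact is non-intimate | 0.3 | — |
| `δ` | non-intimate attenuation of `b` | 0.3 | — |
| `K` | network average degree | 4 | contacts |

The defaults are the baseline condition of the numerical experiments;
they describe a small construction team (5–20 workers, default agent
count 15) with a moderate climate and mostly intimate ties. The shipped
sweeps vary one parameter at a time against this baseline:
`e ∈ {0.2, 0.5, 0.8}`, `r ∈ {0, 1}`, `K ∈ {4, 10, 20}`,
`f ∈ {0.05, 0.3, 0.7}`.

A deliberate reading: the printed E→I composite is taken as `r·δ·b`
with `δ` the attenuation factor, since the attenuation parameter
otherwise enters the model nowhere; `δ` is an explicit field, so a user
who prefers a different coupling can set it freely.

## Equilibrium

Setting the derivatives to zero gives two branches. The branch with
`S* ≠ 0` forces `I* = −(d+e)/(aK) ≤ 0`, which is not a density and is
exposed programmatically (`infeasible_branch_infectious_density`) so the
elimination argument is testable. The feasible branch is

```
S* = 0,  E* = cf/D,  I* = fβ/D,  R* = cβ/D,   D = cf + (c+f)β.
```

It requires `D > 0`; a vanishing denominator (`b = 0` with `cf = 0`)
raises `DegenerateParameterError`. The limits `f → 0` (everything
absorbed into R) and `b → 0` with `cf > 0` are exact through the same
formula. Notably the equilibrium contains no `a`, `d`, `e` or `K`: those
parameters shape the transient only. `I*` and `R*` are increasing and
`E*` decreasing in `β` (Möbius functions of `β` with positive
determinant), which underlies the intimacy and forgetting orderings.

Local stability is checked numerically: the 4×4 Jacobian always has a
zero eigenvalue along the conservation direction (its columns sum to
zero), so the reported spectrum is that of the 3×3 Jacobian after
eliminating `R = 1−S−E−I`. At the baseline fixed point the reduced
eigenvalues are `−0.70 ± 0.13i` and `−0.45`, so the equilibrium is a
stable focus-node; no analytic stability proof is attempted, and the
check is per-parameter-set, not global.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` RK45, `rtol=1e-8`,
  `atol=1e-14`, sampled on a uniform grid of 0.01 day over [0, 30] days
  by default. The system is non-stiff at these rates. The small absolute
  tolerance is deliberate: a compartment decaying to zero undershoots by
  roughly the solver's atol, and trajectory densities are required to
  stay above −1e-12. Negative round-off is clipped only when reporting a
  final state, never inside the solver.
* Peaks are located on the output grid without interpolation, ties
  breaking to the earliest time; at 0.01-day spacing the grid error is
  below 1e-6 in peak height (asserted by a refinement test).
* The settling time is the earliest grid time after which every
  compartment stays within `ε` (default 0.01) of the analytic fixed
  point in sup-norm, with `inf` as the not-reached sentinel. The choice
  of `ε` materially affects the number — the baseline intimacy contrast
  settles at 10.2 d (r=0) and 14.9 d (r=1) at `ε=0.01` — so `ε` is
  exposed everywhere a settling time is reported.

## Agent-based cross-check

The stochastic model assigns each of `n` agents a compartment label and
steps in increments of `dt = 0.01` day. Transitions are sampled by
competing risks: an agent with total exit hazard `λ` leaves with
probability `1 − exp(−λ·dt)` and picks its destination proportionally to
the individual hazards (for S: `a·m` to E with `m` the number of
infectious contacts, `d` to I, `e` to R). Exposed agents sample one
contact per step, non-intimate with probability `r`, and convert at
`δb` or `b` accordingly. Updates are synchronous from the pre-step
state. Competing-risk sampling agrees with independent per-destination
draws to O(dt²) while avoiding simultaneous-firing ambiguity.

Two contact modes:

* **annealed** (validation mode): each susceptible's `m` is drawn
  Binomial(`K`, current infectious fraction) — contacts re-randomized
  every step. This matches the well-mixed closure exactly, so the
  ensemble mean must converge to the ODE as `n` and the replicate count
  grow; the shipped check uses 2000 agents × 50 replicates and agrees
  with the ODE within 0.02 sup-norm over 30 days.
* **quenched**: a fixed uniform random K-regular simple graph
  (networkx). Local correlations on a sparse fixed graph legitimately
  deviate from mass action, so quenched runs are reported but never
  asserted against the ODE. An optional per-edge intimacy variant fixes
  each edge's intimacy mark once (via a stored uniform compared to `r`)
  instead of re-sampling per event.

The default crew size of 15 mirrors the teams the model describes but is
far too small for mean-field agreement; ensemble validation always uses
thousands of agents. Replicates draw independent child seeds from a
`numpy` `SeedSequence`, making every run exactly reproducible.

What the agent model does *not* emulate: heterogeneous degrees,
households/shift structure, time-varying climate, or any demographic
turnover. Agreement between the annealed ensemble and the ODE validates
the implementation of both, not the model's fidelity to real crews.

## Known limitations

* All conclusions about peak ordering and settling are grid-read from
  deterministic trajectories; no uncertainty is attached to them.
* The settling-time comparison to the qualitative "about 12 days"
  observation depends on the band criterion (`ε`) that a figure reader
  implicitly applies; the package reports 14.9 days for the slower
  intimacy run at `ε=0.01`.
* Parameters are treated as continuous-time rates although they are
  elicited as probabilities; restricting them to [0, 1] keeps both
  readings consistent at the values used.
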