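# psychseir

Unsafe psychological states — fluke, herd, paralysis and similar moods —
are the direct precursors of unsafe behaviour on construction sites, and
they spread through a crew's social network much like a contagion.
`psychseir` implements a compartmental SEIR-type model of this spread for
safety researchers and modellers: workers are **S**usceptible,
**E**xposed, **I**nfectious or **R**ecovered, with three features specific
to the workplace setting:

* **safety climate** `e`: the shared organizational perception of safety
  immunizes susceptible workers directly (S → R);
* **intimate relationships**: an exposed worker converts to infectious at
  the full rate `b` after contact with an intimate infector, but only at
  the attenuated rate `δb` for a non-intimate one (a contact is
  non-intimate with probability `r`);
* **forgetting** `f`: immunity is temporary, recovered workers relapse to
  exposed (R → E).

Densities on the probability simplex evolve by the mean-field system

```
dS/dt = −aK·S·I − d·S − e·S
dE/dt =  aK·S·I − β·E + f·R         β = rδb + (1−r)b
dI/dt =  d·S + β·E − c·I
dR/dt =  e·S + c·I − f·R
```

with `a` the exposure rate per infectious contact, `K` the network
average degree, `d` the direct infection rate and `c` the improvement
rate. The system has a unique feasible equilibrium in closed form,

```
S* = 0,   E* = cf/D,   I* = fβ/D,   R* = cβ/D,   D = cf + (c+f)β,
```

(the branch with S* ≠ 0 forces I* = −(d+e)/aK < 0 and is rejected), which
the package exposes together with the ODE integrator, the scripted
parameter-sweep experiments, and a stochastic agent-based model on
annealed or quenched K-regular contact networks that cross-validates the
mean-field solution.

## Worked example

The default configuration is the baseline parameter set
`a=0.7, b=0.7, c=0.8, d=0.1, e=0.2, f=0.05, r=0.3, δ=0.3, K=4` with
everyone susceptible at `t=0`. The equilibrium and its stability:

```console
$ psychseir steady
S*=0.000000 E*=0.078424 I*=0.054210 R*=0.867366
residual_norm=0.000e+00
rejected branch I* = -(d+e)/aK = -0.107143 (infeasible)
locally stable: True (reduced eigenvalues: -0.7015-0.1340j, -0.7015+0.1340j, -0.4518+0.0000j)
```

At equilibrium about 5.4 % of the crew is actively infectious and 86.7 %
recovered; the susceptible pool empties completely because climate and
direct infection drain it at rate `d+e` regardless of contact. One
integration over 30 days:

```console
$ psychseir run
peak_I=0.136492 at t=3.55 d
stabilization_time=10.93 d (epsilon=0.01)
final state: S=0.000000 E=0.078424 I=0.054211 R=0.867365
```

The infectious density overshoots its equilibrium (13.6 % at day 3.6)
before relaxing. Sweeping the safety-climate level:

```console
$ psychseir sweep --param e --values 0.2,0.5,0.8
parameter  value   peak_I  t_peak_I  stabilization_time   E_star  I_star   R_star
        e    0.2 0.136492      3.55               10.93 0.078424 0.05421 0.867366
        e    0.5 0.090031      3.02                8.19 0.078424 0.05421 0.867366
        e    0.8 0.067636      2.77                5.84 0.078424 0.05421 0.867366
```

A weak climate (`e=0.2`) produces an infectious peak just over twice the
strong-climate (`e=0.8`) peak, arriving later — a stronger climate both
suppresses and advances the outbreak, while the equilibrium columns show
it does not move where the system finally settles (the fixed point
contains no `e`). Other subcommands: `intimacy` (r=0 vs r=1 contrast),
`abm` (stochastic agent ensemble), `figures` (regenerate all experiment
curves, tables and plots into the output directory). All defaults can be
overridden by a flat YAML config passed with `--config`.

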