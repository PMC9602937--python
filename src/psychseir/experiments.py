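"""Scripted numerical experiments: baseline run and parameter sweeps.

Four experiments probe how the contagion responds to workplace levers,
holding every other parameter at the baseline
(a=0.7, b=0.7, c=0.8, d=0.1, e=0.2, f=0.05, r=0.3, delta=0.3, K=4,
everyone susceptible at t=0):

* baseline: the four density curves over 30 days;
* safety climate: e in {0.2, 0.5, 0.8} — stronger climate suppresses and
  advances the infectious peak;
* intimacy contrast: r in {0, 1} — all-intimate vs all-non-intimate
  contacts shift both the peak and the equilibrium;
* network degree: K in {4, 10, 20} — denser contact raises and advances
  the peak but leaves the equilibrium untouched;
* forgetting rate: f in {0.05, 0.3, 0.7} — faster relapse feeds the
  infectious pool at the expense of the recovered one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model_core import (
    BASELINE_INITIAL_STATE,
    BASELINE_PARAMETERS,
    CompartmentState,
    ModelParameters,
)
from .simulate import (
    DEFAULT_DT_OUT,
    DEFAULT_EPSILON,
    DEFAULT_T_END,
    SummaryStats,
    Trajectory,
    integrate,
    summarize,
)

__all__ = [
    "SweepResult",
    "run_baseline",
    "run_sweep",
    "compare_intimacy",
    "summary_table",
    "SAFETY_CLIMATE_VALUES",
    "DEGREE_VALUES",
    "FORGETTING_VALUES",
    "INTIMACY_VALUES",
]

SAFETY_CLIMATE_VALUES = (0.2, 0.5, 0.8)
DEGREE_VALUES = (4.0, 10.0, 20.0)
FORGETTING_VALUES = (0.05, 0.3, 0.7)
INTIMACY_VALUES = (0.0, 1.0)


@dataclass(frozen=True)
class SweepResult:
    """One integration per value of a single swept parameter."""

    swept_parameter: str
    values: tuple[float, ...]
    stats: tuple[SummaryStats, ...]
    trajectories: tuple[Trajectory, ...]

    def __len__(self) -> int:
        return len(self.values)


def _run_one(
    params: ModelParameters,
    init: CompartmentState,
    t_end: float,
    dt_out: float,
    epsilon: float,
) -> tuple[Trajectory, SummaryStats]:
    traj = integrate(params, init, t_end=t_end, dt_out=dt_out)
    return traj, summarize(traj, epsilon=epsilon)


def run_baseline(
    params: ModelParameters = BASELINE_PARAMETERS,
    init: CompartmentState = BASELINE_INITIAL_STATE,
    t_end: float = DEFAULT_T_END,
    dt_out: float = DEFAULT_DT_OUT,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[Trajectory, SummaryStats]:
    """Integrate the baseline configuration and summarize the curves."""
    return _run_one(params, init, t_end, dt_out, epsilon)


def run_sweep(
    parameter: str,
    values: Sequence[float],
    base: ModelParameters = BASELINE_PARAMETERS,
    init: CompartmentState = BASELINE_INITIAL_STATE,
    t_end: float = DEFAULT_T_END,
    dt_out: float = DEFAULT_DT_OUT,
    epsilon: float = DEFAULT_EPSILON,
) -> SweepResult:
    """Vary one model parameter, holding all others at ``base``.

    Raises
    ------
    ValueError
        For an unknown parameter name or a value outside its domain
        (domain checks are delegated to ``ModelParameters``).
    """
    if parameter not in ModelParameters.field_names():
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of "
            f"{ModelParameters.field_names()}"
        )
    trajs: list[Trajectory] = []
    stats: list[SummaryStats] = []
    for value in values:
        params = base.with_updates(**{parameter: float(value)})
        traj, stat = _run_one(params, init, t_end, dt_out, epsilon)
        trajs.append(traj)
        stats.append(stat)
    return SweepResult(
        swept_parameter=parameter,
        values=tuple(float(v) for v in values),
        stats=tuple(stats),
        trajectories=tuple(trajs),
    )


def compare_intimacy(
    base: ModelParameters = BASELINE_PARAMETERS,
    init: CompartmentState = BASELINE_INITIAL_STATE,
    t_end: float = DEFAULT_T_END,
    dt_out: float = DEFAULT_DT_OUT,
    epsilon: float = DEFAULT_EPSILON,
) -> SweepResult:
    """All-intimate (r=0) vs all-non-intimate (r=1) contact regimes.

    With ``delta = 1`` the two regimes coincide exactly: the intimacy
    distinction only matters through the attenuation of ``b``.
    """
    return run_sweep(
        "r", INTIMACY_VALUES, base=base, init=init, t_end=t_end,
        dt_out=dt_out, epsilon=epsilon,
    )


def summary_table(*results: SweepResult) -> pd.DataFrame:
    """Flatten sweep results into one row per run.

    Columns: swept parameter name and value, infectious-curve peak and
    peak day, settling day, and the analytic equilibrium densities.
    Row order follows the input order (deterministic).
    """
    columns = [
        "parameter",
        "value",
        "peak_I",
        "t_peak_I",
        "stabilization_time",
        "E_star",
        "I_star",
        "R_star",
    ]
    rows = []
    for result in results:
        for value, stat in zip(result.values, result.stats):
            rows.append(
                {
                    "parameter": result.swept_parameter,
                    "value": value,
                    "peak_I": stat.peak_I,
                    "t_peak_I": stat.t_peak_I,
                    "stabilization_time": stat.stabilization_time,
                    "E_star": stat.steady_state.E_star,
                    "I_star": stat.steady_state.I_star,
                    "R_star": stat.steady_state.R_star,
                }
            )
    return pd.DataFrame(rows, columns=columns)


def write_experiment_artifacts(
    outdir: str | Path,
    t_end: float = DEFAULT_T_END,
    dt_out: float = DEFAULT_DT_OUT,
    epsilon: float = DEFAULT_EPSILON,
    plot: bool = True,
) -> pd.DataFrame:
    """Run all shipped experiments, writing per-run CSVs, a summary table
    and (optionally) line plots under ``outdir``; returns the summary."""
    from .cli_io import write_trajectory_csv  # local import: avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    base_traj, base_stats = run_baseline(t_end=t_end, dt_out=dt_out, epsilon=epsilon)
    sweeps = {
        "safety_climate": run_sweep("e", SAFETY_CLIMATE_VALUES, t_end=t_end,
                                    dt_out=dt_out, epsilon=epsilon),
        "intimacy": compare_intimacy(t_end=t_end, dt_out=dt_out, epsilon=epsilon),
        "degree": run_sweep("K", DEGREE_VALUES, t_end=t_end, dt_out=dt_out,
                            epsilon=epsilon),
        "forgetting": run_sweep("f", FORGETTING_VALUES, t_end=t_end,
                                dt_out=dt_out, epsilon=epsilon),
    }

    write_trajectory_csv(base_traj, outdir / "baseline.csv")
    for name, sweep in sweeps.items():
        for value, traj in zip(sweep.values, sweep.trajectories):
            tag = f"{sweep.swept_parameter}={value:g}"
            write_trajectory_csv(traj, outdir / f"{name}_{tag}.csv")

    baseline_result = SweepResult(
        swept_parameter="baseline",
        values=(float("nan"),),
        stats=(base_stats,),
        trajectories=(base_traj,),
    )
    table = summary_table(baseline_result, *sweeps.values())
    table.to_csv(outdir / "summary.csv", index=False)

    if plot:
        _plot_all(outdir, base_traj, sweeps)
    return table


def _plot_all(outdir: Path, base_traj: Trajectory, sweeps: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for comp in "SEIR":
        ax.plot(base_traj.times, base_traj.column(comp), label=comp)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("density")
    ax.set_title("Baseline node-density curves")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "baseline.png", dpi=120)
    plt.close(fig)

    for name, sweep in sweeps.items():
        for comp in ("I", "R"):
            fig, ax = plt.subplots(figsize=(6, 4))
            for value, traj in zip(sweep.values, sweep.trajectories):
                ax.plot(
                    traj.times,
                    traj.column(comp),
                    label=f"{sweep.swept_parameter}={value:g}",
                )
            ax.set_xlabel("time (days)")
            ax.set_ylabel(f"{comp} density")
            ax.set_title(f"{name} sweep: {comp} density vs time")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / f"{name}_{comp}.png", dpi=120)
            plt.close(fig)
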