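"""Benchmark harness: method-comparison sweeps, solver-budget sweeps,
high-density scaling, and multi-iteration campaign replay.

All randomness flows from one base seed through ``numpy`` seed sequences, so
reports are reproducible bit for bit; the routing backend's budget is a move
count, not wall-clock time, which keeps results machine-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .labware import get_plate
from .tasks import TaskMatrix, TransferJob, WorkList, random_task, read_worklist_csv
from .distance import TimingParams, combined_distance
from .evaluator import SimParams, simulate_execution
from .schedulers import DEFAULT_MOVE_BUDGET, METHODS, schedule

__all__ = [
    "BenchmarkReport",
    "run_method_sweep",
    "run_budget_sweep",
    "run_campaign",
    "percent_reduction",
    "generate_campaign_tasks",
]

DEFAULT_METHODS = ("row-major", "lap", "greedy", "cvrp")


def derive_seed(base: int, *parts) -> int:
    """Stable sub-seed from a base seed and arbitrary labels (< 2**31)."""
    ints = [
        p if isinstance(p, (int, np.integer)) else zlib.crc32(str(p).encode())
        for p in parts
    ]
    ss = np.random.SeedSequence([int(base)] + [int(i) for i in ints])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class BenchmarkReport:
    """Raw per-run rows plus aggregated summary and the run configuration."""

    raw: pd.DataFrame
    summary: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_csv(self, out_dir, prefix: str = "bench") -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.raw.to_csv(out / f"{prefix}_raw.csv", index=False)
        self.summary.to_csv(out / f"{prefix}_summary.csv", index=False)
        (out / f"{prefix}_config.json").write_text(
            json.dumps(self.config, indent=2, default=str)
        )


def _check_methods(methods: Sequence[str]) -> tuple[str, ...]:
    methods = tuple(methods)
    if not methods:
        raise ValueError("at least one scheduling method is required")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; available: {sorted(METHODS)}")
    return methods


def run_method_sweep(
    combos: Sequence[tuple[str, str]],
    multipliers: Sequence[int] = tuple(range(1, 11)),
    n_seeds: int = 3,
    methods: Sequence[str] = DEFAULT_METHODS,
    move_budget: int = DEFAULT_MOVE_BUDGET,
    seed: int = 0,
    params: TimingParams | None = None,
    simulate: bool = False,
    sim_params: SimParams | None = None,
) -> BenchmarkReport:
    """Method comparison over random tasks.

    For each (source, destination) combo and each multiplier, the number of
    transfers is multiplier x destination well count; ``n_seeds`` random
    tasks per cell are scheduled by every method.  Defaults mirror the
    standard benchmark design: sizes 1x-10x the destination plate, 3
    replicate tasks per size.
    """
    methods = _check_methods(methods)
    if not combos:
        raise ValueError("at least one plate combination is required")
    rows = []
    for ci, (src_name, dst_name) in enumerate(combos):
        src, dst = get_plate(src_name), get_plate(dst_name)
        for mult in multipliers:
            n = mult * dst.n_wells
            if n > src.n_wells * dst.n_wells:
                raise ValueError(
                    f"{src.name}->{dst.name}: {n} transfers exceed the "
                    f"task-matrix capacity"
                )
            for rep in range(n_seeds):
                task_seed = derive_seed(seed, "task", ci, mult, rep)
                task = random_task(src, dst, n, seed=task_seed)
                model = combined_distance(task, params)
                for method in methods:
                    res = schedule(
                        task,
                        method,
                        model,
                        move_budget=move_budget,
                        seed=derive_seed(seed, "solve", ci, mult, rep, method),
                    )
                    row = {
                        "source_format": src.name,
                        "dest_format": dst.name,
                        "multiplier": mult,
                        "n_transfers": n,
                        "replicate": rep,
                        "task_seed": task_seed,
                        "method": method,
                        "computed_time": res.computed_time,
                        "solve_seconds": res.solve_seconds,
                    }
                    if simulate:
                        row["simulated_time"] = simulate_execution(
                            res.worklist, sim_params
                        )
                    rows.append(row)
    raw = pd.DataFrame(rows)
    value_cols = ["computed_time"] + (["simulated_time"] if simulate else [])
    summary = (
        raw.groupby(
            ["source_format", "dest_format", "n_transfers", "method"],
            sort=False,
        )[value_cols]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c
        for c in summary.columns
    ]
    config = {
        "combos": list(combos),
        "multipliers": list(multipliers),
        "n_seeds": n_seeds,
        "methods": list(methods),
        "move_budget": move_budget,
        "seed": seed,
        "simulate": simulate,
    }
    return BenchmarkReport(raw, summary, config)


def percent_reduction(
    report: BenchmarkReport, method: str = "cvrp", baseline: str = "row-major"
) -> float:
    """Mean per-cell percent reduction of ``method`` vs ``baseline``.

    mean over cells of (1 - cost_method / cost_baseline), in percent; cells
    where the baseline cost is zero (nothing to save) are skipped.
    """
    piv = report.raw.pivot_table(
        index=["source_format", "dest_format", "n_transfers", "replicate"],
        columns="method",
        values="computed_time",
    )
    for name in (method, baseline):
        if name not in piv.columns:
            raise ValueError(f"method {name!r} not present in the report")
    mask = piv[baseline] > 0
    return float((100.0 * (1.0 - piv.loc[mask, method] / piv.loc[mask, baseline])).mean())


def run_budget_sweep(
    budgets: Sequence[int] = tuple(range(2, 71, 2)),
    n_tasks: int = 6,
    n_transfers: int = 2000,
    source_format: str = "96",
    dest_format: str = "96",
    budget_kind: str = "seconds",
    seed: int = 0,
    params: TimingParams | None = None,
) -> BenchmarkReport:
    """Routing cost as a function of the solver budget.

    The full-scale design solves 6 random 2000-transfer tasks between
    96-well plates at budgets of 2-70 s in 2 s steps.  With
    ``budget_kind="moves"`` the budgets are deterministic move-evaluation
    counts instead of wall-clock seconds (preferred for reproducible runs
    and used by the test suite at reduced scale).
    """
    if budget_kind not in ("seconds", "moves"):
        raise ValueError("budget_kind must be 'seconds' or 'moves'")
    if not budgets:
        raise ValueError("at least one budget is required")
    rows = []
    for t in range(n_tasks):
        task_seed = derive_seed(seed, "budget-task", t)
        task = random_task(source_format, dest_format, n_transfers, seed=task_seed)
        model = combined_distance(task, params)
        solve_seed = derive_seed(seed, "budget-solve", t)
        for budget in budgets:
            kwargs = (
                {"time_budget": float(budget), "move_budget": 2**62}
                if budget_kind == "seconds"
                else {"move_budget": int(budget)}
            )
            res = schedule(
                task, "cvrp", model, seed=solve_seed, **kwargs
            )
            rows.append(
                {
                    "task": t,
                    "task_seed": task_seed,
                    "n_transfers": n_transfers,
                    "budget": budget,
                    "budget_kind": budget_kind,
                    "computed_time": res.computed_time,
                    "solve_seconds": res.solve_seconds,
                }
            )
    raw = pd.DataFrame(rows)
    summary = (
        raw.groupby("budget", sort=True)["computed_time"]
        .agg(["mean", "std"])
        .reset_index()
    )
    config = {
        "budgets": list(budgets),
        "budget_kind": budget_kind,
        "n_tasks": n_tasks,
        "n_transfers": n_transfers,
        "combo": [source_format, dest_format],
        "seed": seed,
    }
    return BenchmarkReport(raw, summary, config)


def run_campaign(
    tasks: Sequence,
    source_plate: str = "96",
    dest_plate: str = "96",
    methods: Sequence[str] = DEFAULT_METHODS,
    move_budget: int = DEFAULT_MOVE_BUDGET,
    seed: int = 0,
    params: TimingParams | None = None,
    simulate: bool = True,
    sim_params: SimParams | None = None,
) -> BenchmarkReport:
    """Schedule every iteration of a campaign with every method.

    ``tasks`` may mix :class:`TaskMatrix` instances and paths to triplet
    work-list CSVs (e.g. the per-iteration files of a screening campaign).
    The summary holds per-method totals; totals are sums of the
    per-iteration values.
    """
    methods = _check_methods(methods)
    resolved: list[TaskMatrix] = []
    for item in tasks:
        if isinstance(item, TaskMatrix):
            resolved.append(item)
        elif isinstance(item, WorkList):
            resolved.append(item.task)
        else:
            resolved.append(read_worklist_csv(item, source_plate, dest_plate).task)
    rows = []
    for it, task in enumerate(resolved):
        model = combined_distance(task, params)
        for method in methods:
            res = schedule(
                task,
                method,
                model,
                move_budget=move_budget,
                seed=derive_seed(seed, "campaign", it, method),
            )
            row = {
                "iteration": it,
                "m": task.m,
                "method": method,
                "computed_time": res.computed_time,
                "solve_seconds": res.solve_seconds,
            }
            if simulate:
                row["simulated_time"] = simulate_execution(res.worklist, sim_params)
            rows.append(row)
    raw = pd.DataFrame(rows)
    value_cols = ["computed_time"] + (["simulated_time"] if simulate else [])
    summary = raw.groupby("method", sort=False)[value_cols].sum().reset_index()
    config = {
        "n_iterations": len(resolved),
        "methods": list(methods),
        "move_budget": move_budget,
        "seed": seed,
    }
    return BenchmarkReport(raw, summary, config)


def generate_campaign_tasks(
    seed: int = 0,
    source_format: str = "96",
    dest_format: str = "96",
    n_rounds: int = 9,
    components_per_well: int = 4,
    reserved_rows: int = 8,
    zipf_exponent: float = 1.2,
    control_volume: float = 50.0,
) -> list[TaskMatrix]:
    """Synthetic screening campaign emulating an adaptive blending workflow.

    Round 0 is a diagonal control task with the first ``reserved_rows``
    source rows of the task matrix empty (source well i -> destination well
    i).  Round 1 draws uniformly random source components for each active
    destination well.  Later rounds skew source-well usage with Zipf-like
    weights over a fixed random source ranking, emulating how an optimiser
    increasingly favours certain stock solutions; destination wells below
    ``reserved_rows`` stay free for controls throughout.
    """
    src, dst = get_plate(source_format), get_plate(dest_format)
    if src.n_wells != dst.n_wells:
        raise ValueError("campaign generator expects same-size plates")
    rng = np.random.default_rng(derive_seed(seed, "campaign-gen"))
    active = np.arange(reserved_rows + 1, dst.n_wells + 1)
    tasks = [
        TaskMatrix.from_jobs(
            src,
            dst,
            [TransferJob(int(w), int(w), control_volume) for w in active],
        )
    ]
    ranking = rng.permutation(src.n_wells)  # favoured-source order, fixed
    weights = 1.0 / (np.arange(1, src.n_wells + 1) ** zipf_exponent)
    skewed = np.empty(src.n_wells)
    skewed[ranking] = weights / weights.sum()
    uniform = np.full(src.n_wells, 1.0 / src.n_wells)
    for rnd in range(1, n_rounds):
        p = uniform if rnd == 1 else skewed
        jobs: dict[tuple[int, int], float] = {}
        for w in active:
            sources = rng.choice(
                src.n_wells, size=components_per_well, replace=False, p=p
            )
            for s in sources:
                jobs[(int(s) + 1, int(w))] = float(rng.uniform(1.0, 100.0))
        tasks.append(
            TaskMatrix.from_jobs(
                src, dst, [TransferJob(s, d, v) for (s, d), v in jobs.items()]
            )
        )
    return tasks
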