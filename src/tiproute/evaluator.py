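"""Execution-time evaluation: the routing objective and an event simulator.

Two ways of timing a work list:

* :func:`computed_execution_time` — the routing objective a scheduler
  minimizes: the sum of D' entries over consecutive within-cycle job pairs.
  The first job of every cycle enters from the zero-cost depot.
* :func:`simulate_execution` — an event-level simulator of the physical
  run.  Within a cycle, the aspiration pass splits jobs into maximal runs of
  consecutive tip-adjacent source wells; each run is one stroke (lower,
  aspirate in parallel, raise, move) whose aspirate time is the run's
  maximum volume over the rate.  The dispense pass is analogous on the
  destination plate, and each cycle adds one source-to-destination arm
  transit plus a wash.

The proxy charges the successor's volume on non-adjacent transitions whereas
the simulator charges each stroke's group maximum, so the two are not
algebraically identical — the benchmark suite checks that they correlate
strongly instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labware import adjacency_matrix
from .tasks import WorkList, expected_cycles
from .distance import JobDistanceModel

__all__ = [
    "FeasibilityError",
    "FeasibilityReport",
    "SimParams",
    "TECAN_LIKE",
    "verify_feasibility",
    "computed_execution_time",
    "simulate_execution",
]


class FeasibilityError(ValueError):
    """Work list violates the scheduling constraints."""


@dataclass(frozen=True)
class FeasibilityReport:
    ok: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class SimParams:
    """Event-simulator timing constants (seconds; rates in uL/s).

    Defaults split the unit-action aggregate of
    :class:`~tiproute.distance.TimingParams` (t1 + t3 + t4 = 1 s) and keep
    wash and arm transit at zero so simulator and routing objective can be
    compared cleanly; ``TECAN_LIKE`` is an illustrative preset with
    realistic per-cycle overheads.
    """

    t1: float = 0.4  # tip lowering
    t3: float = 0.4  # tip raising
    t4: float = 0.2  # arm move to the next position within a pass
    q_src: float = 100.0
    q_dst: float = 100.0
    wash: float = 0.0  # per-cycle wash/tip change
    arm_transit: float = 0.0  # per-cycle source->destination move

    def __post_init__(self) -> None:
        for name in ("t1", "t3", "t4", "wash", "arm_transit"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be non-negative")
        for name in ("q_src", "q_dst"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SimParams.{name} must be strictly positive")


TECAN_LIKE = SimParams(
    t1=1.2, t3=1.2, t4=0.6, q_src=100.0, q_dst=100.0, wash=25.0, arm_transit=3.0
)


def verify_feasibility(worklist: WorkList) -> FeasibilityReport:
    """Check the plan constraints: permutation, capacity, cycle count.

    Every job scheduled exactly once; no cycle exceeds the tip capacity; the
    number of cycles equals K = ceil(m / capacity); no self-loops (a job
    following itself).  Returns a report rather than raising.
    """
    violations: list[str] = []
    m = worklist.task.m
    order = list(worklist.order)
    if worklist.cycles is not None and [
        i for cyc in worklist.cycles for i in cyc
    ] != order:
        violations.append("explicit cycles do not concatenate to the job order")
    if sorted(order) != list(range(m)):
        counts = np.bincount(
            [i for i in order if 0 <= i < m], minlength=m
        )
        dup = np.flatnonzero(counts > 1)
        missing = np.flatnonzero(counts == 0)
        bad = [i for i in order if not 0 <= i < m]
        if len(dup):
            violations.append(
                f"each job must be completed exactly once; repeated jobs {dup.tolist()}"
            )
        if len(missing):
            violations.append(f"jobs never scheduled: {missing.tolist()}")
        if bad:
            violations.append(f"unknown job indices: {sorted(set(bad))}")
    for k, cyc in enumerate(worklist.cycle_list, start=1):
        if len(cyc) > worklist.capacity:
            violations.append(
                f"cycle {k} has {len(cyc)} jobs, exceeding tip capacity "
                f"{worklist.capacity}"
            )
        for a, b in zip(cyc, cyc[1:]):
            if a == b:
                violations.append(f"cycle {k} contains a self-loop at job {a}")
    K = expected_cycles(m, worklist.capacity)
    if worklist.n_cycles != K:
        violations.append(
            f"expected K = ceil({m}/{worklist.capacity}) = {K} cycles, "
            f"got {worklist.n_cycles}"
        )
    return FeasibilityReport(not violations, tuple(violations))


def _require_feasible(worklist: WorkList) -> None:
    report = verify_feasibility(worklist)
    if not report.ok:
        raise FeasibilityError("; ".join(report.violations))


def computed_execution_time(worklist: WorkList, model: JobDistanceModel) -> float:
    """Routing objective: sum of D' over consecutive within-cycle pairs.

    Cycle-opening transitions come from the depot and cost zero.  Raises
    :class:`FeasibilityError` on an infeasible plan.
    """
    _require_feasible(worklist)
    if model.task is not worklist.task and model.task != worklist.task:
        raise ValueError("distance model was built for a different task")
    total = 0.0
    dd = model.dprime
    for cyc in worklist.cycle_list:
        if len(cyc) > 1:
            a = np.asarray(cyc)
            total += float(dd[a[:-1] + 1, a[1:] + 1].sum())
    return total


def _pass_time(
    wells: np.ndarray,
    volumes: np.ndarray,
    D: np.ndarray,
    t134: float,
    rate: float,
) -> float:
    """One aspiration or dispense pass over a cycle's jobs.

    Jobs are split into maximal runs where each successive well is
    tip-adjacent (distance 0) to its predecessor; each run is one parallel
    stroke costing t1 + max(v)/q + t3 + t4.
    """
    total = 0.0
    start = 0
    for i in range(1, len(wells)):
        if D[wells[i - 1] - 1, wells[i] - 1]:  # non-adjacent: new stroke
            total += t134 + float(volumes[start:i].max()) / rate
            start = i
    if len(wells):
        total += t134 + float(volumes[start:].max()) / rate
    return total


def simulate_execution(worklist: WorkList, sim: SimParams | None = None) -> float:
    """Event-level execution time of a feasible work list, in seconds."""
    sim = sim or SimParams()
    _require_feasible(worklist)
    task = worklist.task
    D_src = adjacency_matrix(task.source_plate)
    D_dst = adjacency_matrix(task.dest_plate)
    t134 = sim.t1 + sim.t3 + sim.t4
    total = 0.0
    for cyc in worklist.cycle_list:
        idx = np.asarray(cyc)
        if not len(idx):
            continue
        vols = task.volumes[idx]
        total += _pass_time(task.source_wells[idx], vols, D_src, t134, sim.q_src)
        total += sim.arm_transit
        total += _pass_time(task.dest_wells[idx], vols, D_dst, t134, sim.q_dst)
        total += sim.wash
    return total
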