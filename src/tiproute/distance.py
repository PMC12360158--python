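"""Job-level distance matrices and the time-weighted cost matrix with depot.

Well-level adjacency (:func:`tiproute.labware.adjacency_matrix`) is lifted to
job level: for jobs i, j,

    dbar_src[i, j] = D_src[source(i), source(j)]
    dbar_dst[i, j] = D_dst[dest(i),  dest(j)]

equivalently S @ D_src @ S.T and E @ D_dst @ E.T with the incidence matrices
(S, E).  These binary gates are combined with per-action times into the
routing cost matrix D' of shape (m+1, m+1):

    D'[i, j] = dbar_src[i, j] * (t134_src + v_j / q_src)
             + dbar_dst[i, j] * (t134_dst + v_j / q_dst)      (i, j >= 1)

where t134 is the lower+raise+move time of one unit action, v_j the volume of
the successor job j, and q the aspiration/dispense rate, so v_j / q is the
aspirate (or dispense) time t2.  If j is adjacent to i on a plate the tips
act simultaneously there and that plate contributes no extra time.  Index 0
is a dummy depot job (v_0 = 0) with zero distance to and from every job, so
starting or ending a cycle is free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labware import adjacency_matrix
from .tasks import TaskMatrix

__all__ = [
    "TimingParams",
    "JobDistanceModel",
    "job_distances",
    "combined_distance",
]

#: Dense D' above this many jobs gets large; warn rather than fail.
_MEMORY_GUARD_JOBS = 15_000


@dataclass(frozen=True)
class TimingParams:
    """Per-action timing constants of the cost model.

    ``t134_src``/``t134_dst`` (s) aggregate tip lowering (t1), raising (t3)
    and arm movement (t4) for one aspiration/dispense stroke; ``q_src`` and
    ``q_dst`` (uL/s) are the aspiration and dispense rates, so a transfer of
    v uL adds v/q of rate-limited time (t2) per plate.
    """

    t134_src: float = 1.0
    t134_dst: float = 1.0
    q_src: float = 100.0
    q_dst: float = 100.0

    def __post_init__(self) -> None:
        for name in ("t134_src", "t134_dst", "q_src", "q_dst"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TimingParams.{name} must be strictly positive")


@dataclass(frozen=True)
class JobDistanceModel:
    """Job adjacency gates plus the combined (m+1) x (m+1) cost matrix D'.

    Row and column 0 of ``dprime`` are the dummy depot (all zero); the
    diagonal is never traversed (no self-loops).
    """

    task: TaskMatrix
    params: TimingParams
    variant: str
    dbar_src: np.ndarray
    dbar_dst: np.ndarray
    dprime: np.ndarray

    @property
    def m(self) -> int:
        return self.task.m

    def integer_distances(self, scale: int = 1000) -> np.ndarray:
        """D' scaled and rounded for integer-only solver backends.

        Reported computed execution times are always the unscaled float
        sums; this matrix exists only for backends that require integers.
        """
        return np.rint(self.dprime * scale).astype(np.int64)


def job_distances(task: TaskMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Lift well adjacency to the m x m job matrices (dbar_src, dbar_dst)."""
    D_src = adjacency_matrix(task.source_plate)
    D_dst = adjacency_matrix(task.dest_plate)
    s = task.source_wells - 1
    d = task.dest_wells - 1
    return D_src[np.ix_(s, s)].copy(), D_dst[np.ix_(d, d)].copy()


def combined_distance(
    task: TaskMatrix,
    params: TimingParams | None = None,
    variant: str = "multiplicative",
) -> JobDistanceModel:
    """Build D' from the task geometry and timing parameters.

    ``variant="multiplicative"`` (default) gates the full unit-action cost,
    including the volume term, by adjacency — adjacent consecutive jobs are
    free.  ``variant="additive"`` gates only the t134 term and always charges
    the volume time (kept for sensitivity analyses); the depot row/column is
    forced to zero in both variants.
    """
    params = params or TimingParams()
    if variant not in ("multiplicative", "additive"):
        raise ValueError(f"unknown distance variant {variant!r}")
    m = task.m
    if m > _MEMORY_GUARD_JOBS:
        warnings.warn(
            f"dense distance matrix for m={m} jobs needs about "
            f"{(m + 1) ** 2 * 8 / 1e9:.1f} GB",
            ResourceWarning,
            stacklevel=2,
        )
    dbar_src, dbar_dst = job_distances(task)
    unit_src = params.t134_src + task.volumes / params.q_src  # per successor j
    unit_dst = params.t134_dst + task.volumes / params.q_dst
    if variant == "multiplicative":
        core = dbar_src * unit_src[None, :] + dbar_dst * unit_dst[None, :]
    else:
        core = (
            dbar_src * params.t134_src
            + dbar_dst * params.t134_dst
            + (task.volumes / params.q_src + task.volumes / params.q_dst)[None, :]
            * np.ones((m, 1))
        )
    dprime = np.zeros((m + 1, m + 1))
    dprime[1:, 1:] = core
    return JobDistanceModel(task, params, variant, dbar_src, dbar_dst, dprime)
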