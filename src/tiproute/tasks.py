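"""Transfer tasks: the task matrix, work lists, random generation, CSV I/O.

A liquid-transfer task between a source and a destination plate is a sparse
matrix T of shape (n_src, n_dst) whose non-zero entry ``T[a, b] = v`` means
"aspirate v uL from source well a, dispense into destination well b" — one
*job*.  Jobs are kept in a canonical order: row-major over (source_well,
dest_well), which is exactly the scan order of ``np.argwhere(T)`` and the
execution order of the row-major baseline scheduler.

A *work list* is an ordered job sequence executed in cycles of at most 8
transfers (aspirate all, move the arm, dispense all, wash); tips are
assigned in ascending order within each cycle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import cached_property
from math import ceil
from typing import Iterable, Sequence

import numpy as np

from .labware import PlateFormat, get_plate

__all__ = [
    "TaskError",
    "WorklistFormatError",
    "TransferJob",
    "TaskMatrix",
    "WorkList",
    "incidence_matrices",
    "random_task",
    "read_worklist_csv",
    "write_worklist_csv",
    "read_task_matrix_csv",
    "write_task_matrix_csv",
]

#: Number of independently addressable pipette tips, hence jobs per cycle.
DEFAULT_CAPACITY = 8


class TaskError(ValueError):
    """Invalid transfer task."""


class WorklistFormatError(TaskError):
    """Malformed work-list or task-matrix file."""


@dataclass(frozen=True)
class TransferJob:
    """One aspirate/dispense transfer: (source well, destination well, uL)."""

    source_well: int
    dest_well: int
    volume: float


@dataclass(frozen=True)
class TaskMatrix:
    """A transfer task with jobs stored in canonical row-major order."""

    source_plate: PlateFormat
    dest_plate: PlateFormat
    jobs: tuple[TransferJob, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        prev: tuple[int, int] | None = None
        for job in self.jobs:
            if not 1 <= job.source_well <= self.source_plate.n_wells:
                raise TaskError(
                    f"source well {job.source_well} outside plate "
                    f"{self.source_plate.name!r} (1..{self.source_plate.n_wells})"
                )
            if not 1 <= job.dest_well <= self.dest_plate.n_wells:
                raise TaskError(
                    f"destination well {job.dest_well} outside plate "
                    f"{self.dest_plate.name!r} (1..{self.dest_plate.n_wells})"
                )
            if not job.volume > 0:
                raise TaskError(
                    f"volume must be positive, got {job.volume} for "
                    f"({job.source_well} -> {job.dest_well})"
                )
            key = (job.source_well, job.dest_well)
            if key in seen:
                raise TaskError(f"duplicate (source, destination) pair {key}")
            seen.add(key)
            if prev is not None and key < prev:
                raise TaskError(
                    "jobs must be in canonical row-major order; "
                    "use TaskMatrix.from_jobs to sort"
                )
            prev = key

    @classmethod
    def from_jobs(
        cls,
        source_plate: "PlateFormat | str | int",
        dest_plate: "PlateFormat | str | int",
        jobs: Iterable[TransferJob | tuple],
    ) -> "TaskMatrix":
        """Build a task, canonicalizing the job order (insertion-order free)."""
        norm = [
            j if isinstance(j, TransferJob) else TransferJob(int(j[0]), int(j[1]), float(j[2]))
            for j in jobs
        ]
        norm.sort(key=lambda j: (j.source_well, j.dest_well))
        return cls(get_plate(source_plate), get_plate(dest_plate), tuple(norm))

    @property
    def m(self) -> int:
        """Number of jobs (non-zero entries of T)."""
        return len(self.jobs)

    @cached_property
    def source_wells(self) -> np.ndarray:
        a = np.array([j.source_well for j in self.jobs], dtype=np.intp)
        a.setflags(write=False)
        return a

    @cached_property
    def dest_wells(self) -> np.ndarray:
        a = np.array([j.dest_well for j in self.jobs], dtype=np.intp)
        a.setflags(write=False)
        return a

    @cached_property
    def volumes(self) -> np.ndarray:
        a = np.array([j.volume for j in self.jobs], dtype=float)
        a.setflags(write=False)
        return a

    def to_dense(self) -> np.ndarray:
        """Dense T of shape (n_src, n_dst); rows/cols 0-based by well - 1."""
        T = np.zeros((self.source_plate.n_wells, self.dest_plate.n_wells))
        T[self.source_wells - 1, self.dest_wells - 1] = self.volumes
        return T

    @classmethod
    def from_dense(
        cls,
        source_plate: "PlateFormat | str | int",
        dest_plate: "PlateFormat | str | int",
        T: np.ndarray,
    ) -> "TaskMatrix":
        src, dst = get_plate(source_plate), get_plate(dest_plate)
        T = np.asarray(T)
        if T.shape != (src.n_wells, dst.n_wells):
            raise TaskError(
                f"task matrix shape {T.shape} does not match plates "
                f"({src.n_wells}, {dst.n_wells})"
            )
        rows, cols = np.nonzero(T)
        jobs = [
            TransferJob(int(a) + 1, int(b) + 1, float(T[a, b]))
            for a, b in zip(rows, cols)
        ]
        return cls.from_jobs(src, dst, jobs)


@dataclass(frozen=True)
class WorkList:
    """An ordered execution plan over a task's jobs.

    ``order`` holds 0-based indices into ``task.jobs`` in execution order.
    Cycles are the consecutive blocks of ``capacity`` jobs unless explicit
    ``cycles`` are given (used to represent, and then reject, infeasible
    plans).  Feasibility is *not* enforced at construction; see
    :func:`tiproute.evaluator.verify_feasibility`.
    """

    task: TaskMatrix
    order: tuple[int, ...]
    capacity: int = DEFAULT_CAPACITY
    cycles: tuple[tuple[int, ...], ...] | None = field(default=None)

    @property
    def m(self) -> int:
        return len(self.order)

    @property
    def cycle_list(self) -> tuple[tuple[int, ...], ...]:
        if self.cycles is not None:
            return self.cycles
        c = self.capacity
        return tuple(
            tuple(self.order[i : i + c]) for i in range(0, len(self.order), c)
        )

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_list)

    def ordered_jobs(self) -> list[TransferJob]:
        return [self.task.jobs[i] for i in self.order]

    @classmethod
    def from_cycles(
        cls,
        task: TaskMatrix,
        cycles: Sequence[Sequence[int]],
        capacity: int = DEFAULT_CAPACITY,
    ) -> "WorkList":
        order = tuple(int(i) for cyc in cycles for i in cyc)
        return cls(task, order, capacity, tuple(tuple(int(i) for i in c) for c in cycles))


def expected_cycles(m: int, capacity: int = DEFAULT_CAPACITY) -> int:
    """K = ceil(m / capacity): cycles needed to execute m jobs."""
    return ceil(m / capacity) if m else 0


def incidence_matrices(task: TaskMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary incidence matrices (S, E) of T in canonical job order.

    ``S[i, a-1] == 1`` iff job i aspirates from source well a, and
    ``E[i, b-1] == 1`` iff job i dispenses into destination well b; each row
    of S and E therefore has exactly one 1.
    """
    S = np.zeros((task.m, task.source_plate.n_wells), dtype=np.uint8)
    E = np.zeros((task.m, task.dest_plate.n_wells), dtype=np.uint8)
    idx = np.arange(task.m)
    S[idx, task.source_wells - 1] = 1
    E[idx, task.dest_wells - 1] = 1
    return S, E


def random_task(
    source_plate: "PlateFormat | str | int",
    dest_plate: "PlateFormat | str | int",
    n_transfers: int,
    volume_range: tuple[float, float] = (1.0, 100.0),
    seed: "int | np.random.Generator | None" = None,
    integer_volumes: bool = False,
) -> TaskMatrix:
    """Uniformly random transfer task.

    Exactly ``n_transfers`` distinct (source, destination) cells of the task
    matrix are drawn uniformly without replacement; each receives an i.i.d.
    volume, uniform on ``volume_range`` (default 1–100 uL).  A fixed ``seed``
    yields an identical task.
    """
    src, dst = get_plate(source_plate), get_plate(dest_plate)
    capacity = src.n_wells * dst.n_wells
    if not 0 <= n_transfers <= capacity:
        raise TaskError(
            f"n_transfers={n_transfers} exceeds task-matrix capacity "
            f"{src.n_wells} x {dst.n_wells} = {capacity}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flat = rng.choice(capacity, size=n_transfers, replace=False)
    flat.sort()  # canonical row-major order over (source, dest)
    lo, hi = volume_range
    if not 0 < lo <= hi:
        raise TaskError(f"invalid volume range {volume_range}")
    if integer_volumes:
        vols = rng.integers(int(lo), int(hi), size=n_transfers, endpoint=True)
    else:
        vols = rng.uniform(lo, hi, size=n_transfers)
    jobs = tuple(
        TransferJob(int(f // dst.n_wells) + 1, int(f % dst.n_wells) + 1, float(v))
        for f, v in zip(flat, vols)
    )
    return TaskMatrix(src, dst, jobs)


# ---------------------------------------------------------------------------
# Work-list CSV I/O: one "source,destination,volume" triplet per row, the
# format liquid-handler control software parses.  Reading preserves row
# order; writing is bit-stable (repr round-trips floats exactly).
# ---------------------------------------------------------------------------


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_worklist_csv(
    path,
    source_plate: "PlateFormat | str | int",
    dest_plate: "PlateFormat | str | int",
    capacity: int = DEFAULT_CAPACITY,
    merge_duplicates: bool = False,
) -> WorkList:
    """Parse a triplet work-list CSV, preserving the supplied job order.

    A single header line is auto-detected (non-numeric first field).
    Duplicate (source, destination) pairs are rejected — the matrix
    representation cannot encode them — unless ``merge_duplicates`` is set,
    which sums their volumes into the first occurrence.
    """
    src, dst = get_plate(source_plate), get_plate(dest_plate)
    entries: list[tuple[int, int, float]] = []  # file order
    index_of: dict[tuple[int, int], int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and not _is_number(row[0].strip()):
                continue  # header
            if len(row) < 3:
                raise WorklistFormatError(
                    f"{path}: line {lineno}: expected 3 fields "
                    f"(source, destination, volume), got {len(row)}"
                )
            try:
                s = int(row[0].strip())
                d = int(row[1].strip())
                v = float(row[2].strip())
            except ValueError as exc:
                raise WorklistFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
            if not 1 <= s <= src.n_wells:
                raise WorklistFormatError(
                    f"{path}: line {lineno}: source position {s} outside "
                    f"plate {src.name!r} (1..{src.n_wells})"
                )
            if not 1 <= d <= dst.n_wells:
                raise WorklistFormatError(
                    f"{path}: line {lineno}: destination position {d} outside "
                    f"plate {dst.name!r} (1..{dst.n_wells})"
                )
            if not v > 0:
                raise WorklistFormatError(
                    f"{path}: line {lineno}: volume must be positive, got {v}"
                )
            key = (s, d)
            if key in index_of:
                if merge_duplicates:
                    i = index_of[key]
                    entries[i] = (s, d, entries[i][2] + v)
                    continue
                raise WorklistFormatError(
                    f"{path}: line {lineno}: duplicate transfer {key}; "
                    "pass merge_duplicates=True (--merge-duplicates) to sum"
                )
            index_of[key] = len(entries)
            entries.append((s, d, v))
    task = TaskMatrix.from_jobs(src, dst, entries)
    canonical = {(j.source_well, j.dest_well): i for i, j in enumerate(task.jobs)}
    order = tuple(canonical[(s, d)] for s, d, _ in entries)
    return WorkList(task, order, capacity)


def write_worklist_csv(worklist: WorkList, path, header: bool = True) -> None:
    """Write the work list as triplet CSV rows in execution order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header:
            fh.write("source,destination,volume\n")
        for job in worklist.ordered_jobs():
            fh.write(f"{job.source_well},{job.dest_well},{job.volume!r}\n")


def read_task_matrix_csv(
    path,
    source_plate: "PlateFormat | str | int",
    dest_plate: "PlateFormat | str | int",
) -> TaskMatrix:
    """Read a dense task-matrix CSV: rows = source wells, cols = dest wells."""
    src, dst = get_plate(source_plate), get_plate(dest_plate)
    try:
        T = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise WorklistFormatError(f"{path}: {exc}") from None
    return TaskMatrix.from_dense(src, dst, T)


def write_task_matrix_csv(task: TaskMatrix, path) -> None:
    np.savetxt(path, task.to_dense(), delimiter=",", fmt="%.17g")
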