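"""Microplate geometry, column-major well indexing, and tip-adjacency distances.

Wells are numbered 1-based in column-major order: A1 is well 1, B1 is well 2,
and position = (col - 1) * n_rows + row.  An 8-channel pipette with
individually addressable tips spans the short axis of the plate (the rows
within one column), so two wells can be served by neighbouring tips in a
single stroke only when they lie in the same column with the second exactly
``adjacency_stride`` rows below the first.  The stride accounts for well
pitch: on 384-well plates tips reach every other well, on 1536-well plates
every fourth well.

The relation is directional.  Tips are assigned in ascending order within a
cycle, so the well one stride *below* can be reached by the next tip, while
the well above cannot: within a column, row 3 pairs with row 4 but not with
row 2.  ``adjacency_matrix`` encodes this as a binary distance matrix D where
``D[a, b] == 0`` iff well b can be accessed simultaneously right after well a.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from string import ascii_uppercase

import numpy as np

__all__ = [
    "LabwareError",
    "PlateFormat",
    "PLATE_REGISTRY",
    "get_plate",
    "register_plate",
    "well_index",
    "well_coords",
    "well_name",
    "adjacency_matrix",
]


class LabwareError(ValueError):
    """Invalid plate geometry or out-of-range well coordinates."""


@dataclass(frozen=True)
class PlateFormat:
    """An SBS-footprint labware format.

    Parameters
    ----------
    name:
        Identifier used on the command line and in reports (e.g. ``"96"``).
    n_rows:
        Wells along the tip axis (the short plate edge).
    n_cols:
        Wells along the long plate edge.
    adjacency_stride:
        Row offset within a column at which neighbouring tips can access
        wells simultaneously (1 for 12/24/96-well, 2 for 384, 4 for 1536).
    """

    name: str
    n_rows: int
    n_cols: int
    adjacency_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LabwareError(
                f"plate {self.name!r}: n_rows and n_cols must be positive"
            )
        if not 1 <= self.adjacency_stride < self.n_rows:
            raise LabwareError(
                f"plate {self.name!r}: adjacency_stride must satisfy "
                f"1 <= stride < n_rows ({self.n_rows})"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


#: The five standard formats: name -> (rows, cols, stride).
_STANDARD = {
    "12": (3, 4, 1),
    "24": (4, 6, 1),
    "96": (8, 12, 1),
    "384": (16, 24, 2),
    "1536": (32, 48, 4),
}

PLATE_REGISTRY: dict[str, PlateFormat] = {
    name: PlateFormat(name, r, c, s) for name, (r, c, s) in _STANDARD.items()
}


def get_plate(fmt: "PlateFormat | str | int") -> PlateFormat:
    """Resolve a plate format by instance, registry name, or well count."""
    if isinstance(fmt, PlateFormat):
        return fmt
    key = str(fmt)
    try:
        return PLATE_REGISTRY[key]
    except KeyError:
        raise LabwareError(
            f"unknown plate format {fmt!r}; registered: "
            f"{sorted(PLATE_REGISTRY)}"
        ) from None


def register_plate(
    name: str, n_rows: int, n_cols: int, adjacency_stride: int = 1
) -> PlateFormat:
    """Register a custom labware format (e.g. a vial holder) by name."""
    plate = PlateFormat(str(name), int(n_rows), int(n_cols), int(adjacency_stride))
    PLATE_REGISTRY[plate.name] = plate
    return plate


def well_index(plate: PlateFormat, row: int, col: int) -> int:
    """1-based column-major well position of (row, col), both 1-based."""
    if not 1 <= row <= plate.n_rows or not 1 <= col <= plate.n_cols:
        raise LabwareError(
            f"plate {plate.name!r}: (row={row}, col={col}) outside "
            f"{plate.n_rows}x{plate.n_cols} layout"
        )
    return (col - 1) * plate.n_rows + row


def well_coords(plate: PlateFormat, position: int) -> tuple[int, int]:
    """Inverse of :func:`well_index`: position -> (row, col), all 1-based."""
    if not 1 <= position <= plate.n_wells:
        raise LabwareError(
            f"plate {plate.name!r}: position {position} outside 1..{plate.n_wells}"
        )
    row = (position - 1) % plate.n_rows + 1
    col = (position - 1) // plate.n_rows + 1
    return row, col


def well_name(plate: PlateFormat, position: int) -> str:
    """Human-readable label such as ``"A1"`` (rows lettered A, B, ...)."""
    row, col = well_coords(plate, position)
    label = ""
    r = row - 1
    while True:
        label = ascii_uppercase[r % 26] + label
        r = r // 26 - 1
        if r < 0:
            break
    return f"{label}{col}"


@lru_cache(maxsize=None)
def adjacency_matrix(plate: PlateFormat) -> np.ndarray:
    """Directional binary well-distance matrix D of shape (n_wells, n_wells).

    ``D[a-1, b-1] == 0`` iff wells a and b (1-based positions) lie in the
    same column with ``row(b) == row(a) + adjacency_stride``; all other
    entries, including the diagonal and the reversed direction, are 1.  The
    diagonal is 1 because two tips can never occupy the same well
    simultaneously.  The returned array is read-only and cached per format.
    """
    n = plate.n_wells
    D = np.ones((n, n), dtype=np.uint8)
    pos = np.arange(1, n + 1)
    row = (pos - 1) % plate.n_rows + 1
    ok = row <= plate.n_rows - plate.adjacency_stride
    a = pos[ok] - 1
    D[a, a + plate.adjacency_stride] = 0
    D.setflags(write=False)
    return D
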