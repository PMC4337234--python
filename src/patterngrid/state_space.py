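"""State-space grids and the dispersion statistic.

Each coded session is a point (positive activation, negative activation)
on a 5x5 grid (both axes 0-4).  Dispersion measures how widely a patient's
sessions spread over the grid within a treatment phase:

    dispersion = 1 - (n * sum_i (d_i / D)^2 - 1) / (n - 1)

where ``d_i`` is the number of sessions in cell i, ``D`` the total number
of sessions in the phase, and ``n`` the total number of cells in the grid
(25 for the 5x5 activation grid) — occupied or not.  The statistic is 0
when every session falls in one cell and reaches 1.00 when sessions are
spread evenly over all n cells; it is algebraically a normalized Simpson
diversity index, n (1 - sum p_i^2) / (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError, DegenerateDataError


@dataclass(frozen=True)
class StateSpaceGrid:
    """Occupancy counts of activation points for one patient-phase."""

    counts: Mapping[tuple[int, int], int]
    n_rows: int = 5
    n_cols: int = 5
    points: tuple = field(default=(), compare=False)  # original order kept

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ContractError("grid must have at least 2 cells")
        for (x, y), c in self.counts.items():
            if c < 0:
                raise ContractError(f"negative count in cell ({x}, {y})")
            if not (0 <= x < self.n_cols and 0 <= y < self.n_rows):
                raise ContractError(
                    f"cell ({x}, {y}) outside the {self.n_cols}x{self.n_rows} grid"
                )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def D(self) -> int:
        """Total number of observations (coded sessions)."""
        return int(sum(self.counts.values()))

    @property
    def degenerate(self) -> bool:
        return self.D <= 1


@dataclass(frozen=True)
class DispersionScore:
    value: float
    D: int
    n_cells: int
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def build_grid(
    points: Sequence[tuple[int, int]],
    n_rows: int = 5,
    n_cols: int = 5,
) -> StateSpaceGrid:
    """Tally ordered (x, y) = (positive, negative) activation pairs.

    Point order is retained on the grid for trajectory export; an empty
    point list yields a degenerate D = 0 grid.
    """
    counts: dict[tuple[int, int], int] = {}
    for p in points:
        x, y = int(p[0]), int(p[1])
        if not (0 <= x < n_cols and 0 <= y < n_rows):
            raise ContractError(
                f"point ({p[0]}, {p[1]}) outside the {n_cols}x{n_rows} grid"
            )
        counts[(x, y)] = counts.get((x, y), 0) + 1
    return StateSpaceGrid(
        counts=counts,
        n_rows=n_rows,
        n_cols=n_cols,
        points=tuple((int(p[0]), int(p[1])) for p in points),
    )


def dispersion(grid: StateSpaceGrid) -> DispersionScore:
    """Normalized spread of grid occupancy in [0, 1].

    Uses the full cell count of the grid (n = 25 by default), so the
    maximum 1.00 is attained only when the D observations are spread
    evenly over every cell.  D = 1 grids return 0 (formula-consistent)
    but are flagged degenerate.
    """
    D = grid.D
    if D == 0:
        raise DegenerateDataError("dispersion undefined on an empty grid (D = 0)")
    n = grid.n_cells
    d = np.fromiter(grid.counts.values(), dtype=float)
    value = 1.0 - (n * float(np.sum((d / D) ** 2)) - 1.0) / (n - 1.0)
    # guard against representation error only; the formula itself is in [0, 1]
    value = min(1.0, max(0.0, value))
    return DispersionScore(value=value, D=D, n_cells=n, degenerate=grid.degenerate)


def dispersion_simpson(grid: StateSpaceGrid) -> float:
    """Simpson-identity form n(1 - sum p_i^2)/(n - 1); oracle for testing."""
    D = grid.D
    if D == 0:
        raise DegenerateDataError("dispersion undefined on an empty grid (D = 0)")
    n = grid.n_cells
    p = np.fromiter(grid.counts.values(), dtype=float) / D
    return n * (1.0 - float(np.sum(p**2))) / (n - 1.0)


def grid_summary(grid: StateSpaceGrid) -> dict:
    """Cells visited, modal cell (ties: lowest x then lowest y), proportions."""
    if grid.D == 0:
        return {"cells_visited": 0, "modal_cell": None, "proportions": {}}
    cells = sorted(grid.counts)
    max_count = max(grid.counts.values())
    modal = min(c for c in cells if grid.counts[c] == max_count)
    props = {c: grid.counts[c] / grid.D for c in cells}
    return {
        "cells_visited": len(cells),
        "modal_cell": modal,
        "proportions": props,
    }
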