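"""The 3D bubble grid: coordinates, movement actions and performance zones.

The virtual reaching space is a rectangular box of unit cells (default
8 x 8 x 4 = 256).  A bubble occupies exactly one cell; the agent moves it
one cell at a time along one of six directions.  Every cell belongs to one
of three performance zones: zone 1 is the small, challenging target block
in the far upper-right corner, zone 2 the difficult surround of that
corner, zone 3 the large remainder where movement is easy.

Coordinate convention (1-based, inclusive): x is horizontal (Right +1,
Left -1), y vertical (Up +1, Down -1), z depth (Forward +1, Backward -1).
The patient's shoulder reference sits at (nx/2, ny/2, 0), on the near face
just outside the grid; it is informational only and never a bubble cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "BubbleState",
    "MoveAction",
    "GridSpace",
    "corner_shell_zone_map",
    "corner_face_zone_map",
    "NAMED_ZONE_LAYOUTS",
    "default_zone_map",
    "InvalidStateError",
    "BoundaryViolationError",
    "valid_actions",
    "apply_action",
    "zone_of",
]


class InvalidStateError(ValueError):
    """A bubble state lies outside the grid bounds."""


class BoundaryViolationError(ValueError):
    """An action would move the bubble outside the grid."""


class BubbleState(NamedTuple):
    """Grid cell holding the current bubble; 1-based indices."""

    x: int
    y: int
    z: int


class MoveAction(Enum):
    """The six unit displacements available to the placement agent."""

    UP = 0
    DOWN = 1
    RIGHT = 2
    LEFT = 3
    FORWARD = 4
    BACKWARD = 5

    @property
    def delta(self) -> tuple[int, int, int]:
        return _DELTAS[self]

    @property
    def opposite(self) -> "MoveAction":
        return _OPPOSITES[self]


_DELTAS: dict[MoveAction, tuple[int, int, int]] = {
    MoveAction.UP: (0, 1, 0),
    MoveAction.DOWN: (0, -1, 0),
    MoveAction.RIGHT: (1, 0, 0),
    MoveAction.LEFT: (-1, 0, 0),
    MoveAction.FORWARD: (0, 0, 1),
    MoveAction.BACKWARD: (0, 0, -1),
}

_OPPOSITES: dict[MoveAction, MoveAction] = {
    MoveAction.UP: MoveAction.DOWN,
    MoveAction.DOWN: MoveAction.UP,
    MoveAction.RIGHT: MoveAction.LEFT,
    MoveAction.LEFT: MoveAction.RIGHT,
    MoveAction.FORWARD: MoveAction.BACKWARD,
    MoveAction.BACKWARD: MoveAction.FORWARD,
}

ACTIONS: tuple[MoveAction, ...] = tuple(MoveAction)
N_ACTIONS = len(ACTIONS)


def corner_shell_zone_map(nx: int = 8, ny: int = 8, nz: int = 4) -> np.ndarray:
    """Default three-zone layout: zone 2 wraps *around* the target block.

    Zone 1 is the 2 x 2 x 1 block in the far upper-right corner
    ``{x in {nx-1, nx}, y in {ny-1, ny}, z = nz}``.  Zone 2 is the 12-cell
    shell beside and below it — the 3 x 3 x 2 corner block minus zone 1 and
    minus the diagonal edge farthest from the corner — so that every path
    into the target crosses the difficult surround first.  Zone 3 is
    everything else.  On the default 8 x 8 x 4 grid the zone sizes are
    4, 12 and 240.
    """
    zm = np.full((nx, ny, nz), 3, dtype=np.int8)
    x2, y2, z2 = max(nx - 3, 0), max(ny - 3, 0), max(nz - 2, 0)
    zm[x2:, y2:, z2:] = 2
    zm[x2, y2, z2:] = 3  # diagonal edge: keeps the shell at 12 cells
    x1, y1 = max(nx - 2, 0), max(ny - 2, 0)
    zm[x1:, y1:, nz - 1] = 1
    return zm


def corner_face_zone_map(nx: int = 8, ny: int = 8, nz: int = 4) -> np.ndarray:
    """Alternative flat layout: zones 1 and 2 tile the far face only.

    Zone 1 as in :func:`corner_shell_zone_map`; zone 2 is the remaining 12
    cells of the 4 x 4 x 1 far-layer corner block.  Same zone sizes.
    """
    zm = np.full((nx, ny, nz), 3, dtype=np.int8)
    x2, y2 = max(nx - 4, 0), max(ny - 4, 0)
    zm[x2:, y2:, nz - 1] = 2
    x1, y1 = max(nx - 2, 0), max(ny - 2, 0)
    zm[x1:, y1:, nz - 1] = 1
    return zm


NAMED_ZONE_LAYOUTS = {
    "corner-shell": corner_shell_zone_map,
    "corner-face": corner_face_zone_map,
}

# default layout used when GridSpace is built without an explicit zone_map
default_zone_map = corner_shell_zone_map


@dataclass(eq=False)
class GridSpace:
    """The reaching space: dimensions, zone assignment and movement topology.

    Parameters
    ----------
    nx, ny, nz
        Cell counts along the horizontal, vertical and depth axes.
    shoulder_ref
        Grid coordinate of the patient's shoulder joint, on or outside the
        boundary.  Informational only; plays no role in any computation.
    zone_map
        Integer array of shape ``(nx, ny, nz)`` assigning every cell to a
        zone in {1, 2, 3}.  Defaults to :func:`default_zone_map`.
    """

    nx: int = 8
    ny: int = 8
    nz: int = 4
    shoulder_ref: tuple[int, int, int] | None = None
    zone_map: np.ndarray | None = None

    # movement topology caches, built once
    _valid_mask: np.ndarray = field(init=False, repr=False)
    _neighbor_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.shoulder_ref is None:
            self.shoulder_ref = (self.nx // 2, self.ny // 2, 0)
        if self.zone_map is None:
            self.zone_map = default_zone_map(self.nx, self.ny, self.nz)
        self.zone_map = np.asarray(self.zone_map, dtype=np.int8)
        if self.zone_map.shape != (self.nx, self.ny, self.nz):
            raise ValueError(
                f"zone_map shape {self.zone_map.shape} does not match grid "
                f"({self.nx}, {self.ny}, {self.nz})"
            )
        if not np.isin(self.zone_map, (1, 2, 3)).all():
            raise ValueError("zone_map entries must be in {1, 2, 3}")
        self._build_topology()

    def _build_topology(self) -> None:
        n = self.n_states
        self._valid_mask = np.zeros((n, N_ACTIONS), dtype=bool)
        self._neighbor_index = np.full((n, N_ACTIONS), -1, dtype=np.int64)
        for idx in range(n):
            x, y, z = self.state_from_index(idx)
            for a in ACTIONS:
                dx, dy, dz = a.delta
                nxt = (x + dx, y + dy, z + dz)
                if self._in_bounds(*nxt):
                    self._valid_mask[idx, a.value] = True
                    self._neighbor_index[idx, a.value] = self.state_index(
                        BubbleState(*nxt)
                    )

    # -- indexing ---------------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.nx * self.ny * self.nz

    def _in_bounds(self, x: int, y: int, z: int) -> bool:
        return 1 <= x <= self.nx and 1 <= y <= self.ny and 1 <= z <= self.nz

    def contains(self, state: BubbleState) -> bool:
        return self._in_bounds(*state)

    def state_index(self, state: BubbleState) -> int:
        """Row index of a cell in the Q-table (x fastest, z slowest)."""
        if not self.contains(state):
            raise InvalidStateError(f"state {tuple(state)} outside grid")
        x, y, z = state
        return (x - 1) + self.nx * ((y - 1) + self.ny * (z - 1))

    def state_from_index(self, idx: int) -> BubbleState:
        if not 0 <= idx < self.n_states:
            raise InvalidStateError(f"state index {idx} out of range")
        x = idx % self.nx
        y = (idx // self.nx) % self.ny
        z = idx // (self.nx * self.ny)
        return BubbleState(x + 1, y + 1, z + 1)

    def all_states(self) -> list[BubbleState]:
        return [self.state_from_index(i) for i in range(self.n_states)]

    # -- zones ------------------------------------------------------------

    def zone_of(self, state: BubbleState) -> int:
        if not self.contains(state):
            raise InvalidStateError(f"state {tuple(state)} outside grid")
        return int(self.zone_map[state.x - 1, state.y - 1, state.z - 1])

    def zone_sizes(self) -> dict[int, int]:
        """Cell count per zone identifier."""
        ids, counts = np.unique(self.zone_map, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    @property
    def zone_index(self) -> np.ndarray:
        """Zone id per flat state index."""
        return self.zone_map.reshape(self.n_states, order="F")

    # -- movement ---------------------------------------------------------

    def valid_actions(self, state: BubbleState) -> set[MoveAction]:
        idx = self.state_index(state)
        return {a for a in ACTIONS if self._valid_mask[idx, a.value]}

    def apply_action(self, state: BubbleState, action: MoveAction) -> BubbleState:
        idx = self.state_index(state)
        nxt = self._neighbor_index[idx, action.value]
        if nxt < 0:
            raise BoundaryViolationError(
                f"action {action.name} from {tuple(state)} leaves the grid"
            )
        return self.state_from_index(int(nxt))


def valid_actions(state: BubbleState, grid: GridSpace) -> set[MoveAction]:
    """Actions whose application keeps the bubble within the grid."""
    return grid.valid_actions(state)


def apply_action(state: BubbleState, action: MoveAction, grid: GridSpace) -> BubbleState:
    """Displace the bubble one cell along the action's axis."""
    return grid.apply_action(state, action)


def zone_of(state: BubbleState, grid: GridSpace) -> int:
    """Performance-zone identifier (1, 2 or 3) of a cell."""
    return grid.zone_of(state)
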