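"""Tabular Q-learning: value store, update rule and epsilon-greedy selection.

The agent maintains Q(S, A) over every (cell, direction) pair.  In-bounds
entries start at zero; entries for moves that would leave the grid are
pinned at the sentinel -100 and are never selected or updated, so they
stay -100 for the whole run.

The value update is the standard one-step rule

    Q(s, a) <- (1 - alpha) * Q(s, a) + alpha * (r + gamma * max_a' Q(s', a'))

with the maximum taken over the *valid* actions of the successor cell.

Exploration follows a dynamically decreasing epsilon-greedy schedule:

    epsilon = clamp(E / (total_actions * total_reward), eps_min, eps_max)

recomputed before every action selection from the run's cumulative action
count and cumulative reward, so a run that earns reward explores less as
it progresses.  While the cumulative reward is zero or negative the agent
knows nothing useful yet and epsilon stays at its upper clamp.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import ACTIONS, N_ACTIONS, BubbleState, GridSpace, MoveAction

__all__ = [
    "OUT_OF_BOUNDS_VALUE",
    "LearningParams",
    "ExplorationSchedule",
    "QTable",
    "init_qtable",
    "update_q",
    "epsilon_value",
    "select_action",
]

OUT_OF_BOUNDS_VALUE = -100.0


@dataclass(frozen=True)
class LearningParams:
    """Q-learning rates.

    alpha : learning rate in [0, 1]; 0 means no learning at all, 1 discards
        the old value entirely.  Default 0.4 balances previous with current
        performance.
    gamma : discount factor in [0, 1].  Default 1 gives future rewards full
        weight, encouraging moves through low-reward cells that lead to
        high-reward ones.
    """

    alpha: float = 0.4
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class ExplorationSchedule:
    """Dynamically decreasing epsilon-greedy schedule.

    E : numerator constant (default 0.9).
    eps_max : upper clamp; the exploration rate in early, ignorant sessions
        (default 0.5).
    eps_min : lower clamp reached once actions and reward accumulate
        (default 0.3).
    """

    E: float = 0.9
    eps_max: float = 0.5
    eps_min: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps_min <= self.eps_max <= 1.0:
            raise ValueError(
                f"need 0 <= eps_min <= eps_max <= 1, got "
                f"[{self.eps_min}, {self.eps_max}]"
            )


class QTable:
    """Per-(state, action) value table over a grid.

    Materialized as an ``(n_states, 6)`` float array; rows follow the
    grid's state indexing, columns the action enumeration order.
    """

    def __init__(self, grid: GridSpace, values: np.ndarray | None = None):
        self.grid = grid
        if values is None:
            values = np.where(grid._valid_mask, 0.0, OUT_OF_BOUNDS_VALUE)
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (grid.n_states, N_ACTIONS):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({grid.n_states}, {N_ACTIONS})"
            )
        self.values = values

    def __getitem__(self, key: tuple[BubbleState, MoveAction]) -> float:
        state, action = key
        return float(self.values[self.grid.state_index(state), action.value])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def max_valid(self, state: BubbleState) -> float:
        """Maximum Q over the valid actions of a cell."""
        idx = self.grid.state_index(state)
        row = self.values[idx]
        return float(row[self.grid._valid_mask[idx]].max())

    def copy(self) -> "QTable":
        return QTable(self.grid, self.values.copy())

    # -- persistence ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular snapshot: one row per cell, one column per action."""
        coords = np.array([tuple(s) for s in self.grid.all_states()])
        df = pd.DataFrame(coords, columns=["x", "y", "z"])
        for a in ACTIONS:
            df[a.name.lower()] = self.values[:, a.value]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, grid: GridSpace) -> "QTable":
        """Reload a snapshot written by :meth:`to_csv`, bit-exactly."""
        df = pd.read_csv(path, float_precision="round_trip")
        values = np.empty((grid.n_states, N_ACTIONS), dtype=np.float64)
        for _, row in df.iterrows():
            idx = grid.state_index(BubbleState(int(row.x), int(row.y), int(row.z)))
            for a in ACTIONS:
                values[idx, a.value] = row[a.name.lower()]
        return cls(grid, values)


def init_qtable(grid: GridSpace) -> QTable:
    """Fresh Q-table: zeros in bounds, -100 for boundary-leaving moves."""
    return QTable(grid)


def update_q(
    qtable: QTable,
    s: BubbleState,
    a: MoveAction,
    r: float,
    s_next: BubbleState,
    params: LearningParams,
    terminal: bool = False,
) -> float:
    """One-step Q update of entry (s, a); returns the new entry value.

    ``s_next`` must be the cell that taking ``a`` from ``s`` produces; the
    future term is the maximum Q over the valid actions of ``s_next``.
    With ``terminal=True`` the transition ends its episode and the future
    term is dropped, so the target is the immediate reward alone.
    """
    grid = qtable.grid
    idx = grid.state_index(s)
    if not grid._valid_mask[idx, a.value]:
        raise ValueError(f"action {a.name} is not valid from {tuple(s)}")
    if grid.state_index(s_next) != grid._neighbor_index[idx, a.value]:
        raise ValueError(
            f"s_next {tuple(s_next)} is not the successor of {tuple(s)} "
            f"under {a.name}"
        )
    old = qtable.values[idx, a.value]
    future = 0.0 if terminal else qtable.max_valid(s_next)
    new = (1.0 - params.alpha) * old + params.alpha * (r + params.gamma * future)
    qtable.values[idx, a.value] = new
    return float(new)


def epsilon_value(
    total_actions: int,
    total_reward: float,
    schedule: ExplorationSchedule = ExplorationSchedule(),
) -> float:
    """Exploration rate from cumulative run totals.

    The literal dynamically-decreasing schedule
    ``clamp(E / (total_actions * total_reward), eps_min, eps_max)``:
    ``eps_max`` while the denominator is zero (no actions taken or no net
    reward yet), the lower clamp ``eps_min`` once the product grows large —
    or whenever the net reward is negative, where the expression falls
    below every clamp.
    """
    if total_actions < 0:
        raise ValueError("total_actions must be >= 0")
    denom = total_actions * total_reward
    if denom == 0.0:
        return schedule.eps_max
    return max(min(schedule.E / denom, schedule.eps_max), schedule.eps_min)


def select_action(
    qtable: QTable,
    state: BubbleState,
    epsilon: float,
    rng: np.random.Generator,
    grid: GridSpace | None = None,
) -> MoveAction:
    """Epsilon-greedy choice among the valid actions of a cell.

    With probability ``epsilon`` a uniformly random valid action; otherwise
    a Q-maximizing valid action, ties broken uniformly at random.  Actions
    that would leave the grid are never returned on either branch.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    grid = grid if grid is not None else qtable.grid
    idx = grid.state_index(state)
    mask = grid._valid_mask[idx]
    candidates = np.flatnonzero(mask)
    if rng.random() >= epsilon:
        row = qtable.values[idx, candidates]
        candidates = candidates[row == row.max()]
    choice = candidates[rng.integers(len(candidates))]
    return ACTIONS[int(choice)]
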