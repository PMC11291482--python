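"""Session orchestration: the days x iterations simulation loop.

One *day* is a therapy session of ``iterations`` bubble presentations
(default 400); a *program* is ``days`` consecutive sessions (default 10)
over which the Q-table, the bubble position and the cumulative
exploration totals all persist — the program is one continuing learning
process, only the patient's schedule changes between days.

Each presentation: the simulated patient's performance at the current
bubble is sampled, scored (K) and rewarded; the reward updates the
predecessor (state, action) pair that produced this bubble (the first
presentation of a run has no predecessor and triggers no update); the
exploration rate is recomputed from the cumulative totals; an
epsilon-greedy action moves the bubble to its next cell.  By default each
presentation is treated as an episode of length one, so entries track the
patient's current per-cell reward and adapt within a session when
abilities change; see ``SessionConfig.presentation_episodes``.

Per-day metrics mirror the session report a therapist would read: bubble
count, count/zone-size density and reward sum per zone.  For comparing
runs with different daily iteration counts, densities are additionally
normalized to the nominal 400-presentation day.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agent import (
    ExplorationSchedule,
    LearningParams,
    QTable,
    epsilon_value,
    init_qtable,
    select_action,
    update_q,
)
from .patient import (
    PatientProfile,
    builtin_profile,
    kinematic_score,
    load_profile,
    profile_from_dict,
    profile_to_dict,
)
from .reward import RewardPolicy, compute_reward
from .space import (
    ACTIONS,
    NAMED_ZONE_LAYOUTS,
    BubbleState,
    GridSpace,
    MoveAction,
    default_zone_map,
)
from .space import apply_action as _apply_action

__all__ = [
    "SessionConfig",
    "DayMetrics",
    "RunResult",
    "RunTotals",
    "SweepResult",
    "run_day",
    "run_program",
    "normalized_bubble_number",
    "sweep_iterations",
    "write_results",
    "read_metrics",
    "load_config",
    "save_config",
]

logger = logging.getLogger("reachrl")

NOMINAL_ITERATIONS = 400

# sub-stream tags so adding days or sweep values never perturbs earlier draws
_INIT_STREAM = 0
_DAY_STREAM = 1
_SWEEP_STREAM = 2

PolicyLike = RewardPolicy | Mapping[int, RewardPolicy]


@dataclass
class SessionConfig:
    """Everything a reproducible program run needs.

    ``policy`` is either a single :class:`RewardPolicy` applied everywhere
    (the canonical strategy) or a mapping from zone id to policy, letting a
    therapist weight zones differently.  ``profile`` may be a
    :class:`PatientProfile` or the name of a built-in one.
    """

    days: int = 10
    iterations: int = NOMINAL_ITERATIONS
    seed: int = 0
    grid: GridSpace = field(default_factory=GridSpace)
    agent_params: LearningParams = field(default_factory=LearningParams)
    schedule: ExplorationSchedule = field(default_factory=ExplorationSchedule)
    policy: PolicyLike = field(default_factory=RewardPolicy)
    profile: PatientProfile | str = "test_case_1"
    start_state: BubbleState | None = None
    snapshot_qtables: bool = False
    # Each presentation is its own episode: the transition that produced a
    # bubble is credited with that bubble's reward alone, so entries track
    # the patient's current performance and stay bounded.  False gives the
    # continuing-task target r + gamma * max Q(s'), under which values grow
    # without bound (gamma defaults to 1) and placement locks in on the
    # first rewarding zone found.
    presentation_episodes: bool = True

    def resolved_profile(self) -> PatientProfile:
        if isinstance(self.profile, str):
            return builtin_profile(self.profile)
        return self.profile

    def policy_for(self, zone: int) -> RewardPolicy:
        if isinstance(self.policy, RewardPolicy):
            return self.policy
        return self.policy[zone]

    def validate(self) -> None:
        """Raise a single error listing every violation."""
        problems: list[str] = []
        if self.days < 1:
            problems.append(f"days must be >= 1, got {self.days}")
        if self.iterations < 1:
            problems.append(f"iterations must be >= 1, got {self.iterations}")
        try:
            profile = self.resolved_profile()
            if self.days > profile.day_max:
                problems.append(
                    f"profile {profile.name!r} covers {profile.day_max} days, "
                    f"run asks for {self.days}"
                )
        except KeyError as exc:
            problems.append(str(exc))
        if self.start_state is not None and not self.grid.contains(self.start_state):
            problems.append(f"start_state {tuple(self.start_state)} outside grid")
        if not isinstance(self.policy, RewardPolicy):
            for z in self.grid.zone_sizes():
                if z not in self.policy:
                    problems.append(f"zone {z} has no reward policy")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


@dataclass
class RunTotals:
    """Cumulative run state carried across days.

    ``actions``/``reward`` feed the exploration schedule; the pending
    (state, action) pair is the transition awaiting its reward.
    """

    actions: int = 0
    reward: float = 0.0
    prev_state: BubbleState | None = None
    prev_action: MoveAction | None = None


@dataclass
class DayMetrics:
    """Per-zone session tallies, one row block of the results table."""

    day: int
    bubble_count: dict[int, int]
    density: dict[int, float]
    reward_sum: dict[int, float]
    total_reward: float


@dataclass
class RunResult:
    """Complete outcome of a program: config echo, metrics, log, Q-table."""

    config: SessionConfig
    day_metrics: list[DayMetrics]
    qtable: QTable
    log: pd.DataFrame
    qtable_snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        """Long-format metrics: 3 zone rows plus 1 total row per day."""
        rows = []
        for dm in self.day_metrics:
            for z in sorted(dm.bubble_count):
                rows.append(
                    {"day": dm.day, "zone": str(z),
                     "bubbles": dm.bubble_count[z],
                     "bubbles_per_unit": dm.density[z],
                     "reward_sum": dm.reward_sum[z],
                     "total_reward": np.nan}
                )
            rows.append(
                {"day": dm.day, "zone": "total",
                 "bubbles": sum(dm.bubble_count.values()),
                 "bubbles_per_unit": np.nan, "reward_sum": np.nan,
                 "total_reward": dm.total_reward}
            )
        return pd.DataFrame(rows)


_LOG_COLUMNS = [
    "day", "step", "x", "y", "z", "zone", "pop",
    "m1", "m2", "m3", "m4", "K", "reward", "epsilon", "action",
]


def run_day(
    day: int,
    qtable: QTable,
    start_state: BubbleState,
    totals: RunTotals,
    config: SessionConfig,
    rng: np.random.Generator,
    log_rows: list | None = None,
) -> tuple[DayMetrics, BubbleState, RunTotals]:
    """Simulate one session of ``config.iterations`` presentations.

    Mutates ``qtable`` and ``totals`` in place and returns the day's
    metrics together with the bubble position at the end of the day.
    """
    grid = config.grid
    profile = config.resolved_profile()
    zones = sorted(grid.zone_sizes())
    specs = {z: profile.spec_for(day, z) for z in zones}
    policies = {z: config.policy_for(z) for z in zones}
    sizes = grid.zone_sizes()

    counts = {z: 0 for z in zones}
    rewards = {z: 0.0 for z in zones}
    state = start_state

    for step in range(1, config.iterations + 1):
        zone = grid.zone_of(state)
        sample = specs[zone].sample(rng)
        K = kinematic_score(sample)
        r = compute_reward(sample.pop, K, policies[zone])
        if totals.prev_state is not None:
            update_q(qtable, totals.prev_state, totals.prev_action, r, state,
                     config.agent_params, terminal=config.presentation_episodes)
        totals.reward += r
        counts[zone] += 1
        rewards[zone] += r
        eps = epsilon_value(totals.actions, totals.reward, config.schedule)
        action = select_action(qtable, state, eps, rng, grid)
        totals.actions += 1
        if log_rows is not None:
            log_rows.append(
                (day, step, state.x, state.y, state.z, zone, sample.pop,
                 sample.m1, sample.m2, sample.m3, sample.m4, K, r, eps,
                 action.name)
            )
        totals.prev_state, totals.prev_action = state, action
        state = _apply_action(state, action, grid)

    metrics = DayMetrics(
        day=day,
        bubble_count=counts,
        density={z: counts[z] / sizes[z] for z in zones},
        reward_sum=rewards,
        total_reward=sum(rewards.values()),
    )
    return metrics, state, totals


def run_program(config: SessionConfig) -> RunResult:
    """Run the full multi-day program with persistent learning state.

    The Q-table, bubble position, pending transition and cumulative
    exploration totals all carry over between days.  The first bubble is
    placed uniformly at random unless ``config.start_state`` pins it.
    Per-day random sub-streams derive deterministically from the master
    seed, so extending the program never perturbs earlier days.
    """
    config.validate()
    grid = config.grid
    qtable = init_qtable(grid)

    if config.start_state is not None:
        state = config.start_state
    else:
        init_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(_INIT_STREAM,))
        )
        state = grid.state_from_index(int(init_rng.integers(grid.n_states)))

    totals = RunTotals()
    log_rows: list = []
    day_metrics: list[DayMetrics] = []
    snapshots: dict[int, pd.DataFrame] = {}

    for day in range(1, config.days + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(_DAY_STREAM, day))
        )
        metrics, state, totals = run_day(
            day, qtable, state, totals, config, rng, log_rows
        )
        day_metrics.append(metrics)
        if config.snapshot_qtables:
            snapshots[day] = qtable.to_frame()
        logger.info(
            "day %d: bubbles per zone %s, total reward %.2f",
            day, metrics.bubble_count, metrics.total_reward,
        )

    log = pd.DataFrame(log_rows, columns=_LOG_COLUMNS)
    return RunResult(config, day_metrics, qtable, log, snapshots)


def normalized_bubble_number(count: int, zone_size: int, iterations: int) -> float:
    """Zone density normalized to the nominal 400-presentation day.

    ``(count / zone_size) * (400 / iterations)`` — makes runs with
    different daily iteration counts comparable.
    """
    if zone_size <= 0:
        raise ValueError(f"zone_size must be > 0, got {zone_size}")
    if iterations <= 0:
        raise ValueError(f"iterations must be > 0, got {iterations}")
    return (count / zone_size) * (NOMINAL_ITERATIONS / iterations)


@dataclass
class SweepResult:
    """One program run per daily-iteration value, plus aligned densities."""

    runs: dict[int, RunResult]
    densities: pd.DataFrame  # columns: iterations, day, zone, bubbles, normalized_density


def sweep_iterations(config: SessionConfig, iteration_values: Sequence[int]) -> SweepResult:
    """Re-run the program for each daily-iteration count.

    Each member runs under an independent sub-seed derived from
    ``config.seed`` and its iteration value, so members are mutually
    independent but individually reproducible.
    """
    for v in iteration_values:
        if v < 1:
            raise ValueError(f"iteration values must be >= 1, got {v}")
    runs: dict[int, RunResult] = {}
    rows = []
    sizes = config.grid.zone_sizes()
    for v in iteration_values:
        sub_seed = sweep_member_seed(config.seed, v)
        member = dataclasses.replace(config, iterations=int(v), seed=sub_seed)
        result = run_program(member)
        runs[int(v)] = result
        for dm in result.day_metrics:
            for z in sorted(dm.bubble_count):
                rows.append(
                    {"iterations": int(v), "day": dm.day, "zone": z,
                     "bubbles": dm.bubble_count[z],
                     "normalized_density": normalized_bubble_number(
                         dm.bubble_count[z], sizes[z], int(v))}
                )
    return SweepResult(runs, pd.DataFrame(rows))


def sweep_member_seed(seed: int, iteration_value: int) -> int:
    """Deterministic sub-seed (< 2^31) for one sweep member."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(_SWEEP_STREAM, int(iteration_value)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# -- persistence ----------------------------------------------------------

def write_results(result: RunResult, path: str | Path) -> Path:
    """Persist a run: metrics CSV, presentation log CSV, config echo, Q-table.

    Round-trips losslessly: :func:`read_metrics` recovers the metrics
    frame and :meth:`QTable.from_csv` the Q-table, bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    result.metrics_frame().to_csv(path / "metrics.csv", index=False,
                                  float_format="%.17g")
    result.log.to_csv(path / "presentations.csv", index=False,
                      float_format="%.17g")
    save_config(result.config, path / "config.yaml")
    result.qtable.to_csv(path / "qtable.csv")
    for day, frame in result.qtable_snapshots.items():
        frame.to_csv(path / f"qtable_day{day:02d}.csv", index=False,
                     float_format="%.17g")
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "metrics.csv", dtype={"zone": str})


def _policy_to_dict(p: RewardPolicy) -> dict:
    return dataclasses.asdict(p)


def config_to_dict(config: SessionConfig) -> dict:
    grid = config.grid
    d: dict = {
        "days": config.days,
        "iterations": config.iterations,
        "seed": config.seed,
        "grid": {"nx": grid.nx, "ny": grid.ny, "nz": grid.nz,
                 "shoulder_ref": list(grid.shoulder_ref)},
        "agent": dataclasses.asdict(config.agent_params),
        "exploration": dataclasses.asdict(config.schedule),
    }
    if not np.array_equal(grid.zone_map, default_zone_map(grid.nx, grid.ny, grid.nz)):
        d["grid"]["zone_map"] = grid.zone_map.tolist()
    if isinstance(config.policy, RewardPolicy):
        d["policy"] = _policy_to_dict(config.policy)
    else:
        d["policy"] = {int(z): _policy_to_dict(p) for z, p in config.policy.items()}
    if isinstance(config.profile, str):
        d["profile"] = config.profile
    else:
        d["profile"] = profile_to_dict(config.profile)
    if config.start_state is not None:
        d["start_state"] = list(config.start_state)
    if config.snapshot_qtables:
        d["snapshot_qtables"] = True
    if not config.presentation_episodes:
        d["presentation_episodes"] = False
    return d


def config_from_dict(d: dict) -> SessionConfig:
    grid_d = dict(d.get("grid", {}))
    zone_map = grid_d.pop("zone_map", None)
    layout = grid_d.pop("zone_layout", None)
    shoulder = grid_d.pop("shoulder_ref", None)
    nx = int(grid_d.get("nx", 8))
    ny = int(grid_d.get("ny", 8))
    nz = int(grid_d.get("nz", 4))
    if zone_map is not None:
        zm = np.asarray(zone_map)
    elif layout is not None:
        zm = NAMED_ZONE_LAYOUTS[layout](nx, ny, nz)
    else:
        zm = None
    grid = GridSpace(
        nx=nx, ny=ny, nz=nz,
        shoulder_ref=tuple(shoulder) if shoulder is not None else None,
        zone_map=zm,
    )
    pol_d = d.get("policy", {})
    policy: PolicyLike
    if pol_d and all(isinstance(v, dict) for v in pol_d.values()):
        policy = {int(z): RewardPolicy(**p) for z, p in pol_d.items()}
    else:
        policy = RewardPolicy(**pol_d)
    prof_d = d.get("profile", "test_case_1")
    profile: PatientProfile | str
    profile = prof_d if isinstance(prof_d, str) else profile_from_dict(prof_d)
    start = d.get("start_state")
    return SessionConfig(
        days=int(d.get("days", 10)),
        iterations=int(d.get("iterations", NOMINAL_ITERATIONS)),
        seed=int(d.get("seed", 0)),
        grid=grid,
        agent_params=LearningParams(**d.get("agent", {})),
        schedule=ExplorationSchedule(**d.get("exploration", {})),
        policy=policy,
        profile=profile,
        start_state=BubbleState(*start) if start is not None else None,
        snapshot_qtables=bool(d.get("snapshot_qtables", False)),
        presentation_episodes=bool(d.get("presentation_episodes", True)),
    )


def save_config(config: SessionConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> SessionConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data)
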