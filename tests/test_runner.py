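"""Session orchestration: conservation, determinism, persistence, sweeps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from reachrl import (
    BubbleState,
    GridSpace,
    LearningParams,
    RewardPolicy,
    SessionConfig,
    compute_reward,
    init_qtable,
    load_config,
    normalized_bubble_number,
    read_metrics,
    run_program,
    save_config,
    sweep_iterations,
    write_results,
)
from reachrl.runner import sweep_member_seed


def small_config(**kw):
    base = dict(days=3, iterations=120, seed=7, profile="test_case_1")
    base.update(kw)
    return SessionConfig(**base)


# -- normalized density ---------------------------------------------------

@pytest.mark.parametrize(
    "count,size,iters,expected",
    [(43, 4, 400, 10.75), (60, 4, 50, 120.0), (18, 12, 400, 1.5)],
)
def test_normalized_bubble_number(count, size, iters, expected):
    assert normalized_bubble_number(count, size, iters) == pytest.approx(expected)


def test_normalized_density_reduces_to_plain_density_at_400():
    assert normalized_bubble_number(37, 12, 400) == pytest.approx(37 / 12)


def test_normalized_density_domain_errors():
    with pytest.raises(ValueError):
        normalized_bubble_number(1, 0, 400)
    with pytest.raises(ValueError):
        normalized_bubble_number(1, 4, 0)


# -- the program loop -----------------------------------------------------

def test_single_presentation_performs_no_update():
    res = run_program(small_config(days=1, iterations=1))
    assert len(res.log) == 1
    fresh = init_qtable(res.config.grid)
    assert (res.qtable.values == fresh.values).all()


def test_identical_seeds_are_bit_identical():
    a, b = run_program(small_config()), run_program(small_config())
    assert (a.qtable.values == b.qtable.values).all()
    pd.testing.assert_frame_equal(a.log, b.log)
    for da, db in zip(a.day_metrics, b.day_metrics):
        assert da == db


def test_different_seeds_diverge():
    a = run_program(small_config(seed=1))
    b = run_program(small_config(seed=2))
    assert hash(tuple(a.log["x"])) != hash(tuple(b.log["x"]))


def test_conservation_and_double_entry():
    cfg = small_config()
    res = run_program(cfg)
    pol = cfg.policy
    for dm in res.day_metrics:
        assert sum(dm.bubble_count.values()) == cfg.iterations
        assert dm.total_reward == pytest.approx(sum(dm.reward_sum.values()), abs=1e-9)
        day_log = res.log[res.log.day == dm.day]
        for z in (1, 2, 3):
            rows = day_log[day_log.zone == z]
            assert len(rows) == dm.bubble_count[z]
            recomputed = sum(
                compute_reward(int(p), float(k), pol)
                for p, k in zip(rows["pop"], rows["K"])
            )
            assert recomputed == pytest.approx(dm.reward_sum[z], abs=1e-9)


def test_log_shape_and_columns():
    cfg = small_config(days=2, iterations=50)
    res = run_program(cfg)
    assert len(res.log) == 2 * 50
    assert list(res.log.columns[:7]) == ["day", "step", "x", "y", "z", "zone", "pop"]
    assert res.log["epsilon"].between(0.3, 0.5).all()


def test_epsilon_trace_non_increasing_while_reward_grows():
    res = run_program(small_config(days=10, iterations=400))
    eps = res.log["epsilon"].to_numpy()
    cum = res.log["reward"].cumsum().to_numpy()
    rew = res.log["reward"].to_numpy()
    # wherever the cumulative reward is positive and the step added reward,
    # the exploration rate cannot rise
    for t in range(1, len(eps)):
        if cum[t - 1] > 0 and rew[t] >= 0:
            assert eps[t] <= eps[t - 1] + 1e-12


def test_alpha_zero_leaves_table_at_initialization():
    cfg = small_config(agent_params=LearningParams(alpha=0.0, gamma=1.0))
    res = run_program(cfg)
    assert (res.qtable.values == init_qtable(cfg.grid).values).all()


@pytest.mark.parametrize("episodes", [True, False])
def test_boundary_sentinels_untouched_by_any_run(episodes):
    cfg = small_config(presentation_episodes=episodes)
    res = run_program(cfg)
    mask = cfg.grid._valid_mask
    assert (res.qtable.values[~mask] == -100.0).all()


def test_validation_reports_every_violation():
    cfg = SessionConfig(days=0, iterations=0, profile="nope",
                        start_state=BubbleState(99, 1, 1))
    with pytest.raises(ValueError) as err:
        run_program(cfg)
    msg = str(err.value)
    assert "days" in msg and "iterations" in msg and "nope" in msg
    assert "start_state" in msg


def test_days_beyond_profile_coverage_rejected():
    with pytest.raises(ValueError, match="covers 10 days"):
        run_program(small_config(days=12))


def test_fixed_start_state_honored():
    cfg = small_config(days=1, iterations=5, start_state=BubbleState(2, 3, 1))
    res = run_program(cfg)
    first = res.log.iloc[0]
    assert (first.x, first.y, first.z) == (2, 3, 1)


def test_per_zone_policies_change_rewards():
    pols = {1: RewardPolicy(), 2: RewardPolicy(r_unreached=0.9),
            3: RewardPolicy()}
    cfg = small_config(days=1, iterations=50, policy=pols)
    res = run_program(cfg)
    day = res.log
    z2_unreached = day[(day.zone == 2) & (day["pop"] == 0)]
    if len(z2_unreached):
        assert (z2_unreached.reward == 0.9).all()
    with pytest.raises(ValueError, match="zone 3 has no reward policy"):
        run_program(small_config(policy={1: RewardPolicy(), 2: RewardPolicy()}))


# -- persistence ----------------------------------------------------------

def test_write_and_reload_round_trip(tmp_path):
    cfg = small_config(days=2, iterations=40, snapshot_qtables=True)
    res = run_program(cfg)
    out = write_results(res, tmp_path / "run")
    metrics = read_metrics(out)
    zone_rows = metrics[metrics.zone != "total"]
    total_rows = metrics[metrics.zone == "total"]
    assert len(zone_rows) == 2 * 3 and len(total_rows) == 2
    for dm in res.day_metrics:
        for z in (1, 2, 3):
            row = zone_rows[(zone_rows.day == dm.day) & (zone_rows.zone == str(z))]
            assert float(row.bubbles.iloc[0]) == dm.bubble_count[z]
            assert float(row.reward_sum.iloc[0]) == pytest.approx(
                dm.reward_sum[z], abs=1e-9)
        trow = total_rows[total_rows.day == dm.day]
        assert float(trow.total_reward.iloc[0]) == pytest.approx(
            dm.total_reward, abs=1e-9)
    log_back = pd.read_csv(out / "presentations.csv")
    assert len(log_back) == len(res.log)
    assert (out / "qtable_day01.csv").exists()
    cfg_back = load_config(out / "config.yaml")
    assert cfg_back.days == cfg.days and cfg_back.seed == cfg.seed


def test_minimal_run_writes_without_error(tmp_path):
    res = run_program(small_config(days=1, iterations=1))
    write_results(res, tmp_path / "tiny")
    assert (tmp_path / "tiny" / "metrics.csv").exists()


def test_config_round_trip_preserves_custom_settings(tmp_path):
    grid = GridSpace(zone_map=np.roll(GridSpace().zone_map, 1, axis=0))
    cfg = SessionConfig(days=4, iterations=10, seed=3, grid=grid,
                        policy={z: RewardPolicy(r_easy=-0.1 * z) for z in (1, 2, 3)},
                        presentation_episodes=False)
    path = tmp_path / "cfg.yaml"
    save_config(cfg, path)
    back = load_config(path)
    assert (back.grid.zone_map == grid.zone_map).all()
    assert back.policy[2].r_easy == pytest.approx(-0.2)
    assert back.presentation_episodes is False


def test_named_zone_layout_in_config(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("days: 2\niterations: 5\nseed: 1\n"
                    "grid: {nx: 8, ny: 8, nz: 4, zone_layout: corner-face}\n")
    cfg = load_config(path)
    from reachrl.space import corner_face_zone_map
    assert (cfg.grid.zone_map == corner_face_zone_map()).all()


# -- sweeps ---------------------------------------------------------------

def test_degenerate_sweep_matches_single_run():
    cfg = small_config(days=2, iterations=400)
    sweep = sweep_iterations(cfg, [400])
    solo = run_program(dataclasses.replace(cfg, seed=sweep_member_seed(cfg.seed, 400)))
    pd.testing.assert_frame_equal(sweep.runs[400].log, solo.log)


def test_sweep_densities_are_aligned_and_normalized():
    cfg = small_config(days=2)
    res = sweep_iterations(cfg, [50, 100])
    assert set(res.densities.iterations) == {50, 100}
    assert len(res.densities) == 2 * 2 * 3
    for v in (50, 100):
        sub = res.densities[res.densities.iterations == v]
        day1 = sub[sub.day == 1]
        assert day1.bubbles.sum() == v
    with pytest.raises(ValueError):
        sweep_iterations(cfg, [0])
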