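"""Run a built-in simulated patient through the 10-day program.

The agent places 400 reaching bubbles per day in the 8 x 8 x 4 grid and
learns, from the pop flag and kinematic score of each reach, where the
therapist's reward strategy wants practice to concentrate.  The printed
table mirrors a session report: bubbles per zone, bubbles per zone cell,
and the reward earned in each zone per day.
"""

from reachrl import SessionConfig, run_program

config = SessionConfig(profile="test_case_1", days=10, iterations=400, seed=5)
result = run_program(config)

print(f"profile={config.profile}  alpha={config.agent_params.alpha}  "
      f"gamma={config.agent_params.gamma}  seed={config.seed}")
print(f"{'day':>3} | {'bubbles z1/z2/z3':>18} | {'per cell z1/z2/z3':>20} | total reward")
for dm in result.day_metrics:
    counts = "/".join(str(dm.bubble_count[z]) for z in (1, 2, 3))
    dens = "/".join(f"{dm.density[z]:.2f}" for z in (1, 2, 3))
    print(f"{dm.day:>3} | {counts:>18} | {dens:>20} | {dm.total_reward:8.2f}")

# The stroke patient cannot reach zone 1 until day 4.  Expect placement to
# concentrate in the difficult surround (zone 2) during days 1-3, then shift
# into the recovering corner (zone 1) once popping there earns the high
# difficult-reach reward, while the easy zone 3 is avoided throughout.
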