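"""Define a custom therapist strategy and a custom simulated patient.

A patient pops with identical difficulty everywhere (all four kinematic
measures at 0.4), and the strategy pays reward only in zone 2: the other
zones earn exactly zero.  Placement should migrate into the rewarded zone
over the program regardless of geometry — the adaptivity the engine is
built around.
"""

from reachrl import RewardPolicy, SessionConfig, run_program
from reachrl.patient import PatientProfile, ScheduleEntry, ZonePerformanceSpec

difficult = ZonePerformanceSpec.constant((0.4, 0.4, 0.4, 0.4))
patient = PatientProfile(
    "uniform_difficult",
    [ScheduleEntry(1, 10, zone, difficult) for zone in (1, 2, 3)],
)

# 1 - 2.5 * 0.4 = 0: difficult reaches in zones 1 and 3 earn nothing
zero = RewardPolicy(r_unreached=0.0, r_easy=0.0, difficulty_slope=2.5)
strategy = {1: zero, 2: RewardPolicy(), 3: zero}

result = run_program(SessionConfig(profile=patient, policy=strategy, seed=5))

print("share of bubbles placed in the rewarded zone (zone 2):")
for dm in result.day_metrics:
    share = dm.bubble_count[2] / sum(dm.bubble_count.values())
    print(f"  day {dm.day:>2}: {share:5.1%}")

first = result.day_metrics[0].bubble_count[2] / 400
last = result.day_metrics[-1].bubble_count[2] / 400
print(f"zone-2 share grew from {first:.1%} (day 1) to {last:.1%} (day 10)")
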