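# Methods

## The placement problem

A reaching-rehabilitation game shows the patient one bubble at a time in a
3D volume in front of them; the engine must decide where the next bubble
appears.  Formulated as reinforcement learning: the state is the current
bubble cell in an `nx × ny × nz` grid (default 8 × 8 × 4, 1-based indices;
x horizontal, y vertical, z depth), the action one of six unit
displacements, and the reward a therapist-defined function of how the
patient reached for that bubble.  The patient is the environment; the
engine never models them, it only observes pop/kinematic outcomes, so the
same machinery applies to any pathology.

The grid cells are partitioned into three performance zones.  Zone 1
(4 cells) is the far upper-right corner block `{x ∈ {7,8}, y ∈ {7,8},
z = 4}` — the challenging target at the limit of the range of motion.
Zone 2 (12 cells) is the default *corner-shell* layout: the 3 × 3 × 2
corner block minus zone 1 and minus its far diagonal edge, i.e. the
difficult surround wrapping beside and below the target, so that every
path into the target crosses zone 2 first.  Zone 3 is the 240 remaining
easy cells.  A flat alternative (`corner-face`: zones 1 and 2 tiling the
far face only) ships as a named layout, and any explicit 256-cell
assignment with sizes 4/12/240 can be supplied.  The shell was chosen as
the default because the surround is described as lying *around* the
target, and because in simulation it halves how often the bubble drifts
deep into the easy region after a random excursion.  The shoulder
reference (4, 4, 0) is stored for orientation only and enters no
computation.

## Learning rule and its episode convention

The Q-table holds `nx·ny·nz` rows × 6 action columns; in-bounds entries
start at 0, boundary-leaving entries at −100 and are never selected or
updated.  The update is the standard weighted average

    Q(s,a) ← (1−α)·Q(s,a) + α·(r + γ·max_{a′ valid} Q(s′,a′))

with α = 0.4 and γ = 1.  Credit assignment: the reward observed at the
bubble just presented updates the predecessor pair (s, a) that produced
it; the first presentation of a run has no predecessor and triggers no
update.

The one genuinely open design choice is the episode convention, and it
changes the engine's character completely:

* **Per-presentation episodes (default).**  Each presentation is treated
  as an episode of length one: the future term is dropped and every entry
  tracks an exponentially-weighted average of its destination cell's
  recent rewards.  Values stay bounded in the reward scale, so a regime
  change in the patient (recovery, pain) re-ranks neighboring cells within
  a few visits and placement follows the patient's *current* abilities.
* **Continuing task (`presentation_episodes=False`).**  The textbook
  bootstrapped target `r + γ·max Q(s′)`.  With γ = 1 and rewards that are
  positive wherever practice is useful, values grow without bound
  (~200 after 4000 presentations); frequently visited regions grow fastest,
  so whichever rewarding zone the bubble finds first becomes permanently
  dominant and the engine stops adapting.  Kept as a switch because it is
  the standard formulation and useful for studying exactly this failure
  mode.

The default is the convention under which the simulator reproduces the
intended clinical behavior — practice following the patient day by day —
and the reference two-test-case trajectories.  The continuing-task variant
still concentrates placement in a statically rewarded zone (it passes the
adaptivity property), but it cannot follow the test cases' mid-program
regime changes: once locked in, it never abandons a souring zone.

## Exploration

Action selection is epsilon-greedy over the valid actions only: with
probability ε a uniformly random valid action, otherwise a Q-maximizing
valid action with uniform tie-breaking (the all-zero initial table plus
random tie-breaks gives an unbiased novelty-seeking walk before any
reward is seen).  The exploration rate is recomputed before every
selection from run-cumulative totals:

    ε = max(min(E / (total_actions · total_reward), 0.5), 0.3),  E = 0.9.

The clamps are taken literally: a zero denominator (no actions yet, or no
net reward) yields the high rate 0.5; a negative cumulative reward puts
the expression below every clamp and yields the floor 0.3.  Totals, like
the Q-table and the bubble position, persist across days: the program is
one continuing course of treatment in which only the patient changes.

## Simulated patients

A patient profile is a total mapping from (day, zone) to a performance
spec — constant four-vector `(m1..m4)` with a pop flag, or four uniform
`[low, high]` ranges drawn independently per presentation.  An unreached
bubble is the all-zero sample.  Profiles are validated for gap- and
overlap-free coverage at load time.  The two built-in cases follow the
canonical 3-period schedules (days 1–3, 4–6, 7–10): the stroke case's
corner becomes poppable-with-difficulty (m = 0.4) from day 4; the
frozen-shoulder case loses zones 1–2 entirely on days 4–6 while zone 3
degrades to 30 % of good performance (`[0.24, 0.27]` vs `[0.8, 0.9]`).
Per-measure rather than per-score sampling was chosen so K remains a pure
average; since easy-zone draws always satisfy K ≥ 0.8, the reward is
unaffected by this choice.

What the generator emulates is the *schedule* of ability by zone and day;
it does not model trajectories, measurement noise of hand tracking,
fatigue within a session, or correlations between the four measures.
Passing tests therefore show that the engine adapts to piecewise-stationary
per-zone reward fields, not that it is robust to real tracking data.

## Reward strategy

`RewardPolicy(r_unreached=0.2, r_easy=−0.3, ease_threshold=0.8,
difficulty_slope=0.5)` reproduces the canonical strategy exactly,
including the discontinuous drop from 0.6 to −0.3 at K = 0.8 (the
threshold itself counts as easy).  The runner also accepts a mapping
`{zone: RewardPolicy}` so a therapist can weight zones directly; this is
what expresses "reward only zone 2" in the adaptivity property.  Day-
varying strategies are expressed by running consecutive programs with
different policies.

## Runs, metrics, reproducibility

A day performs exactly `iterations` presentations and tallies, by the
zone of the presented bubble: count, count/zone-size density, and reward
sum (a double-entry identity ties the sums to the presentation log).  For
cross-run comparison the density is normalized to the nominal session,
`(count / zone_size) · (400 / iterations)`.  The first bubble is placed
uniformly at random (configurable).  One master seed drives everything;
per-day and per-sweep-member substreams are spawned from it by key, so
extending a program or a sweep never perturbs earlier results, and
identical configurations are bit-identical.  Artifacts (metrics CSV,
presentation log, config echo, Q-table snapshots) round-trip losslessly;
Q-table CSVs are written at 17 significant digits and re-parsed with
round-trip float precision.

## Problem sizes and known limitations

Replicate studies in the tests and the acceptance script use 20 seeds for
the test-case replications and the adaptivity property, and 10 seeds for
the 50/400/1000 iteration sweep — enough to separate the systematic
effects from single-run noise while keeping a full suite run in well under
a minute of simulation time (one 10-day program takes ~0.15 s).

The main limitation is first-contact discovery: before any reward gradient
exists, finding the 16-cell corner block is an undirected search of a
256-cell volume, and in roughly a third of seeds it does not happen within
the first 400-presentation session.  Replicate means of day-1 and day-10
zone occupancies are therefore noticeably wider than any single reference
realization suggests; the corresponding replication checks in
`tests/test_acceptance.py` state the strict bands and are expected to flag
this.  Other non-goals: anthropometric scaling of the physical volume,
biomechanical trajectory generation, pain models, real-time VR client
integration, and statistical comparison across patients.
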