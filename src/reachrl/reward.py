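"""The therapist's reward strategy: mapping a presentation to a scalar.

The strategy encourages practice at the limits of the range of motion:

* unpopped bubble        -> small positive reward (keep a few bubbles
  there so the patient can try again without frustration);
* easy pop (K >= 0.8)    -> small negative reward (nothing to train here);
* difficult pop          -> high reward 1 - c*K, largest where movement
  quality is poorest.

All four constants are configurable; the defaults (0.2, -0.3, 0.8, 0.5)
reproduce the canonical strategy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RewardPolicy", "compute_reward"]


@dataclass(frozen=True)
class RewardPolicy:
    r_unreached: float = 0.2
    r_easy: float = -0.3
    ease_threshold: float = 0.8
    difficulty_slope: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.ease_threshold <= 1.0:
            raise ValueError(
                f"ease_threshold must be in [0, 1], got {self.ease_threshold}"
            )


def compute_reward(pop: int, K: float, policy: RewardPolicy = RewardPolicy()) -> float:
    """Reward for one presentation given its pop flag and kinematic score.

    Pure and deterministic: unpopped bubbles earn ``r_unreached``; pops at
    or above the ease threshold earn ``r_easy``; difficult pops earn
    ``1 - difficulty_slope * K``, decreasing in movement quality.
    """
    if not 0.0 <= K <= 1.0:
        raise ValueError(f"kinematic score must be in [0, 1], got {K}")
    if pop not in (0, 1):
        raise ValueError(f"pop must be 0 or 1, got {pop}")
    if pop == 0:
        return policy.r_unreached
    if K >= policy.ease_threshold:
        return policy.r_easy
    return 1.0 - policy.difficulty_slope * K
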