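"""Simulated patients: per-day, per-zone kinematic schedules and sampling.

A patient is described by a schedule assigning, to every (day, zone) pair
of the program, either a fixed outcome or a stochastic one.  Each bubble
presentation yields a :class:`KinematicSample`: a binary pop flag and four
normalized movement-quality measures in [0, 1] —

    m1  course length        m2  trajectory smoothness
    m3  time to pop          m4  maximal speed

An unpopped bubble carries all-zero measures.  The kinematic score K is
their plain average.

Two built-in profiles ship with the package: ``test_case_1`` (a stroke
patient whose reach into the hard corner recovers over the 10-day
program) and ``test_case_2`` (a frozen-shoulder patient whose pain
transiently removes zones 1 and 2 from reach on days 4-6).  In the easy
zone 3, good performance is drawn per measure uniformly from [0.8, 0.9]
and the degraded days 4-6 of test case 2 at 30% of that, [0.24, 0.27].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "KinematicSample",
    "ZonePerformanceSpec",
    "PatientProfile",
    "ScheduleGapError",
    "kinematic_score",
    "sample_performance",
    "builtin_profile",
    "load_profile",
    "save_profile",
    "BUILTIN_PROFILES",
]


class ScheduleGapError(KeyError):
    """A (day, zone) pair is not covered by the patient's schedule."""


@dataclass(frozen=True)
class KinematicSample:
    """One presentation's outcome: pop flag and normalized measures."""

    pop: int
    m1: float
    m2: float
    m3: float
    m4: float

    def __post_init__(self) -> None:
        if self.pop not in (0, 1):
            raise ValueError(f"pop must be 0 or 1, got {self.pop}")
        for name, v in zip(("m1", "m2", "m3", "m4"), self.m):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pop == 0 and any(v != 0.0 for v in self.m):
            raise ValueError("an unpopped bubble must carry all-zero measures")

    @property
    def m(self) -> tuple[float, float, float, float]:
        return (self.m1, self.m2, self.m3, self.m4)


def kinematic_score(sample: KinematicSample) -> float:
    """K = (m1 + m2 + m3 + m4) / 4, the mean movement-quality score."""
    return (sample.m1 + sample.m2 + sample.m3 + sample.m4) / 4.0


@dataclass(frozen=True)
class ZonePerformanceSpec:
    """Performance regime of one zone during one day range.

    ``kind`` is ``"constant"`` (four fixed m-values, returned verbatim) or
    ``"uniform-range"`` (four (low, high) intervals, each measure drawn
    independently and uniformly per presentation).  ``pop_flag`` False
    forces the all-zero unpopped sample regardless of values.
    """

    pop_flag: bool
    kind: str
    values: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "uniform-range"):
            raise ValueError(f"unknown spec kind {self.kind!r}")
        if len(self.values) != 4:
            raise ValueError("need exactly four m-value entries")
        if self.kind == "constant":
            for v in self.values:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"constant m-value {v} outside [0, 1]")
        else:
            for lo, hi in self.values:
                if not (0.0 <= lo <= hi <= 1.0):
                    raise ValueError(f"bad range [{lo}, {hi}]")

    @staticmethod
    def constant(m: Sequence[float], pop: bool = True) -> "ZonePerformanceSpec":
        return ZonePerformanceSpec(pop, "constant", tuple(float(v) for v in m))

    @staticmethod
    def uniform(lo: float, hi: float, pop: bool = True) -> "ZonePerformanceSpec":
        """Four identical (lo, hi) ranges, one per measure."""
        return ZonePerformanceSpec(pop, "uniform-range", ((lo, hi),) * 4)

    @staticmethod
    def unreachable() -> "ZonePerformanceSpec":
        return ZonePerformanceSpec(False, "constant", (0.0, 0.0, 0.0, 0.0))

    def sample(self, rng: np.random.Generator) -> KinematicSample:
        if not self.pop_flag:
            return KinematicSample(0, 0.0, 0.0, 0.0, 0.0)
        if self.kind == "constant":
            return KinematicSample(1, *self.values)
        ms = tuple(float(rng.uniform(lo, hi)) for lo, hi in self.values)
        return KinematicSample(1, *ms)


@dataclass(frozen=True)
class ScheduleEntry:
    day_start: int
    day_end: int
    zone: int
    spec: ZonePerformanceSpec


class PatientProfile:
    """Total schedule mapping every (day, zone) of a program to a spec.

    Validated at construction: within the covered day span, every
    (day, zone) pair resolves to exactly one spec — gaps and overlaps are
    errors, not defaults.
    """

    def __init__(self, name: str, entries: Iterable[ScheduleEntry]):
        self.name = name
        self.entries = tuple(entries)
        if not self.entries:
            raise ValueError("profile has no schedule entries")
        self.zones = sorted({e.zone for e in self.entries})
        self.day_max = max(e.day_end for e in self.entries)
        self._validate()
        self._lookup = {
            (d, e.zone): e.spec
            for e in self.entries
            for d in range(e.day_start, e.day_end + 1)
        }

    def _validate(self) -> None:
        problems = []
        for e in self.entries:
            if e.day_start < 1 or e.day_end < e.day_start:
                problems.append(f"bad day range {e.day_start}-{e.day_end}")
        seen: dict[tuple[int, int], int] = {}
        for e in self.entries:
            for d in range(e.day_start, e.day_end + 1):
                seen[(d, e.zone)] = seen.get((d, e.zone), 0) + 1
        for (d, z), c in seen.items():
            if c > 1:
                problems.append(f"day {d} zone {z} covered {c} times")
        for d in range(1, self.day_max + 1):
            for z in self.zones:
                if (d, z) not in seen:
                    problems.append(f"day {d} zone {z} uncovered")
        if problems:
            raise ValueError(
                f"profile {self.name!r} schedule invalid: " + "; ".join(problems)
            )

    def spec_for(self, day: int, zone: int) -> ZonePerformanceSpec:
        try:
            return self._lookup[(day, zone)]
        except KeyError:
            raise ScheduleGapError(
                f"profile {self.name!r} does not cover day {day}, zone {zone}"
            ) from None

    def sample(self, day: int, zone: int, rng: np.random.Generator) -> KinematicSample:
        return self.spec_for(day, zone).sample(rng)


def sample_performance(
    profile: PatientProfile, day: int, zone: int, rng: np.random.Generator
) -> KinematicSample:
    """Draw one presentation's outcome for (day, zone) under the profile."""
    return profile.sample(day, zone, rng)


# -- built-in test cases --------------------------------------------------

_EASE = ZonePerformanceSpec.uniform(0.8, 0.9)  # "pops with ease"
_NOPOP = ZonePerformanceSpec.unreachable()  # "can't reach, can't pop"


def _test_case_1() -> PatientProfile:
    """Stroke patient: corner zone becomes reachable from day 4 onward."""
    c = ZonePerformanceSpec.constant
    rows = [
        (1, 3, 1, _NOPOP),
        (1, 3, 2, c((0.3, 0.5, 0.7, 0.6))),
        (1, 3, 3, _EASE),
        (4, 6, 1, c((0.4, 0.4, 0.4, 0.4))),
        (4, 6, 2, c((0.6, 0.8, 0.8, 0.9))),
        (4, 6, 3, _EASE),
        (7, 10, 1, c((0.4, 0.4, 0.4, 0.4))),
        (7, 10, 2, c((0.6, 0.6, 0.6, 0.6))),
        (7, 10, 3, _EASE),
    ]
    return PatientProfile("test_case_1", [ScheduleEntry(*r) for r in rows])


def _test_case_2() -> PatientProfile:
    """Frozen shoulder: pain removes zones 1-2 on days 4-6, then recovery."""
    c = ZonePerformanceSpec.constant
    degraded = ZonePerformanceSpec.uniform(0.24, 0.27)  # 30% of good performance
    rows = [
        (1, 3, 1, _NOPOP),
        (1, 3, 2, c((0.3, 0.5, 0.7, 0.6))),
        (1, 3, 3, _EASE),
        (4, 6, 1, _NOPOP),
        (4, 6, 2, _NOPOP),
        (4, 6, 3, degraded),
        (7, 10, 1, _NOPOP),
        (7, 10, 2, c((0.3, 0.5, 0.7, 0.6))),
        (7, 10, 3, _EASE),
    ]
    return PatientProfile("test_case_2", [ScheduleEntry(*r) for r in rows])


BUILTIN_PROFILES = {"test_case_1": _test_case_1, "test_case_2": _test_case_2}


def builtin_profile(name: str) -> PatientProfile:
    """One of the two canonical simulated patients, by name."""
    try:
        return BUILTIN_PROFILES[name]()
    except KeyError:
        raise KeyError(
            f"unknown built-in profile {name!r}; "
            f"choose from {sorted(BUILTIN_PROFILES)}"
        ) from None


# -- structured-text round trip -------------------------------------------

def _spec_to_dict(spec: ZonePerformanceSpec) -> dict:
    if spec.kind == "constant":
        m = list(spec.values)
    else:
        m = [list(pair) for pair in spec.values]
    return {"pop": spec.pop_flag, "m": m}


def _spec_from_dict(d: dict) -> ZonePerformanceSpec:
    m = d["m"]
    if len(m) != 4:
        raise ValueError("'m' must list four values or four [low, high] pairs")
    pop = bool(d["pop"])
    if all(isinstance(v, (list, tuple)) for v in m):
        return ZonePerformanceSpec(pop, "uniform-range",
                                   tuple((float(lo), float(hi)) for lo, hi in m))
    if not pop:
        return ZonePerformanceSpec.unreachable()
    return ZonePerformanceSpec.constant([float(v) for v in m])


def profile_to_dict(profile: PatientProfile) -> dict:
    return {
        "name": profile.name,
        "schedule": [
            {"days": [e.day_start, e.day_end], "zone": e.zone,
             **_spec_to_dict(e.spec)}
            for e in profile.entries
        ],
    }


def profile_from_dict(d: dict) -> PatientProfile:
    entries = [
        ScheduleEntry(int(row["days"][0]), int(row["days"][1]),
                      int(row["zone"]), _spec_from_dict(row))
        for row in d["schedule"]
    ]
    return PatientProfile(str(d["name"]), entries)


def load_profile(path: str | Path) -> PatientProfile:
    """Read a profile from a YAML or JSON schedule file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return profile_from_dict(data)


def save_profile(profile: PatientProfile, path: str | Path) -> None:
    path = Path(path)
    data = profile_to_dict(profile)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
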