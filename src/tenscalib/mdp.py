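"""The calibration Markov decision process.

Two agents are trained, one per target perceived-intensity level (a "low"
just-perceivable sensation and a "high" strong but non-painful one, anchored
at ratings 2 and 8 on a 0-10 scale).  Both share the same 13 states and the
same 9 actions; they differ only in which intensity class counts as the
target, which reorders state desirability and hence the reward table.

States are ordered prioritising (1) perceived intensity, (2) location,
(3) type.  Uncomfortable/too-strong states carry increasingly negative
reward, desired states increasingly positive reward, and the not-perceived
state sits at a zero pivot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import (
    Intensity,
    Location,
    N_STATES,
    ParamGrid,
    SensationReport,
    SensationType,
    StimParams,
    encode_state,
)

__all__ = [
    "Action",
    "RewardTable",
    "enumerate_actions",
    "IDENTITY_ACTION_INDEX",
    "apply_action",
    "state_ordering",
    "default_reward_table",
    "reward",
    "discounted_return",
]


@dataclass(frozen=True)
class Action:
    """A parameter delta: PA shifts by -1/0/+1 mA, PW by -10/0/+10 µs."""

    d_pa: int
    d_pw: int


def enumerate_actions() -> tuple[Action, ...]:
    """The 9 actions in canonical order (d_pa major, d_pw minor).

    The position of an action in this tuple is the index of the Q-network
    output neuron that scores it.
    """
    return tuple(
        Action(d_pa, d_pw) for d_pa in (-1, 0, 1) for d_pw in (-10, 0, 10)
    )


IDENTITY_ACTION_INDEX = enumerate_actions().index(Action(0, 0))


def apply_action(p: StimParams, a: Action, grid: ParamGrid) -> StimParams:
    """Shift parameters by an action, clamping at the grid boundary."""
    p.validate(grid)
    pa = min(max(p.pa + a.d_pa, grid.pa_values[0]), grid.pa_values[-1])
    pw = min(max(p.pw + a.d_pw, grid.pw_values[0]), grid.pw_values[-1])
    return StimParams(pa=pa, pw=pw)


def _perceived_intensity_order(level: str) -> list[Intensity]:
    """Perceived intensity classes from least to most desirable.

    Too-high is always the worst perceived class; the non-target safe class
    sits in between; the target class is best.
    """
    if level == "low":
        return [Intensity.TOO_HIGH, Intensity.HIGH, Intensity.LOW]
    if level == "high":
        return [Intensity.TOO_HIGH, Intensity.LOW, Intensity.HIGH]
    raise ValueError(f"level must be 'low' or 'high', got {level!r}")


def state_ordering(level: str) -> list[int]:
    """All 13 state ids ranked from least (rank 0) to most desirable.

    Within each intensity class, somatotopic beats not-somatotopic, and
    comfortable beats uncomfortable (intensity > location > type priority).
    The not-perceived state is placed at the zero-reward pivot between the
    negatively rewarded states and the target-intensity states.
    """
    ordering: list[int] = []
    for intensity in _perceived_intensity_order(level):
        block = [
            encode_state(SensationReport(intensity=intensity, stype=t, location=loc))
            for loc in (Location.NOT_SOMATOTOPIC, Location.SOMATOTOPIC)
            for t in (SensationType.UNCOMFORTABLE, SensationType.COMFORTABLE)
        ]
        if intensity == _perceived_intensity_order(level)[-1]:
            ordering.append(0)  # not-perceived pivot just below the targets
        ordering.extend(block)
    return ordering


#: Discrete nonlinear rewards assigned by rank: too-high block (worst
#: first), then the safe-but-wrong intensity block, the zero pivot, and the
#: target block topping out at +1.  Magnitudes are kept of order one so the
#: discounted state values stay within easy reach of a small critic network.
_DEFAULT_RANK_REWARDS = (-1.0, -0.9, -0.8, -0.6, -0.4, -0.3, -0.2, -0.1,
                         0.0, 0.2, 0.4, 0.6, 1.0)


@dataclass(frozen=True)
class RewardTable:
    """State-id -> reward map for one agent level, plus its ordering."""

    level: str
    values: dict
    ordering: tuple

    def __post_init__(self) -> None:
        if set(self.values) != set(range(N_STATES)):
            raise ValueError("reward table must cover state ids 0..12 exactly")
        if self.values[0] != 0.0:
            raise ValueError("not-perceived state must carry zero reward")
        ranked = [self.values[s] for s in self.ordering]
        if any(a >= b for a, b in zip(ranked, ranked[1:])):
            raise ValueError("rewards must strictly increase with desirability")


def default_reward_table(level: str) -> RewardTable:
    ordering = tuple(state_ordering(level))
    values = {s: r for s, r in zip(ordering, _DEFAULT_RANK_REWARDS)}
    return RewardTable(level=level, values=values, ordering=ordering)


def reward(state_id: int, table: RewardTable) -> float:
    return table.values[state_id]


def discounted_return(rewards: Iterable[float], gamma: float) -> float:
    """G = sum_k gamma^k r_k for a finite reward sequence."""
    total = 0.0
    g = 1.0
    for r in rewards:
        total += g * r
        g *= gamma
    return total
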