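"""Stimulation parameter space, sensation reports and derived quantities.

Transcutaneous electrical nerve stimulation (TENS) for somatosensory
feedback delivers trains of biphasic current pulses; calibration searches a
discrete grid of pulse amplitude (PA, mA) and pulse width (PW, µs) at fixed
train frequency.  The subject's answer to a stimulus has three categorical
components -- perceived intensity (4 levels), sensation type (2 classes) and
location (2 classes) -- plus a 0-10 rating of the unwanted sensation felt
directly under the electrodes ("in-loco", SE).

This module defines those types, the injected charge Q = PA*PW, the encoding
of reports into the 13 Markov-decision-process states used by the learning
agents, and the sensation quality index that grades a finished calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Intensity",
    "SensationType",
    "Location",
    "ParamGrid",
    "StimParams",
    "SensationReport",
    "QualityWeights",
    "N_STATES",
    "charge",
    "encode_state",
    "decode_state",
    "state_features",
    "quality_index",
]


class Intensity(IntEnum):
    """Perceived intensity class, ordered by evoked drive."""

    NOT_PERCEIVED = 0
    LOW = 1
    HIGH = 2
    TOO_HIGH = 3


class SensationType(IntEnum):
    UNCOMFORTABLE = 0
    COMFORTABLE = 1


class Location(IntEnum):
    NOT_SOMATOTOPIC = 0
    SOMATOTOPIC = 1


#: Number of distinct MDP states: 3 perceived intensities x 2 types x 2
#: locations, plus the single collapsed "not perceived" state.  The raw
#: component product would give 16 combinations, but a subject cannot
#: describe the type or location of a sensation that was never felt.
N_STATES = 13


@dataclass(frozen=True)
class ParamGrid:
    """The discrete (PA, PW) search space.

    Defaults: PA in 1..16 mA (1 mA step), PW in 70..600 µs (10 µs step),
    50 Hz trains of 2 s.  The stimulator hardware resolves amplitude down to
    0.5 mA, but the action space moves in 1 mA steps, so the grid does too;
    the finer hardware resolution is kept as metadata only.
    """

    pa_values: tuple = tuple(range(1, 17))
    pw_values: tuple = tuple(range(70, 601, 10))
    frequency: float = 50.0
    train_duration: float = 2.0
    hardware_pa_resolution: float = 0.5

    @property
    def pa_step(self) -> float:
        return self.pa_values[1] - self.pa_values[0]

    @property
    def pw_step(self) -> float:
        return self.pw_values[1] - self.pw_values[0]

    def contains(self, pa: float, pw: float) -> bool:
        return pa in self.pa_values and pw in self.pw_values

    def clip(self, pa: float, pw: float) -> "StimParams":
        """Snap an off-grid pair onto the nearest grid point."""
        pa_arr = np.asarray(self.pa_values)
        pw_arr = np.asarray(self.pw_values)
        return StimParams(
            pa=float(pa_arr[np.argmin(np.abs(pa_arr - pa))]),
            pw=float(pw_arr[np.argmin(np.abs(pw_arr - pw))]),
        )


@dataclass(frozen=True, order=True)
class StimParams:
    """A (pulse amplitude, pulse width) point; units mA and µs."""

    pa: float
    pw: float

    def validate(self, grid: ParamGrid) -> "StimParams":
        if not grid.contains(self.pa, self.pw):
            raise ValueError(f"({self.pa} mA, {self.pw} µs) is not on the grid")
        return self


@dataclass(frozen=True)
class SensationReport:
    """A subject's description of one stimulus.

    ``se`` is the in-loco intensity (0-10) under the electrodes; it is only
    used when scoring a finished mapping, never inside the RL state.  When
    ``intensity`` is NOT_PERCEIVED the other fields are meaningless and are
    ignored by every consumer.
    """

    intensity: Intensity
    stype: SensationType = SensationType.COMFORTABLE
    location: Location = Location.NOT_SOMATOTOPIC
    se: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.se <= 10:
            raise ValueError(f"in-loco intensity se={self.se} outside [0, 10]")


@dataclass(frozen=True)
class QualityWeights:
    """Weights of the sensation quality index; they sum to 1."""

    w1: float = 0.6  # intensity reached
    w2: float = 0.15  # comfortable type
    w3: float = 0.25  # somatotopic location, discounted by in-loco sensation


def charge(p: StimParams, grid: ParamGrid | None = None) -> float:
    """Injected charge per phase Q = PA * PW, in µC (mA * µs / 1000)."""
    if grid is not None:
        p.validate(grid)
    return p.pa * p.pw / 1000.0


def encode_state(report: SensationReport) -> int:
    """Map a report onto one of the 13 MDP state ids.

    All not-perceived reports collapse onto id 0.  Perceived states are laid
    out as ``1 + 4*(intensity-1) + 2*location + type`` so that ids 1-4 are
    the low-intensity states, 5-8 high, 9-12 too high.
    """
    if report.intensity == Intensity.NOT_PERCEIVED:
        return 0
    return (
        1
        + 4 * (int(report.intensity) - 1)
        + 2 * int(report.location)
        + int(report.stype)
    )


def decode_state(state_id: int) -> SensationReport:
    """Inverse of :func:`encode_state` (canonical representative for id 0)."""
    if not 0 <= state_id < N_STATES:
        raise ValueError(f"state id {state_id} outside 0..{N_STATES - 1}")
    if state_id == 0:
        return SensationReport(intensity=Intensity.NOT_PERCEIVED)
    k = state_id - 1
    return SensationReport(
        intensity=Intensity(1 + k // 4),
        location=Location((k % 4) // 2),
        stype=SensationType(k % 2),
    )


def state_features(state_id: int) -> np.ndarray:
    """The 3-component network input for a state, each scaled to [0, 1].

    Components are (intensity code / 3, type, location); the collapsed
    not-perceived state is the all-zero vector.
    """
    r = decode_state(state_id)
    if r.intensity == Intensity.NOT_PERCEIVED:
        return np.zeros(3)
    return np.array([int(r.intensity) / 3.0, float(r.stype), float(r.location)])


def quality_index(
    intensity_reached: int,
    comfortable: int,
    somatotopic: int,
    se: int,
    weights: QualityWeights = QualityWeights(),
) -> float:
    """Sensation quality index Q = w1*I + w2*T + w3*L*(1 - SE/10).

    ``I``, ``T`` and ``L`` are binary flags: target intensity level reached,
    comfortable type, somatotopic location.  ``SE`` penalises a somatotopic
    sensation that is accompanied by a strong sensation under the electrodes.
    The score lies in [0, 1] with 1 the ideal mapping.
    """
    if not 0 <= se <= 10:
        raise ValueError(f"se={se} outside [0, 10]")
    for name, v in (("I", intensity_reached), ("T", comfortable), ("L", somatotopic)):
        if v not in (0, 1):
            raise ValueError(f"{name} must be 0 or 1, got {v}")
    w = weights
    return w.w1 * intensity_reached + w.w2 * comfortable + w.w3 * somatotopic * (
        1.0 - se / 10.0
    )
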