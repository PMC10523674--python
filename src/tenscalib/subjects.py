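"""Synthetic subjects with psychometric ground truth.

A virtual subject answers a TENS stimulus the way a study participant
would: perceived intensity follows a strength-duration law (Weiss-Lapicque:
threshold current ``rheobase * (1 + chronaxie / PW)``), the evoked rating
grows linearly with supra-threshold drive up to a pain level set by a
multiplicative ``pain_margin``; the percept is somatotopic once the drive
recruits the nerve trunk and stays so until a charge cap (current spread)
is exceeded, and comfort is lost above a slightly lower charge cap.  Each
subject stores its
ground-truth (PA, PW) pairs for the low (rating 2) and high (rating 8)
targets, so oracle tests can check that search policies actually recover
them.

Cohort sampling reproduces the composition of the offline dataset this
system is trained against: 49 subjects (27 men, 22 women) contributing 888
trials split 552/108/228 across the peroneal, tibial and sural nerves.
Neuropathic subjects have their rheobase scaled up, which roughly doubles
the charge needed at both target levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    Intensity,
    Location,
    ParamGrid,
    SensationReport,
    SensationType,
    StimParams,
    charge,
)

__all__ = [
    "NERVES",
    "VirtualSubject",
    "CohortSpec",
    "threshold_current",
    "respond",
    "sample_cohort",
    "target_charge",
    "generate_trials",
    "TRIAL_COLUMNS",
]

NERVES = ("peroneal", "tibial", "sural")

#: Rating bands mapping the 0-10 perceived scale onto intensity classes.
#: The low and high targets (ratings 2 and 8) sit inside the low and high
#: bands; 10 is pain.
RATING_BANDS = {"not_perceived": 0.5, "low": 5.0, "high": 9.0}

TRIAL_COLUMNS = [
    "subject_id", "gender", "weight_kg", "nerve", "neuropathic",
    "pa_mA", "pw_us", "intensity", "stype", "location", "se",
]


@dataclass(frozen=True)
class VirtualSubject:
    """Ground-truth psychometric model of one subject x nerve."""

    subject_id: str
    gender: str  # "M" or "F"
    weight: float  # kg
    nerve: str
    neuropathic: bool
    rheobase: float  # mA, threshold current as PW -> infinity
    chronaxie: float  # µs, PW at which threshold = 2 * rheobase
    pain_margin: float  # pain current / rheobase, > 1
    comfort_band: tuple  # (µC, µC): charges evoking a comfortable type
    somatotopy_band: tuple  # (µC, µC): charge range where the percept projects to the foot
    se_slope: float  # in-loco intensity per unit normalized drive
    rng_seed: int
    target_low: StimParams  # grid pair evoking rating ~2 (level "low")
    target_high: StimParams  # grid pair evoking rating ~8 (level "high")
    rating_noise_sd: float = 0.0
    label_flip_prob: float = 0.0
    #: minimum normalized drive recruiting the nerve trunk: below it nothing
    #: projects distally (same strength-duration law as perception), above it
    #: the sensation is somatotopic until the charge cap is exceeded
    som_drive_min: float = 0.05

    def covariates(self) -> dict:
        return {
            "gender": self.gender,
            "weight_kg": self.weight,
            "nerve": self.nerve,
            "neuropathic": int(self.neuropathic),
        }


def threshold_current(s: VirtualSubject, pw: float) -> float:
    """Perception-threshold current (mA) at pulse width ``pw`` (µs)."""
    if pw <= 0:
        raise ValueError(f"pulse width must be positive, got {pw}")
    return s.rheobase * (1.0 + s.chronaxie / pw)


def target_charge(s: VirtualSubject, level: str, pw: float) -> float:
    """Ground-truth charge (µC) evoking the level's target rating at ``pw``.

    The target rating (2 for the low level, 8 for the high one) is reached at
    pa = threshold(pw) + rating/10 * (pain_margin - 1) * rheobase; the charge
    follows the strength-duration law and therefore depends on the pulse
    width at which the level is elicited.
    """
    rating = {"low": 2.0, "high": 8.0}[level]
    pa = threshold_current(s, pw) + rating / 10.0 * (s.pain_margin - 1.0) * s.rheobase
    return pa * pw / 1000.0


def _drive(s: VirtualSubject, pa, pw):
    """Normalized supra-threshold drive: 0 at threshold, 1 at pain level."""
    thr = s.rheobase * (1.0 + s.chronaxie / np.asarray(pw, dtype=float))
    return (np.asarray(pa, dtype=float) - thr) / ((s.pain_margin - 1.0) * s.rheobase)


def _rating(s: VirtualSubject, pa, pw):
    return np.clip(10.0 * _drive(s, pa, pw), 0.0, 10.0)


def _intensity_from_rating(r: float) -> Intensity:
    if r < RATING_BANDS["not_perceived"]:
        return Intensity.NOT_PERCEIVED
    if r < RATING_BANDS["low"]:
        return Intensity.LOW
    if r < RATING_BANDS["high"]:
        return Intensity.HIGH
    return Intensity.TOO_HIGH


def respond(s: VirtualSubject, p: StimParams, grid: ParamGrid | None = None) -> SensationReport:
    """The subject's report for one stimulus.

    Deterministic given (subject, stimulus): optional rating jitter and
    type/location label flips are drawn from a stream seeded by the subject
    seed and the stimulus coordinates, so repeated delivery of the same
    train yields the same answer.
    """
    if grid is not None:
        p.validate(grid)
    d = float(_drive(s, p.pa, p.pw))
    r = float(np.clip(10.0 * d, 0.0, 10.0))
    flip_type = flip_loc = False
    if s.rating_noise_sd > 0.0 or s.label_flip_prob > 0.0:
        rng = np.random.default_rng(
            np.random.SeedSequence([s.rng_seed, int(round(p.pa * 2)), int(round(p.pw))])
        )
        if s.rating_noise_sd > 0.0:
            r = float(np.clip(r + rng.normal(0.0, s.rating_noise_sd), 0.0, 10.0))
        if s.label_flip_prob > 0.0:
            flip_type = rng.random() < s.label_flip_prob
            flip_loc = rng.random() < s.label_flip_prob
    intensity = _intensity_from_rating(r)
    q = charge(p)
    comfortable = s.comfort_band[0] <= q <= s.comfort_band[1]
    somatotopic = (
        d >= s.som_drive_min and s.somatotopy_band[0] <= q <= s.somatotopy_band[1]
    )
    if flip_type:
        comfortable = not comfortable
    if flip_loc:
        somatotopic = not somatotopic
    se = int(np.clip(round(s.se_slope * max(d, 0.0) * 10.0), 0, 10))
    return SensationReport(
        intensity=intensity,
        stype=SensationType.COMFORTABLE if comfortable else SensationType.UNCOMFORTABLE,
        location=Location.SOMATOTOPIC if somatotopic else Location.NOT_SOMATOTOPIC,
        se=se,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition and parameter distributions of a synthetic cohort.

    Defaults reproduce the offline dataset's structure: 27 men and 22 women
    (49 subjects) contributing 552 peroneal, 108 tibial and 228 sural trials
    (888 total).  Parameter means are per-nerve; gender enters as a
    multiplicative factor on the rheobase and a shift on body weight.
    """

    n_men: int = 27
    n_women: int = 22
    trials_per_nerve: dict = field(
        default_factory=lambda: {"peroneal": 552, "tibial": 108, "sural": 228}
    )
    neuropathic_fraction: float = 0.0
    neuropathic_rheobase_factor: float = 2.0
    rheobase_mean: dict = field(
        default_factory=lambda: {"peroneal": 2.0, "tibial": 2.8, "sural": 2.2}
    )
    rheobase_sd: float = 0.25
    chronaxie_mean: float = 250.0  # µs
    chronaxie_sd: float = 30.0
    pain_margin_mean: float = 3.0
    pain_margin_sd: float = 0.3
    gender_rheobase_factor: dict = field(
        default_factory=lambda: {"M": 1.0, "F": 0.9}
    )
    weight_mean: dict = field(default_factory=lambda: {"M": 80.0, "F": 65.0})
    weight_sd: float = 9.0
    se_slope_mean: float = 0.15
    se_slope_sd: float = 0.05
    rating_noise_sd: float = 0.0
    label_flip_prob: float = 0.0
    seed: int = 0


def _nerve_assignment(spec: CohortSpec, n: int) -> list[str]:
    """Assign each subject a nerve, proportional to the trial split."""
    total = sum(spec.trials_per_nerve.values())
    if total == 0 or n == 0:
        return [NERVES[0]] * n
    quotas = {nv: n * spec.trials_per_nerve.get(nv, 0) / total for nv in NERVES}
    counts = {nv: int(np.floor(q)) for nv, q in quotas.items()}
    remainder = n - sum(counts.values())
    for nv in sorted(NERVES, key=lambda nv: quotas[nv] - counts[nv], reverse=True):
        if remainder <= 0:
            break
        counts[nv] += 1
        remainder -= 1
    out: list[str] = []
    for nv in NERVES:
        out.extend([nv] * counts[nv])
    return out


def _ground_truth_targets(
    rheobase: float, chronaxie: float, pain_margin: float, grid: ParamGrid
) -> tuple[StimParams, StimParams]:
    """Grid pairs whose noiseless rating is closest to 2 and 8.

    Exhaustive scan of the grid; ties broken toward lower charge so the
    stored target is the safest pair achieving the level.
    """
    pa = np.asarray(grid.pa_values, dtype=float)[:, None]
    pw = np.asarray(grid.pw_values, dtype=float)[None, :]
    thr = rheobase * (1.0 + chronaxie / pw)
    rating = np.clip(10.0 * (pa - thr) / ((pain_margin - 1.0) * rheobase), 0.0, 10.0)
    q = pa * pw / 1000.0
    out = []
    for target in (2.0, 8.0):
        err = np.abs(rating - target)
        # lexicographic: rating error first, then charge
        score = err + 1e-6 * q / q.max()
        if out:  # the strong sensation must carry at least the low target's charge
            q_low = out[0].pa * out[0].pw / 1000.0
            score = np.where(q >= q_low, score, np.inf)
        i, j = np.unravel_index(np.argmin(score), score.shape)
        out.append(StimParams(pa=float(pa[i, 0]), pw=float(pw[0, j])))
    return out[0], out[1]


def sample_cohort(spec: CohortSpec, grid: ParamGrid | None = None) -> list[VirtualSubject]:
    """Draw a reproducible cohort of virtual subjects."""
    grid = grid or ParamGrid()
    n = spec.n_men + spec.n_women
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    nerves = _nerve_assignment(spec, n)
    # interleave genders across the nerve-ordered list so every nerve has both
    genders = ["M"] * spec.n_men + ["F"] * spec.n_women
    order = rng.permutation(n)
    genders = [genders[i] for i in order]
    n_neuro = int(round(spec.neuropathic_fraction * n))
    neuro_flags = np.zeros(n, dtype=bool)
    if n_neuro:
        neuro_flags[rng.choice(n, size=n_neuro, replace=False)] = True
    cohort = []
    for i in range(n):
        gender, nerve = genders[i], nerves[i]
        rb = rng.normal(spec.rheobase_mean[nerve], spec.rheobase_sd)
        rb = max(rb, 0.8) * spec.gender_rheobase_factor[gender]
        if neuro_flags[i]:
            rb *= spec.neuropathic_rheobase_factor
        cx = max(rng.normal(spec.chronaxie_mean, spec.chronaxie_sd), 80.0)
        pm = max(rng.normal(spec.pain_margin_mean, spec.pain_margin_sd), 1.5)
        weight = max(rng.normal(spec.weight_mean[gender], spec.weight_sd), 40.0)
        se_slope = float(np.clip(rng.normal(spec.se_slope_mean, spec.se_slope_sd), 0.0, 1.0))
        t_low, t_high = _ground_truth_targets(rb, cx, pm, grid)
        q_low, q_high = charge(t_low), charge(t_high)
        cohort.append(
            VirtualSubject(
                subject_id=f"S{i + 1:03d}",
                gender=gender,
                weight=round(weight, 1),
                nerve=nerve,
                neuropathic=bool(neuro_flags[i]),
                rheobase=rb,
                chronaxie=cx,
                pain_margin=pm,
                comfort_band=(0.0, 1.3 * q_high),
                somatotopy_band=(0.0, 1.5 * q_high),
                se_slope=se_slope,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                target_low=t_low,
                target_high=t_high,
                rating_noise_sd=spec.rating_noise_sd,
                label_flip_prob=spec.label_flip_prob,
            )
        )
    return cohort


def _ramp_trace(s: VirtualSubject, grid: ParamGrid) -> list[StimParams]:
    """Expert-style exploration of a subject's parameter space.

    Mirrors how characterizations are done by hand: a PA ramp at a fixed
    reasonable PW from the grid minimum until the sensation becomes
    somatotopic, then a PW ramp upward until the rating exceeds the high
    target, stopping at the first too-strong report.
    """
    pw0 = grid.clip(1.0, s.target_low.pw).pw
    trace: list[StimParams] = []
    p = StimParams(pa=grid.pa_values[0], pw=pw0)
    for _ in range(len(grid.pa_values)):
        trace.append(p)
        rep = respond(s, p)
        if rep.location == Location.SOMATOTOPIC and rep.intensity != Intensity.NOT_PERCEIVED:
            break
        if p.pa >= grid.pa_values[-1]:
            break
        p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
    for _ in range(len(grid.pw_values) + len(grid.pa_values)):
        if p.pw < grid.pw_values[-1]:
            p = StimParams(pa=p.pa, pw=p.pw + grid.pw_step)
        elif p.pa < grid.pa_values[-1]:
            p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
        else:
            break
        trace.append(p)
        if respond(s, p).intensity == Intensity.TOO_HIGH:
            break
    return trace


def _report_row(s: VirtualSubject, p: StimParams) -> dict:
    rep = respond(s, p)
    return {
        "subject_id": s.subject_id,
        "gender": s.gender,
        "weight_kg": s.weight,
        "nerve": s.nerve,
        "neuropathic": int(s.neuropathic),
        "pa_mA": p.pa,
        "pw_us": p.pw,
        "intensity": {0: "NP", 1: "LOW", 2: "HIGH", 3: "TOOHIGH"}[int(rep.intensity)],
        "stype": {0: "UNC", 1: "COM"}[int(rep.stype)],
        "location": {0: "NSOM", 1: "SOM"}[int(rep.location)],
        "se": rep.se,
    }


def generate_trials(
    cohort: list[VirtualSubject],
    spec: CohortSpec,
    grid: ParamGrid | None = None,
) -> pd.DataFrame:
    """Emit the offline trial table: one row per delivered stimulus.

    Each subject contributes a ramp-style trace around its own thresholds;
    if a nerve's quota exceeds what the ramps produce, extra stimuli are
    drawn around the subjects' target region (seeded), and the pool is
    trimmed to the exact per-nerve count.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    grid = grid or ParamGrid()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    rows: list[dict] = []
    for nerve in NERVES:
        quota = spec.trials_per_nerve.get(nerve, 0)
        members = [s for s in cohort if s.nerve == nerve]
        if quota and not members:
            raise ValueError(f"no subjects assigned to nerve {nerve!r}")
        # every subject contributes an even share of the nerve's quota,
        # subsampled uniformly along its ramp so the whole intensity range
        # (sub-threshold through too strong) stays represented
        shares = [quota // len(members)] * len(members) if members else []
        for i in range(quota - sum(shares)):
            shares[i] += 1
        pool: list[tuple[VirtualSubject, StimParams]] = []
        for s, share in zip(members, shares):
            trace = _ramp_trace(s, grid)
            if share <= len(trace):
                idx = np.unique(np.linspace(0, len(trace) - 1, share).round().astype(int))
            else:
                idx = np.arange(len(trace))
            pool.extend((s, trace[i]) for i in idx)
            for k in range(share - len(idx)):  # ramp shorter than the share
                base = s.target_low if k % 2 == 0 else s.target_high
                p = grid.clip(
                    base.pa + rng.integers(-2, 3) * grid.pa_step,
                    base.pw + rng.integers(-5, 6) * grid.pw_step,
                )
                pool.append((s, p))
        rows.extend(_report_row(s, p) for s, p in pool[:quota])
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
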