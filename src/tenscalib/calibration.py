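"""Closed-loop calibration: RL policy, brute-force and naive baselines.

Online, the trained agents face a real responder instead of the fitted
models; here a responder is anything exposing ``respond(StimParams) ->
SensationReport`` plus the subject covariates.  The RL calibration chains
two greedy phases: the low-level search starts from the safest (minimum
charge) low-level parameters recorded in the reference dataset for the
subject's gender and nerve, and the high-level search starts from the
high-level parameters paired with the found low-level pair in the dataset
(falling back to the low-level pair itself when no previous subject
reported the same threshold).

The brute-force algorithm (BFA) is the non-adaptive baseline: a monotone
charge sweep (PW-major at fixed PA, advancing PA when a further PW step
would overtake the next amplitude's starting charge) that stops at the
first stimulus reported at the target intensity with somatotopic location.
Because it can only increase charge, it fails when the target band lies
below its initialization.  The scripted naive protocol mirrors the fixed
instructions given to inexperienced experimenters: a PA ramp at a fixed
reasonable PW until the sensation is somatotopic, then a PW ramp for the
low and high targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Intensity,
    Location,
    ParamGrid,
    SensationReport,
    StimParams,
    charge,
)
from .dqn import DQNAgent
from .environment import EnvModels, env_step
from .mdp import enumerate_actions, apply_action
from .core import state_features, encode_state
from . import subjects as vs

__all__ = [
    "VirtualResponder",
    "EnvResponder",
    "CalibrationLimits",
    "CalibrationResult",
    "init_low_params",
    "init_high_params",
    "run_calibration",
    "bfa_calibrate",
    "scripted_naive_calibrate",
]


@dataclass
class VirtualResponder:
    """Adapter presenting a virtual subject as an online responder."""

    subject: vs.VirtualSubject

    @property
    def gender(self) -> str:
        return self.subject.gender

    @property
    def nerve(self) -> str:
        return self.subject.nerve

    def respond(self, p: StimParams) -> SensationReport:
        return vs.respond(self.subject, p)


@dataclass
class EnvResponder:
    """Adapter presenting the fitted simulated environment as a responder.

    The three models do not predict the in-loco intensity, so SE is 0.
    """

    models: EnvModels
    gender: str
    weight: float
    nerve: str

    def respond(self, p: StimParams) -> SensationReport:
        _, report = env_step(self.models, self.gender, self.weight, self.nerve, p)
        return report


@dataclass(frozen=True)
class CalibrationLimits:
    step_cap: int = 100  # per phase
    convergence_window: int = 5  # identical parameter pairs in a row
    too_high_abort: int = 3  # consecutive too-strong reports abort the phase


@dataclass
class CalibrationResult:
    low_params: StimParams | None
    high_params: StimParams | None
    n_stims: int
    trace: list  # ordered (StimParams, SensationReport) pairs, all phases
    converged_low: bool
    converged_high: bool
    aborted: bool = False
    low_report: SensationReport | None = None
    high_report: SensationReport | None = None


def init_low_params(
    dataset: pd.DataFrame, gender: str, nerve: str, grid: ParamGrid | None = None
) -> StimParams:
    """Safest starting point: the minimum-charge somatotopic low-level row
    for the subject's gender and nerve.

    Only somatotopic rows qualify -- a recorded low-level working point is a
    completed characterization, which is somatotopic by definition -- with
    fallbacks to any low-level row and to the whole dataset when the
    gender x nerve subgroup is empty.
    """
    low = dataset[dataset["intensity"] == "LOW"]
    if low.empty:
        raise ValueError("dataset contains no low-level rows")
    som = low[low["location"] == "SOM"]
    pool = som if not som.empty else low
    sub = pool[(pool["gender"] == gender) & (pool["nerve"] == nerve)]
    if sub.empty:
        sub = pool
    q = sub["pa_mA"] * sub["pw_us"]
    # ties: lower charge, then lower PA, then lower PW
    order = sub.assign(_q=q).sort_values(["_q", "pa_mA", "pw_us"], kind="stable")
    row = order.iloc[0]
    p = StimParams(pa=float(row["pa_mA"]), pw=float(row["pw_us"]))
    return p.validate(grid) if grid is not None else p


def init_high_params(dataset: pd.DataFrame, low_params: StimParams) -> StimParams:
    """Dataset-matching initialization of the high-level search.

    If any previous subject reported the same low-level parameters, start
    from the minimum-charge high-level pair of those subjects; otherwise
    start from the low-level parameters themselves.
    """
    low = dataset[
        (dataset["intensity"] == "LOW")
        & (dataset["pa_mA"] == low_params.pa)
        & (dataset["pw_us"] == low_params.pw)
    ]
    if low.empty:
        return low_params
    donors = set(low["subject_id"])
    high = dataset[
        (dataset["intensity"] == "HIGH") & (dataset["subject_id"].isin(donors))
    ]
    som = high[high["location"] == "SOM"]
    high = som if not som.empty else high
    if high.empty:
        return low_params
    q = high["pa_mA"] * high["pw_us"]
    order = high.assign(_q=q).sort_values(["_q", "pa_mA", "pw_us"], kind="stable")
    row = order.iloc[0]
    return StimParams(pa=float(row["pa_mA"]), pw=float(row["pw_us"]))


def _greedy_phase(
    agent: DQNAgent,
    responder,
    start: StimParams,
    target: Intensity,
    limits: CalibrationLimits,
    grid: ParamGrid,
) -> tuple[StimParams, bool, bool, list]:
    """One greedy agent phase; returns (final params, converged, aborted, trace).

    The phase finishes successfully as soon as the subject reports the
    desired sensation (target intensity, somatotopic).  It stops
    unsuccessfully when the chosen parameters stall (unchanged for the
    convergence window without reaching the target), after three consecutive
    too-strong reports (safety abort), or at the step cap.
    """
    actions = enumerate_actions()
    trace: list = []
    p = start
    history: list[StimParams] = []
    consec_too_high = 0
    converged = False
    aborted = False
    while len(trace) < limits.step_cap:
        report = responder.respond(p)
        trace.append((p, report))
        history.append(p)
        if report.intensity == target and report.location == Location.SOMATOTOPIC:
            converged = True
            break
        if report.intensity == Intensity.TOO_HIGH:
            consec_too_high += 1
            if consec_too_high >= limits.too_high_abort:
                aborted = True
                break
        else:
            consec_too_high = 0
        if len(history) >= limits.convergence_window and all(
            h == history[-1] for h in history[-limits.convergence_window :]
        ):
            break  # stalled short of the target
        a = actions[agent.greedy(state_features(encode_state(report)))]
        p = apply_action(p, a, grid)
    return p if not trace else trace[-1][0], converged, aborted, trace


def run_calibration(
    agent_low: DQNAgent,
    agent_high: DQNAgent,
    responder,
    dataset: pd.DataFrame,
    limits: CalibrationLimits = CalibrationLimits(),
    grid: ParamGrid | None = None,
    previous: CalibrationResult | None = None,
) -> CalibrationResult:
    """Full two-phase RL calibration against an online responder.

    ``previous`` (e.g. the result of an earlier session on the same nerve)
    overrides the dataset initialization of both phases.
    """
    grid = grid or ParamGrid()
    if previous is not None and previous.low_params is not None:
        start_low = previous.low_params
    else:
        start_low = init_low_params(dataset, responder.gender, responder.nerve, grid)
    low_params, conv_low, aborted_low, trace_low = _greedy_phase(
        agent_low, responder, start_low, Intensity.LOW, limits, grid
    )
    if previous is not None and previous.high_params is not None:
        start_high = previous.high_params
    else:
        start_high = init_high_params(dataset, low_params)
    high_params, conv_high, aborted_high, trace_high = _greedy_phase(
        agent_high, responder, start_high, Intensity.HIGH, limits, grid
    )
    trace = trace_low + trace_high
    return CalibrationResult(
        low_params=low_params,
        high_params=high_params,
        n_stims=len(trace),
        trace=trace,
        converged_low=conv_low,
        converged_high=conv_high,
        aborted=aborted_low or aborted_high,
        low_report=trace_low[-1][1] if trace_low else None,
        high_report=trace_high[-1][1] if trace_high else None,
    )


def _charge_sweep(start: StimParams, grid: ParamGrid):
    """PW-major monotone ramp over the grid from a starting pair.

    PW ramps upward in 10 µs steps at fixed PA (charge nondecreasing within
    each amplitude level); when PW exhausts the grid, PA advances by 1 mA
    and PW resets to the phase's starting value.
    """
    pa, pw = start.pa, start.pw
    pw0 = start.pw
    yield StimParams(pa=pa, pw=pw)
    while True:
        if pw + grid.pw_step <= grid.pw_values[-1]:
            pw += grid.pw_step
        elif pa < grid.pa_values[-1]:
            pa, pw = pa + grid.pa_step, pw0
        else:
            return
        yield StimParams(pa=pa, pw=pw)


def _sweep_until(responder, sweep, target: Intensity, limits, trace) -> tuple[StimParams | None, bool]:
    """Advance a sweep until the target intensity is reported somatotopic."""
    for p in sweep:
        if len(trace) >= limits.step_cap:
            return None, False
        report = responder.respond(p)
        trace.append((p, report))
        if report.intensity == target and report.location == Location.SOMATOTOPIC:
            return p, True
        if report.intensity == Intensity.TOO_HIGH:
            return None, False  # overshot: a monotone ramp cannot recover
    return None, False


def bfa_calibrate(
    responder,
    dataset: pd.DataFrame,
    limits: CalibrationLimits = CalibrationLimits(),
    grid: ParamGrid | None = None,
) -> CalibrationResult:
    """Brute-force baseline: monotone charge ramps from a dataset-derived
    start, for the low then the high target."""
    grid = grid or ParamGrid()
    low_rows = dataset[dataset["intensity"] == "LOW"]
    if low_rows.empty:
        raise ValueError("dataset contains no low-level rows")
    som = low_rows[low_rows["location"] == "SOM"]
    low_rows = som if not som.empty else low_rows
    q = low_rows["pa_mA"] * low_rows["pw_us"]
    row = low_rows.assign(_q=q).sort_values(["_q", "pa_mA", "pw_us"], kind="stable").iloc[0]
    start = grid.clip(float(row["pa_mA"]), float(row["pw_us"]))
    trace: list = []
    low_params, ok_low = _sweep_until(
        responder, _charge_sweep(start, grid), Intensity.LOW, limits, trace
    )
    high_params, ok_high = (None, False)
    if ok_low:
        n_low = len(trace)
        high_params, ok_high = _sweep_until(
            responder, _charge_sweep(low_params, grid), Intensity.HIGH, limits, trace
        )
    return CalibrationResult(
        low_params=low_params,
        high_params=high_params,
        n_stims=len(trace),
        trace=trace,
        converged_low=ok_low,
        converged_high=ok_high,
        low_report=None if not ok_low else trace[[p for p, _ in trace].index(low_params)][1],
        high_report=trace[-1][1] if ok_high else None,
    )


def scripted_naive_calibrate(
    responder,
    limits: CalibrationLimits = CalibrationLimits(),
    grid: ParamGrid | None = None,
    start_pw: float = 300.0,
) -> CalibrationResult:
    """Fixed naive protocol: PA ramp to somatotopy, then PW ramps to targets.

    Starts from the grid's minimum amplitude at a fixed "reasonable" pulse
    width, ramps PA in 1 mA steps until a perceived somatotopic sensation,
    then ramps PW in 10 µs steps until the low and subsequently the high
    target intensities are reported.
    """
    grid = grid or ParamGrid()
    start_pw = grid.clip(grid.pa_values[0], start_pw).pw
    trace: list = []
    p = StimParams(pa=grid.pa_values[0], pw=start_pw)
    somatotopic = None
    while len(trace) < limits.step_cap:
        report = responder.respond(p)
        trace.append((p, report))
        if (
            report.intensity not in (Intensity.NOT_PERCEIVED,)
            and report.location == Location.SOMATOTOPIC
        ):
            somatotopic = p
            break
        if report.intensity == Intensity.TOO_HIGH or p.pa >= grid.pa_values[-1]:
            break
        p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
    low_params = high_params = None
    low_report = high_report = None
    if somatotopic is not None:
        if trace[-1][1].intensity == Intensity.LOW:
            low_params, low_report = trace[-1]
        while low_params is None and p.pw < grid.pw_values[-1] and len(trace) < limits.step_cap:
            p = StimParams(pa=p.pa, pw=p.pw + grid.pw_step)
            report = responder.respond(p)
            trace.append((p, report))
            if report.intensity == Intensity.LOW and report.location == Location.SOMATOTOPIC:
                low_params, low_report = p, report
            if report.intensity >= Intensity.TOO_HIGH:
                break
        while (
            low_params is not None
            and high_params is None
            and (p.pw < grid.pw_values[-1] or p.pa < grid.pa_values[-1])
            and len(trace) < limits.step_cap
        ):
            # PW ramp toward the strong sensation; once PW is exhausted the
            # protocol falls back to amplitude increments
            if p.pw < grid.pw_values[-1]:
                p = StimParams(pa=p.pa, pw=p.pw + grid.pw_step)
            else:
                p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
            report = responder.respond(p)
            trace.append((p, report))
            if report.intensity == Intensity.HIGH and report.location == Location.SOMATOTOPIC:
                high_params, high_report = p, report
            if report.intensity >= Intensity.TOO_HIGH:
                break
    return CalibrationResult(
        low_params=low_params,
        high_params=high_params,
        n_stims=len(trace),
        trace=trace,
        converged_low=low_params is not None,
        converged_high=high_params is not None,
        low_report=low_report,
        high_report=high_report,
    )
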