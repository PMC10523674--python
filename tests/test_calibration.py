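"""Initialization rules, online phases and baseline calibrators."""

import numpy as np
import pandas as pd
import pytest

from tenscalib.calibration import (
    CalibrationLimits,
    VirtualResponder,
    bfa_calibrate,
    init_high_params,
    init_low_params,
    run_calibration,
    scripted_naive_calibrate,
)
from tenscalib.core import Intensity, Location, StimParams, charge
from tenscalib.dqn import DQNAgent, Hyperparams, QNetwork
from tenscalib.mdp import IDENTITY_ACTION_INDEX
from tenscalib.subjects import TRIAL_COLUMNS, VirtualSubject, respond


def dataset(rows) -> pd.DataFrame:
    """Trial table from (subject, gender, nerve, pa, pw, intensity, location)."""
    return pd.DataFrame(
        [
            {
                "subject_id": sid,
                "gender": g,
                "weight_kg": 75.0,
                "nerve": nerve,
                "neuropathic": 0,
                "pa_mA": float(pa),
                "pw_us": float(pw),
                "intensity": inten,
                "stype": "COM",
                "location": loc,
                "se": 0,
            }
            for sid, g, nerve, pa, pw, inten, loc in rows
        ],
        columns=TRIAL_COLUMNS,
    )


def make_subject(**overrides) -> VirtualSubject:
    base = dict(
        subject_id="T001",
        gender="M",
        weight=80.0,
        nerve="peroneal",
        neuropathic=False,
        rheobase=2.0,
        chronaxie=250.0,
        pain_margin=3.0,
        comfort_band=(0.0, 5.0),
        somatotopy_band=(0.0, 6.0),
        se_slope=0.2,
        rng_seed=7,
        target_low=StimParams(pa=5.0, pw=250.0),
        target_high=StimParams(pa=8.0, pw=250.0),
    )
    base.update(overrides)
    return VirtualSubject(**base)


def constant_agent(action_index: int, level: str = "low") -> DQNAgent:
    """An agent whose greedy choice is always the same action."""
    net = QNetwork((3, 40, 30, 9), seed=0)
    for W in net.weights:
        W[:] = 0.0
    for b in net.biases:
        b[:] = 0.0
    net.biases[-1][action_index] = 1.0
    return DQNAgent(net=net, target_net=net.copy(), hp=Hyperparams(), level=level)


class TestInitLow:
    def test_minimum_charge_row_wins(self):
        ds = dataset(
            [
                ("S1", "M", "peroneal", 2, 100, "LOW", "SOM"),  # q = 0.2
                ("S2", "M", "peroneal", 1, 300, "LOW", "SOM"),  # q = 0.3
            ]
        )
        assert init_low_params(ds, "M", "peroneal") == StimParams(pa=2.0, pw=100.0)

    def test_somatotopic_rows_preferred(self):
        ds = dataset(
            [
                ("S1", "M", "peroneal", 1, 100, "LOW", "NSOM"),  # cheaper but NSOM
                ("S2", "M", "peroneal", 2, 200, "LOW", "SOM"),
            ]
        )
        assert init_low_params(ds, "M", "peroneal") == StimParams(pa=2.0, pw=200.0)

    def test_falls_back_outside_subgroup(self):
        ds = dataset([("S1", "F", "sural", 3, 150, "LOW", "SOM")])
        assert init_low_params(ds, "M", "peroneal") == StimParams(pa=3.0, pw=150.0)

    def test_only_low_rows_considered(self):
        ds = dataset(
            [
                ("S1", "M", "peroneal", 1, 70, "NP", "NSOM"),
                ("S2", "M", "peroneal", 4, 400, "LOW", "SOM"),
                ("S3", "M", "peroneal", 1, 100, "HIGH", "SOM"),
            ]
        )
        assert init_low_params(ds, "M", "peroneal") == StimParams(pa=4.0, pw=400.0)

    def test_no_low_rows_rejected(self):
        ds = dataset([("S1", "M", "peroneal", 1, 70, "NP", "NSOM")])
        with pytest.raises(ValueError):
            init_low_params(ds, "M", "peroneal")


class TestInitHigh:
    def test_matching_subject_donates_high_pair(self):
        ds = dataset(
            [
                ("S1", "M", "peroneal", 3, 200, "LOW", "SOM"),
                ("S1", "M", "peroneal", 6, 300, "HIGH", "SOM"),
                ("S2", "M", "peroneal", 3, 200, "LOW", "SOM"),
                ("S2", "M", "peroneal", 5, 300, "HIGH", "SOM"),  # cheaper donor
            ]
        )
        got = init_high_params(ds, StimParams(pa=3.0, pw=200.0))
        assert got == StimParams(pa=5.0, pw=300.0)

    def test_no_match_returns_low_pair(self):
        ds = dataset([("S1", "M", "peroneal", 3, 200, "LOW", "SOM")])
        low = StimParams(pa=9.0, pw=410.0)
        assert init_high_params(ds, low) == low

    def test_charge_tie_breaks_to_lower_amplitude(self):
        ds = dataset(
            [
                ("S1", "M", "peroneal", 3, 200, "LOW", "SOM"),
                ("S1", "M", "peroneal", 4, 300, "HIGH", "SOM"),  # q = 1.2
                ("S1", "M", "peroneal", 6, 200, "HIGH", "SOM"),  # q = 1.2
            ]
        )
        got = init_high_params(ds, StimParams(pa=3.0, pw=200.0))
        assert got == StimParams(pa=4.0, pw=300.0)


class TestRunCalibration:
    def test_identity_agent_converges_immediately_on_target_init(self, grid):
        # the subject reports LOW somatotopic right at the dataset start
        s = make_subject()
        ds = dataset(
            [
                ("S1", "M", "peroneal", 5, 250, "LOW", "SOM"),
                ("S1", "M", "peroneal", 7, 250, "HIGH", "SOM"),
            ]
        )
        agent = constant_agent(IDENTITY_ACTION_INDEX)
        res = run_calibration(agent, agent, VirtualResponder(s), ds, grid=grid)
        assert res.converged_low
        assert res.low_params == StimParams(pa=5.0, pw=250.0)
        assert res.converged_high  # (7, 250) evokes rating 7.5 -> high
        assert res.high_params == StimParams(pa=7.0, pw=250.0)
        assert res.n_stims == 2  # one stimulus per phase

    def test_identity_agent_stalls_without_drifting(self, grid):
        s = make_subject()
        ds = dataset([("S1", "M", "peroneal", 1, 100, "LOW", "SOM")])  # NP for s
        agent = constant_agent(IDENTITY_ACTION_INDEX)
        limits = CalibrationLimits()
        res = run_calibration(agent, agent, VirtualResponder(s), ds, limits, grid)
        assert not res.converged_low
        assert res.low_params == StimParams(pa=1.0, pw=100.0)  # never moved
        # stalled after the convergence window in each phase
        assert res.n_stims == 2 * limits.convergence_window

    def test_previous_result_overrides_initialization(self, grid):
        s = make_subject()
        ds = dataset([("S1", "M", "peroneal", 1, 100, "LOW", "SOM")])
        agent = constant_agent(IDENTITY_ACTION_INDEX)
        from tenscalib.calibration import CalibrationResult

        previous = CalibrationResult(
            low_params=StimParams(pa=5.0, pw=250.0),
            high_params=StimParams(pa=7.0, pw=250.0),
            n_stims=0,
            trace=[],
            converged_low=True,
            converged_high=True,
        )
        res = run_calibration(
            agent, agent, VirtualResponder(s), ds, grid=grid, previous=previous
        )
        assert res.converged_low and res.converged_high
        assert res.n_stims == 2

    def test_all_stimuli_on_grid(self, trained_run, grid):
        s = trained_run.cohort[0]
        res = run_calibration(
            trained_run.agent_low,
            trained_run.agent_high,
            VirtualResponder(s),
            trained_run.trials,
            grid=grid,
        )
        for p, _ in res.trace:
            assert grid.contains(p.pa, p.pw)


class TestBFA:
    def _oracle(self, s, start, grid, step_cap=100):
        """Independent replay of the monotone PW-major ramp."""

        def sweep(p0):
            pa, pw = p0.pa, p0.pw
            yield pa, pw
            while True:
                if pw + grid.pw_step <= grid.pw_values[-1]:
                    pw += grid.pw_step
                elif pa < grid.pa_values[-1]:
                    pa, pw = pa + grid.pa_step, p0.pw
                else:
                    return
                yield pa, pw

        def until(p0, target, n_before):
            for n, (pa, pw) in enumerate(sweep(p0), start=1):
                if n_before + n > step_cap:
                    return None, n - 1
                rep = respond(s, StimParams(pa=pa, pw=pw))
                if rep.intensity == target and rep.location == Location.SOMATOTOPIC:
                    return StimParams(pa=pa, pw=pw), n
                if rep.intensity == Intensity.TOO_HIGH:
                    return None, n
            return None, n

        low, n_low = until(start, Intensity.LOW, 0)
        high, n_high = (None, 0)
        if low is not None:
            high, n_high = until(low, Intensity.HIGH, n_low)
        return low, high, n_low + n_high

    def test_matches_exhaustive_ramp_oracle(self, grid):
        s = make_subject()
        ds = dataset([("S1", "M", "peroneal", 3, 300, "LOW", "SOM")])
        res = bfa_calibrate(VirtualResponder(s), ds, grid=grid)
        low, high, n = self._oracle(s, StimParams(pa=3.0, pw=300.0), grid)
        assert res.converged_low and res.low_params == low
        assert res.converged_high and res.high_params == high
        assert res.n_stims == n
        # the found pairs really evoke their levels
        assert respond(s, low).intensity == Intensity.LOW
        assert respond(s, high).intensity == Intensity.HIGH

    def test_charge_nondecreasing_within_each_amplitude(self, grid):
        s = make_subject()
        ds = dataset([("S1", "M", "peroneal", 3, 300, "LOW", "SOM")])
        res = bfa_calibrate(VirtualResponder(s), ds, grid=grid)
        for phase in (res.trace[: res.n_stims],):
            by_pa: dict = {}
            for p, _ in phase:
                by_pa.setdefault(p.pa, []).append(charge(p))
        # within one amplitude level, PW only ramps upward
        segment: list = []
        last_pa = None
        for p, _ in res.trace:
            if p.pa != last_pa:
                segment, last_pa = [], p.pa
            segment.append(charge(p))
            assert all(a <= b for a, b in zip(segment, segment[1:]))

    def test_fails_when_target_band_lies_below_start(self, grid):
        # start charge far above the subject's too-strong boundary
        s = make_subject()
        ds = dataset([("S1", "M", "peroneal", 10, 600, "LOW", "SOM")])
        res = bfa_calibrate(VirtualResponder(s), ds, grid=grid)
        assert not res.converged_low
        assert not res.converged_high
        assert res.trace[0][1].intensity == Intensity.TOO_HIGH

    def test_no_low_rows_rejected(self, grid):
        ds = dataset([("S1", "M", "peroneal", 1, 70, "NP", "NSOM")])
        with pytest.raises(ValueError):
            bfa_calibrate(VirtualResponder(make_subject()), ds, grid=grid)


class TestScriptedNaive:
    def _oracle(self, s, grid, start_pw=300.0, step_cap=100):
        """Independent replay of the scripted protocol."""
        trace = []
        p = StimParams(pa=grid.pa_values[0], pw=start_pw)
        som = None
        while len(trace) < step_cap:
            rep = respond(s, p)
            trace.append((p, rep))
            if rep.intensity != Intensity.NOT_PERCEIVED and rep.location == Location.SOMATOTOPIC:
                som = p
                break
            if rep.intensity == Intensity.TOO_HIGH or p.pa >= grid.pa_values[-1]:
                break
            p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
        low = high = None
        if som is not None:
            if trace[-1][1].intensity == Intensity.LOW:
                low = trace[-1][0]
            while low is None and p.pw < grid.pw_values[-1] and len(trace) < step_cap:
                p = StimParams(pa=p.pa, pw=p.pw + grid.pw_step)
                rep = respond(s, p)
                trace.append((p, rep))
                if rep.intensity == Intensity.LOW and rep.location == Location.SOMATOTOPIC:
                    low = p
                if rep.intensity >= Intensity.TOO_HIGH:
                    break
            while (
                low is not None
                and high is None
                and (p.pw < grid.pw_values[-1] or p.pa < grid.pa_values[-1])
                and len(trace) < step_cap
            ):
                if p.pw < grid.pw_values[-1]:
                    p = StimParams(pa=p.pa, pw=p.pw + grid.pw_step)
                else:
                    p = StimParams(pa=p.pa + grid.pa_step, pw=p.pw)
                rep = respond(s, p)
                trace.append((p, rep))
                if rep.intensity == Intensity.HIGH and rep.location == Location.SOMATOTOPIC:
                    high = p
                if rep.intensity >= Intensity.TOO_HIGH:
                    break
        return low, high, len(trace)

    def test_matches_protocol_oracle(self, grid):
        s = make_subject()
        res = scripted_naive_calibrate(VirtualResponder(s), grid=grid)
        low, high, n = self._oracle(s, grid)
        assert res.low_params == low
        assert res.high_params == high
        assert res.n_stims == n
        assert res.converged_low == (low is not None)
        assert res.converged_high == (high is not None)

    def test_deterministic(self, grid):
        s = make_subject()
        a = scripted_naive_calibrate(VirtualResponder(s), grid=grid)
        b = scripted_naive_calibrate(VirtualResponder(s), grid=grid)
        assert a.trace == b.trace and a.n_stims == b.n_stims

    def test_all_stimuli_on_grid(self, grid):
        s = make_subject()
        res = scripted_naive_calibrate(VirtualResponder(s), grid=grid)
        for p, _ in res.trace:
            assert grid.contains(p.pa, p.pw)
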