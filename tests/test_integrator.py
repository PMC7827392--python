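import numpy as np
import pytest
from scipy.integrate import solve_ivp

import dormancy
from dormancy.dynamics import SystemState, rhs_quiescent
from dormancy.errors import ClassificationError, ConfigError, IntegrationError
from dormancy.integrator import (
    Fate,
    InjectionEvent,
    InjectionSchedule,
    Trajectory,
    classify_fate,
    escape_onset_day,
    integrate,
)
from dormancy.parameters import InitialState, default_initial_state


def make_trajectory(t, Cp, Cq, N=None, T=None, threshold=1e8, horizon=None):
    """Hand-built trajectory for classification tests."""
    t = np.asarray(t, dtype=float)
    states = np.column_stack(
        [
            np.asarray(Cp, dtype=float),
            np.asarray(Cq, dtype=float),
            np.full_like(t, 1e5) if N is None else np.asarray(N, dtype=float),
            np.full_like(t, 1e5) if T is None else np.asarray(T, dtype=float),
        ]
    )
    total = states[:, 0] + states[:, 1]
    max_total = float(total.max())
    crossing = np.nonzero(total >= threshold)[0]
    return Trajectory(
        t=t,
        states=states,
        variant="heterogeneous",
        step=float(t[1] - t[0]),
        escape_threshold=threshold,
        max_total=max_total,
        escape_day=float(t[crossing[0]]) if crossing.size else None,
        horizon=float(t[-1]) if horizon is None else horizon,
    )


class TestIntegration:
    def test_injection_adds_exactly_the_stated_count(self, params):
        """State immediately after an injection equals the state
        immediately before plus the injected cells."""
        init = default_initial_state("quiescent")
        plain = integrate("heterogeneous", init, params, horizon=7.0)
        sched = InjectionSchedule(
            [InjectionEvent(day=7.0, compartment="quiescent", count=2e6)]
        )
        jumped = integrate(
            "heterogeneous", init, params, horizon=14.0, schedule=sched
        )
        i = int(round(7.0 / jumped.step))
        before = plain.states[-1]
        after = jumped.states[i]
        np.testing.assert_array_equal(
            after, before + np.array([0.0, 2e6, 0.0, 0.0])
        )
        assert any(e["type"] == "injection" for e in jumped.events)

    def test_sub_unity_tumor_population_is_zeroed_and_logged(self, params):
        init = InitialState(Cp0=0.0, Cq0=2.0, N0=2.5e5, T0=5e6)
        traj = integrate("quiescent", init, params, horizon=30.0)
        assert traj.Cq[-1] == 0.0
        extinctions = [e for e in traj.events if e["type"] == "extinction"]
        assert extinctions and extinctions[0]["compartment"] == "quiescent"
        # once zeroed without re-seeding it stays at zero
        zero_from = np.argmax(traj.Cq == 0.0)
        assert np.all(traj.Cq[zero_from:] == 0.0)

    def test_states_never_negative(self, dormancy_trajectory):
        assert np.all(dormancy_trajectory.states >= 0.0)

    def test_no_tumor_limit(self, params):
        """Without tumor cells, NK converge monotonically to s/f and CTLs
        decay below one cell in finite time."""
        init = InitialState(Cp0=0.0, Cq0=0.0, N0=1e3, T0=5.2e5)
        traj = integrate(
            "heterogeneous", init, params, horizon=800.0, record_every=10
        )
        assert np.all(np.diff(traj.N) >= 0.0)
        assert traj.N[-1] == pytest.approx(params.s / params.f, rel=1e-6)
        assert traj.T[-1] < 1.0

    def test_step_halving_converges_on_dormancy_scenario(self, params):
        init = default_initial_state("quiescent")
        coarse = integrate(
            "quiescent", init, params, horizon=365.0, step=0.01, record_every=100
        )
        fine = integrate(
            "quiescent", init, params, horizon=365.0, step=0.005, record_every=200
        )
        np.testing.assert_array_equal(coarse.t, fine.t)
        scale = np.abs(fine.states) + 1.0
        assert np.max(np.abs(coarse.states - fine.states) / scale) < 1e-4

    def test_agrees_with_adaptive_reference_integrator(self, params):
        """Fixed-step RK4 matches an independent high-accuracy adaptive
        solution of the dormancy scenario within 0.1%."""
        init = default_initial_state("quiescent")
        traj = integrate(
            "quiescent", init, params, horizon=100.0, record_every=100
        )

        def rhs(t, y):
            return rhs_quiescent(
                SystemState(t=t, Cp=0.0, Cq=y[1], N=y[2], T=y[3]), params
            )

        ref = solve_ivp(
            rhs,
            (0.0, 100.0),
            [0.0, init.Cq0, init.N0, init.T0],
            method="RK45",
            rtol=1e-10,
            atol=1e-6,
            t_eval=traj.t,
        )
        assert ref.success
        rel = np.abs(traj.states[:, 1:] - ref.y[1:].T) / (np.abs(ref.y[1:].T) + 1.0)
        assert np.max(rel) < 1e-3

    def test_overflowing_run_reports_last_valid_time(self, params):
        exploding = params.replace(b2=0.0, eta2=0.0, j=30.0, m=0.0)
        init = default_initial_state("quiescent")
        with pytest.raises(IntegrationError) as excinfo:
            integrate("quiescent", init, exploding, horizon=365.0)
        assert 0.0 < excinfo.value.last_valid_time < 365.0

    def test_step_and_event_validation(self, params):
        init = default_initial_state("quiescent")
        with pytest.raises(ConfigError):
            integrate("quiescent", init, params, horizon=10.0, step=0.5)
        with pytest.raises(ConfigError):
            integrate(
                "quiescent",
                init,
                params,
                horizon=10.0,
                schedule=InjectionSchedule(
                    [InjectionEvent(day=20.0, compartment="quiescent", count=1.0)]
                ),
            )

    def test_schedule_validation(self):
        with pytest.raises(ConfigError):
            InjectionEvent(day=1.0, compartment="quiescent", count=0.0)
        with pytest.raises(ConfigError):
            InjectionEvent(day=1.0, compartment="stromal", count=10.0)
        with pytest.raises(ConfigError):
            InjectionSchedule(
                [
                    InjectionEvent(day=5.0, compartment="quiescent", count=1.0),
                    InjectionEvent(day=1.0, compartment="quiescent", count=1.0),
                ]
            )

    def test_trajectory_round_trips_to_csv(self, params, tmp_path):
        import pandas as pd

        traj = integrate(
            "quiescent",
            default_initial_state("quiescent"),
            params,
            horizon=5.0,
            record_every=10,
        )
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["t", "Cp", "Cq", "N", "T"]
        np.testing.assert_allclose(frame["Cq"].to_numpy(), traj.Cq)
        traj.events_to_json(tmp_path / "events.json")


class TestFateClassification:
    def test_escaped_proliferative_with_eliminated_quiescent(self):
        t = np.arange(0.0, 120.0, 1.0)
        Cq = np.where(t < 40.0, 1e4, 0.0)
        Cp = np.where(t < 90.0, 1e6, 2e8)
        fate = classify_fate(make_trajectory(t, Cp, Cq))
        assert fate.quiescent is Fate.ELIMINATED
        assert fate.proliferative is Fate.ESCAPED
        assert fate.overall is Fate.ESCAPED

    def test_full_elimination(self):
        t = np.arange(0.0, 365.0, 1.0)
        Cp = np.where(t < 60.0, 5e2, 0.0)
        Cq = np.where(t < 30.0, 1e3, 0.0)
        fate = classify_fate(make_trajectory(t, Cp, Cq))
        assert fate.overall is Fate.ELIMINATED

    def test_persistent_quiescent_is_dormant(self):
        t = np.arange(0.0, 366.0, 1.0)
        Cq = np.full_like(t, 2e3)
        Cp = np.zeros_like(t)
        fate = classify_fate(make_trajectory(t, Cp, Cq))
        assert fate.quiescent is Fate.DORMANT
        assert fate.proliferative is Fate.ELIMINATED
        assert fate.overall is Fate.DORMANT

    def test_truncated_trajectory_without_escape_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        traj = make_trajectory(t, np.zeros_like(t), np.full_like(t, 2e3),
                               horizon=365.0)
        with pytest.raises(ClassificationError):
            classify_fate(traj)


class TestEscapeOnset:
    def test_monotone_growth_onsets_at_start(self):
        t = np.arange(0.0, 100.0, 1.0)
        Cp = np.logspace(4, 9, t.size)
        traj = make_trajectory(t, Cp, np.zeros_like(t))
        assert escape_onset_day(traj, definition="regrowth_minimum") == 0.0
        assert escape_onset_day(traj) == traj.escape_day

    def test_dormant_trajectory_has_no_onset(self, dormancy_trajectory):
        assert escape_onset_day(dormancy_trajectory) is None

    def test_onset_follows_last_regrowth_minimum(self):
        t = np.arange(0.0, 200.0, 1.0)
        # dip to a minimum at day 50, then uninterrupted rise past threshold
        Cp = 1e6 * np.exp(-0.1 * np.minimum(t, 50.0)) * np.exp(
            0.2 * np.maximum(t - 50.0, 0.0)
        )
        traj = make_trajectory(t, Cp, np.zeros_like(t))
        assert escape_onset_day(traj, definition="regrowth_minimum") == 50.0
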