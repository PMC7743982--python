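"""Hybrid simulator: event handling, attractor convergence, oscillations."""

import numpy as np
import pytest

import pldesys as pl
from conftest import THETA


@pytest.fixture(scope="module")
def p53m():
    return pl.builtin_p53_model()


@pytest.fixture(scope="module")
def unstressed_run(p53m):
    return pl.simulate(p53m, p53m.initial_state(), 0.0, 1e7)


@pytest.fixture(scope="module")
def ssp1_cycle_run(p53m, request):
    """Limit-cycle trajectory seeded next to the low-PTEN singular point."""
    regions = pl.enumerate_delta_regions(p53m)
    region = next(
        r for r in regions
        if set(r.pinned) == {("P", "theta_P"), ("N", "theta_N2")}
        and r.side_of("theta_T") == "below"
    )
    ssp = pl.find_ssp(p53m, region, 3.0)
    x0 = {k: v * 1.01 for k, v in ssp.location.items()}
    return pl.simulate(p53m, x0, 3.0, 1.5e6)


class TestSimulate:
    def test_unstressed_cell_settles_in_low_p53_state(self, p53m, unstressed_run):
        """R=0: the module relaxes to the {020} resting state (low p53 and
        PTEN, high nuclear MDM2)."""
        traj = unstressed_run
        assert str(traj.domains[-1]) == "{020}"
        target = p53m.state_array(
            pl.focal_point(p53m, p53m.domain((0, 2, 0)), 0.0).coordinates
        )
        assert np.max(np.abs(traj.states[-1] - target) / target) < 1e-3

    def test_times_strictly_increasing_and_finite(self, unstressed_run):
        traj = unstressed_run
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(np.isfinite(traj.states))
        assert len(traj.domains) == traj.times.size

    def test_positivity_from_nonnegative_start(self, p53m):
        for R in (0.0, 1.0, 5.0):
            traj = pl.simulate(p53m, p53m.initial_state(), R, 5e5)
            assert np.all(traj.states >= 0)

    def test_event_consistency(self, p53m, ssp1_cycle_run):
        """At each recorded event the crossed variable sits on its threshold."""
        traj = ssp1_cycle_run
        assert len(traj.events) > 50
        by_time = {round(t, 9): i for i, t in enumerate(traj.times)}
        for ev in traj.events[:200]:
            thr = p53m.threshold_by_name(ev.threshold)
            i = by_time.get(round(ev.time, 9))
            if i is None:
                continue
            value = traj.states[i][p53m.variable_index(thr.variable)]
            assert abs(value - thr.value) <= 1e-6 * thr.value

    def test_domain_labels_consistent_with_states(self, p53m, ssp1_cycle_run):
        traj = ssp1_cycle_run
        for ti, xi, dom in list(zip(traj.times, traj.states, traj.domains))[::37]:
            state = p53m.state_dict(xi)
            on_thr = any(
                abs(state[t.variable] - t.value) <= 1e-9 * t.value
                for t in p53m.thresholds
            )
            if not on_thr:
                assert pl.evaluate_switching_state(p53m, state) == dom

    def test_piecewise_segments_match_closed_form(self, p53m):
        """Between consecutive events the trajectory is the frozen-domain
        closed-form solution."""
        traj = pl.simulate(p53m, p53m.initial_state(), 1.0, 3e5)
        ev_times = [0.0] + [e.time for e in traj.events] + [traj.times[-1]]
        checked = 0
        for a, b in zip(ev_times, ev_times[1:]):
            inside = (traj.times >= a) & (traj.times <= b)
            idx = np.nonzero(inside)[0]
            if idx.size < 3:
                continue
            i0 = idx[0]
            dom = traj.domains[idx[1]]  # label after any event relabelling
            flow = pl.domain_flow(p53m, dom, 1.0)
            rel_ts = traj.times[idx[1:-1]] - traj.times[i0]
            want = flow(traj.states[i0], rel_ts)
            got = traj.states[idx[1:-1]]
            ref = np.maximum(np.abs(want), 1.0)
            assert np.max(np.abs(got - want) / ref) < 1e-8
            checked += 1
        assert checked >= 3

    def test_oscillation_straddles_p_and_n2_below_t(self, p53m, ssp1_cycle_run):
        """On the oscillatory branch p53 crosses its threshold, nuclear MDM2
        crosses its upper threshold, and PTEN stays below its own."""
        summ = pl.detect_oscillation(ssp1_cycle_run, model=p53m)
        assert summ.classification == "limit-cycle"
        assert "theta_P" in summ.anchor_thresholds
        assert "theta_N2" in summ.anchor_thresholds
        assert summ.extrema["T"][1] < THETA["T"]

    def test_upper_cycle_keeps_pten_high(self, p53m):
        """Near the high-PTEN singular point at R=1 the cycle stays above
        theta_T."""
        regions = pl.enumerate_delta_regions(p53m)
        region = next(
            r for r in regions
            if set(r.pinned) == {("P", "theta_P"), ("N", "theta_N2")}
            and r.side_of("theta_T") == "above"
        )
        ssp = pl.find_ssp(p53m, region, 1.0)
        x0 = {k: v * 1.01 for k, v in ssp.location.items()}
        traj = pl.simulate(p53m, x0, 1.0, 1.5e6)
        summ = pl.detect_oscillation(traj, model=p53m)
        assert summ.classification == "limit-cycle"
        assert summ.extrema["T"][0] > THETA["T"]

    def test_period_shortens_with_stress(self, p53m):
        periods = []
        regions = pl.enumerate_delta_regions(p53m)
        region = next(
            r for r in regions
            if set(r.pinned) == {("P", "theta_P"), ("N", "theta_N2")}
            and r.side_of("theta_T") == "below"
        )
        for R in (2.0, 3.0, 4.0):
            ssp = pl.find_ssp(p53m, region, R)
            x0 = {k: v * 1.01 for k, v in ssp.location.items()}
            traj = pl.simulate(p53m, x0, R, 1.5e6)
            summ = pl.detect_oscillation(traj, model=p53m)
            assert summ.classification == "limit-cycle"
            periods.append(summ.period)
        assert periods[0] > periods[1] > periods[2]

    def test_event_tolerance_refinement_stable_extrema(self, p53m):
        """Halving the event tolerance barely moves post-transient extrema."""
        regions = pl.enumerate_delta_regions(p53m)
        region = next(
            r for r in regions
            if set(r.pinned) == {("P", "theta_P"), ("N", "theta_N2")}
            and r.side_of("theta_T") == "below"
        )
        ssp = pl.find_ssp(p53m, region, 3.0)
        x0 = {k: v * 1.01 for k, v in ssp.location.items()}
        ex = []
        for tol in (1e-6, 5e-7):
            traj = pl.simulate(p53m, x0, 3.0, 8e5, event_tol=tol)
            s = pl.detect_oscillation(traj, model=p53m)
            ex.append(s.extrema["P"])
        assert ex[0][0] == pytest.approx(ex[1][0], rel=1e-4)
        assert ex[0][1] == pytest.approx(ex[1][1], rel=1e-4)

    def test_rejects_nonpositive_horizon(self, p53m):
        with pytest.raises(ValueError):
            pl.simulate(p53m, p53m.initial_state(), 0.0, 0.0)


class TestSimulateNonlinear:
    def test_unstressed_steady_state_low_p53(self):
        nl = pl.builtin_nonlinear_model("rescaled")
        m = pl.builtin_p53_model()
        traj = pl.simulate_nonlinear(nl, m.initial_state(), 0.0, 2e6)
        final = traj.states[-1]
        assert final[0] < THETA["P"]  # p53 stays low without stress
        assert np.max(np.abs(nl.rhs(final, 0.0))) < 1e-4

    def test_root_found_steady_state_residual(self):
        from scipy.optimize import root

        nl = pl.builtin_nonlinear_model("rescaled")
        sol = root(lambda y: nl.rhs(np.abs(y), 0.0),
                   np.array([2.7e4, 1.1e4, 1.5e4, 1.7e5]))
        assert sol.success
        assert np.max(np.abs(nl.rhs(np.abs(sol.x), 0.0))) < 1e-6

    def test_convergence_in_tolerance(self):
        nl = pl.builtin_nonlinear_model("rescaled")
        m = pl.builtin_p53_model()
        a = pl.simulate_nonlinear(nl, m.initial_state(), 1.0, 5e5,
                                  rtol=1e-9, atol=1e-6)
        b = pl.simulate_nonlinear(nl, m.initial_state(), 1.0, 5e5,
                                  rtol=5e-10, atol=5e-7)
        ref = np.maximum(np.abs(b.states[-1]), 1.0)
        assert np.max(np.abs(a.states[-1] - b.states[-1]) / ref) < 1e-4

    def test_printed_constants_leave_saturation_degenerate(self):
        """With the verbatim half-saturation constants the Hill factor is
        pinned at 1 for physiological amounts (the documented inconsistency)."""
        nl = pl.builtin_nonlinear_model("printed")
        P = 1e4
        assert P**4 / (P**4 + nl.k2) == pytest.approx(1.0)


class TestDetectOscillation:
    def test_constant_trajectory_is_fixed_point(self, p53m):
        times = np.arange(0.0, 1e6, 600.0)
        states = np.tile([1e4, 2e4, 3e4, 4e4], (times.size, 1))
        traj = pl.Trajectory(times, states, p53m.variable_names, None, [])
        summ = pl.detect_oscillation(traj, model=p53m)
        assert summ.classification == "fixed-point"
        assert summ.extrema["P"] == (1e4, 1e4)

    def test_recovers_period_of_synthetic_sawtooth(self, p53m):
        period = 40_000.0
        times = np.arange(0.0, 1.2e6, 200.0)
        phase = (times / period) % 1.0
        p = THETA["P"] * (0.8 + 0.4 * np.where(phase < 0.5, phase, 1 - phase))
        states = np.column_stack([p, p, p, np.full_like(p, 1e3)])
        traj = pl.Trajectory(times, states, p53m.variable_names, None, [])
        summ = pl.detect_oscillation(traj, model=p53m,
                                     reference=("P", THETA["P"]))
        assert summ.classification == "limit-cycle"
        assert summ.period == pytest.approx(period, rel=0.01)

    def test_short_window_is_undecided(self, p53m):
        period = 40_000.0
        times = np.arange(0.0, 2.2 * period, 200.0)  # < 5 periods after skip
        p = THETA["P"] * (1 + 0.2 * np.sin(2 * np.pi * times / period))
        states = np.column_stack([p, p, p, p])
        traj = pl.Trajectory(times, states, p53m.variable_names, None, [])
        summ = pl.detect_oscillation(traj, model=p53m,
                                     reference=("P", THETA["P"]))
        assert summ.classification == "undecided"
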