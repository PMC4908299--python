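import math

import numpy as np
import pytest

from qsn.common import SpikeTrain, StimulusProtocol, Trajectory
from qsn.dynamics import (classify_excitability, detect_limit_cycle,
                          dominant_frequency, fi_curve, find_equilibria,
                          graded_response_test, graded_spread, jacobian,
                          segment_bursts, sweep_bifurcation, tune_mode)
from qsn.dynamics.bursts import classify_count_sequence


class LinearToy:
    """dv/dt = -v - w + I, dw/dt = v - w: single globally stable focus."""

    ndim = 2
    slow_name = None
    v_range = (-2.0, 2.0)
    dt = 1e-3
    spike_threshold = 100.0  # never spikes
    current_scale = 1.0

    def rhs(self, v, w, I=0.0):
        return (-v - w + I, v - w)

    def jac(self, v, w, I=0.0):
        return np.array([[-1.0, -1.0], [1.0, -1.0]])

    def vnull(self, v, I=0.0):
        return I - np.asarray(v, dtype=float)

    def wnull(self, v):
        return np.asarray(v, dtype=float)

    def simulate(self, v0, w0, stim, T, dt=None):
        dt = dt or self.dt
        n = int(round(T / dt))
        out = np.empty((n + 1, 2))
        v, w = v0, w0
        out[0] = v, w
        for i in range(n):
            I = stim.amplitude(i * dt)
            k1 = self.rhs(v, w, I)
            k2 = self.rhs(v + dt / 2 * k1[0], w + dt / 2 * k1[1], I)
            k3 = self.rhs(v + dt / 2 * k2[0], w + dt / 2 * k2[1], I)
            k4 = self.rhs(v + dt * k3[0], w + dt * k3[1], I)
            v += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            w += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            out[i + 1] = v, w
        t = np.arange(n + 1) * dt
        return Trajectory(t, out, ("v", "w"), dt)


class TestEquilibria:
    def test_linear_toy_closed_form(self):
        eqs = find_equilibria(LinearToy(), I_stim=0.8)
        assert len(eqs) == 1
        assert math.isclose(eqs[0].v, 0.4, abs_tol=1e-12)
        assert eqs[0].label == "stable_focus"

    def test_class1_preset_has_rest_saddle_unstable(self, class1):
        eqs = find_equilibria(class1.planar())
        assert [e.label.split("_")[0] if not e.is_saddle else "saddle"
                for e in eqs] == ["stable", "saddle", "unstable"]
        # frozen locations from first characterization
        assert math.isclose(eqs[0].v, class1.analysis["rest_v"],
                            abs_tol=5e-3)
        assert math.isclose(eqs[2].v, class1.analysis["unstable_v"],
                            abs_tol=5e-3)

    def test_class2_preset_has_single_stable_focus(self, class2):
        eqs = find_equilibria(class2.planar())
        assert len(eqs) == 1
        assert eqs[0].label == "stable_focus"
        assert math.isclose(eqs[0].v, class2.analysis["rest_v"],
                            abs_tol=5e-3)

    def test_labels_consistent_with_eigenvalues(self, class1, class2):
        for pre in (class1, class2):
            for e in find_equilibria(pre.planar()):
                re = np.real(e.eigenvalues)
                if e.is_saddle:
                    assert re.min() < 0 < re.max()
                elif e.stable:
                    assert re.max() < 0
                else:
                    assert re.max() > 0


class TestJacobian:
    def test_linear_toy_exact(self):
        J = jacobian(LinearToy(), (0.3, -0.2))
        assert np.array_equal(J, [[-1, -1], [1, -1]])

    def test_dssn_matches_finite_difference(self, class1, rng):
        m = class1.planar()
        for _ in range(3):
            v, n = rng.uniform(-0.8, 0.8, 2)
            J = m.jac(v, n)
            h = 1e-7
            for col, f in enumerate([lambda d: m.rhs(v + d, n),
                                     lambda d: m.rhs(v, n + d)]):
                fd = (np.array(f(h)) - np.array(f(-h))) / (2 * h)
                assert np.allclose(J[:, col], fd, rtol=1e-6,
                                   atol=1e-6 * np.abs(J).max())


class TestSweep:
    def test_linear_toy_has_no_events(self):
        bd = sweep_bifurcation(LinearToy(), "I_stim", prange=(-0.5, 0.5),
                               resolution=50, T=0.2)
        assert bd.events == []
        assert all(len(s.equilibria) == 1 for s in bd.samples)

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            sweep_bifurcation(LinearToy(), "I_stim", prange=(0, 1),
                              resolution=10)

    def test_class1_snic_under_stimulus_sweep(self, class1):
        m = class1.planar()
        Ic = class1.analysis["I_snic"]
        values = np.concatenate([Ic - np.array([0.02, 0.01, 0.005]),
                                 Ic + np.geomspace(1e-4, 0.1, 40)])
        bd = sweep_bifurcation(m, "I_stim", values=values, T=8.0)
        kinds = {e.type for e in bd.events}
        assert "snic" in kinds or "saddle_node" in kinds
        snics = bd.events_of("snic")
        assert snics and any(e.info["period_ratio"] > 10 for e in snics)

    def test_class2_subcritical_hopf_with_fold_and_bistability(self, class2):
        m = class2.planar()
        lo, hi = class2.protocol["sweep_range"]
        bd = sweep_bifurcation(m, "I_stim", prange=(lo, hi),
                               resolution=51, T=3.0)
        hopf = bd.events_of("hopf")
        assert hopf and hopf[0].info["subcritical"]
        assert bd.events_of("fold_of_cycles")
        bistable = [s.value for s in bd.samples
                    if s.cycle is not None
                    and any(e.stable for e in s.equilibria)]
        assert bistable, "no coexistence of rest and spiking found"

    def test_square_wave_fast_subsystem_bistable_window(self, square_wave):
        fast = square_wave.planar()
        q_lo, q_hi = square_wave.analysis["q_window"]
        bd = sweep_bifurcation(fast, "q",
                               prange=(q_lo - 0.05e-9, q_hi + 0.05e-9),
                               resolution=51, T=0.1)
        bistable = [s.value for s in bd.samples
                    if s.cycle is not None
                    and any(e.stable for e in s.equilibria)]
        assert bistable, "no bistable window in the slow-current sweep"
        assert bd.events_of("saddle_loop")


class TestPeriodScaling:
    def test_snic_inverse_square_root_law(self, class1):
        m = class1.planar()
        # locate the saddle-node by bisection on the equilibrium count
        lo, hi = 0.15, 0.25
        for _ in range(45):
            mid = 0.5 * (lo + hi)
            if len(find_equilibria(m, mid)) == 3:
                lo = mid
            else:
                hi = mid
        Ic = hi
        dIs = np.array([1e-5, 3e-5, 1e-4, 3e-4, 1e-3])
        periods = []
        for dI in dIs:
            c = detect_limit_cycle(m, Ic + dI, T=30.0, dt=5e-5)
            assert c is not None
            periods.append(c.period)
        slope = np.polyfit(np.log(dIs), np.log(periods), 1)[0]
        assert -0.6 < slope < -0.4

    def test_saddle_loop_logarithmic_law(self, square_wave):
        fast = square_wave.planar()
        q_lo, _ = square_wave.analysis["q_window"]
        # refine the homoclinic point by warm-started continuation
        warm = None
        q_death = None
        qs = np.arange(q_lo - 2e-11, q_lo + 3e-11, 1.25e-12)
        rows = []
        for q in qs:
            c = detect_limit_cycle(fast.with_slow(q), T=0.12, dt=2e-6,
                                   start=warm)
            if c is None:
                q_death = q
                break
            warm = c.end_state
            rows.append((q, c.period))
        assert q_death is not None and len(rows) >= 6
        qv = np.array([r[0] for r in rows[-8:]])
        pv = np.array([r[1] for r in rows[-8:]])
        x = np.log(q_death - qv)
        A = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(A, pv, rcond=None)
        ss_tot = np.sum((pv - pv.mean()) ** 2)
        r2 = 1 - (res[0] / ss_tot if res.size else 0.0)
        assert coef[0] < 0  # period grows as the homoclinic point nears
        assert r2 > 0.95


class TestFICurve:
    def test_class1_classification(self, class1):
        proto = class1.protocol
        Ic = class1.analysis["I_snic"]
        grid = np.concatenate([proto["fi_grid_coarse"],
                               Ic + np.array(proto["fi_onset_offsets"]),
                               proto["fi_grid_upper"]])
        fi = fi_curve(class1.planar(), grid, T=proto["fi_T"])
        label, rep = classify_excitability(fi)
        assert label == "class1"
        assert rep["onset_ratio"] < 0.1

    def test_class2_classification_with_hysteresis(self, class2):
        proto = class2.protocol
        m = class2.planar()
        up = fi_curve(m, proto["fi_grid"], T=proto["fi_T"])
        down = fi_curve(m, proto["fi_grid"], T=proto["fi_T"],
                        direction="down")
        label, rep = classify_excitability(up, down)
        assert label == "class2"
        assert rep["min_nonzero_rate"] > 10.0
        assert rep["hysteresis"] > 0  # onset above offset: bistable band

    def test_silent_model_raises(self):
        with pytest.raises(RuntimeError, match="below threshold"):
            fi = fi_curve(LinearToy(), [0.0, 0.1, 0.2], T=0.2)
            classify_excitability(fi)

    def test_isi_rate_agrees_with_fft(self, class2):
        m = class2.planar()
        I = 0.3
        fi = fi_curve(m, [I], T=4.0)
        start = find_equilibria(m, 0.0)[0]
        traj = m.simulate(start.v + 0.8, start.w,
                          StimulusProtocol.constant(I), 4.0)
        f_fft = dominant_frequency(traj, t0=2.0)
        assert abs(f_fft - fi.f[0]) / fi.f[0] < 0.02


class TestGradedResponse:
    def test_zero_amplitude_returns_resting_peak(self, class2):
        m = class2.planar()
        res = graded_response_test(m, [0.0], width=0.005)
        rest = find_equilibria(m)[0]
        assert abs(res[0][1] - rest.v) < 0.02

    def test_repeat_determinism(self, class2):
        m = class2.planar()
        r1 = graded_response_test(m, [2.0], width=0.005)
        r2 = graded_response_test(m, [2.0], width=0.005)
        assert r1 == r2

    def test_requires_sorted_amplitudes(self, class2):
        with pytest.raises(ValueError):
            graded_response_test(class2.planar(), [2.0, 1.0], width=0.005)

    def test_class2_spread_exceeds_twice_class1(self, class1, class2):
        amps = class2.protocol["graded_amps"]
        width = class2.protocol["graded_width"]
        s1 = graded_spread(graded_response_test(class1.planar(), amps,
                                                width=width), 0.0)
        s2 = graded_spread(graded_response_test(class2.planar(), amps,
                                                width=width), 0.0)
        assert s2 > 2 * s1


class TestBurstSegmentation:
    def test_even_spacing_is_one_burst(self):
        seq = segment_bursts(SpikeTrain(np.arange(0, 1, 0.01)))
        assert len(seq) == 1
        assert seq.bursts[0].count == 100

    def test_documented_isi_pattern(self):
        isis = np.array([10, 10, 10, 200, 10, 10]) * 1e-3
        t = np.concatenate([[0.0], np.cumsum(isis)])
        seq = segment_bursts(SpikeTrain(t))
        assert seq.counts == [4, 3]
        assert len(seq.gaps) == 1

    def test_empty_and_single(self):
        assert len(segment_bursts(SpikeTrain(np.array([])))) == 0
        seq = segment_bursts(SpikeTrain(np.array([0.5])))
        assert seq.counts == [1]

    def test_every_spike_in_exactly_one_burst(self, rng):
        t = np.sort(rng.uniform(0, 10, 200))
        seq = segment_bursts(SpikeTrain(t))
        assert sum(seq.counts) == t.size


class TestCountSequenceLabels:
    def test_periodic_three_fixture(self):
        counts = [5, 3, 2] * 10
        assert classify_count_sequence(counts) == "periodic-3"

    def test_constant_single_spike(self):
        assert classify_count_sequence([1] * 20) == "periodic-1"

    def test_single_burst_is_tonic(self):
        assert classify_count_sequence([400]) == "tonic"

    def test_random_long_sequence_is_aperiodic(self, rng):
        counts = list(rng.integers(10, 30, 60))
        assert classify_count_sequence(counts) == "aperiodic"


class TestTuner:
    def test_class1_target_self_verifies(self, class1):
        from qsn.tuning import default_search
        search = default_search(class1, budget=40)
        result = tune_mode("dssn", "class1", search, seed=3)
        assert result.success
        eqs = find_equilibria(search["builder"](result.params))
        assert len(eqs) == 3

    def test_infeasible_bounds_fail_with_report(self, analog_class1):
        from qsn.analog import AnalogFastSubsystem
        search = {
            "base": analog_class1.params,
            "builder": AnalogFastSubsystem,
            "bounds": {"M_m": (0.0, 0.0, "lin")},  # no rising curve at all
            "budget": 20,
        }
        result = tune_mode("analog", "class1", search, seed=1)
        assert not result.success
        assert result.penalty > 0
        assert result.report["evaluations"] >= 1

    def test_unknown_target_rejected(self, class1):
        from qsn.tuning import default_search
        with pytest.raises(ValueError):
            tune_mode("dssn", "bistable-resonator",
                      default_search(class1, budget=5), seed=0)
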