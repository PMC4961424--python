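"""Single-cell model: equilibria, currents, pacing, APD measurement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lafib import _crn, cell
from lafib.cell import PRESETS, RemodelingParams

BASE = PRESETS["baseline"]
AF = PRESETS["af_remodeled"]


class TestRestingState:
    def test_baseline_rest_matches_published_model(self, baseline_resting):
        # the 1998 human atrial model rests near -81.2 mV
        assert -83.0 < baseline_resting[_crn.IV] < -79.0

    def test_af_preset_has_stable_equilibrium(self, af_resting):
        y = af_resting.copy()
        v0 = y[_crn.IV]
        s = AF.as_tuple()
        v_out = np.empty(5001)
        _crn.integrate_cell(y, 0.0, 5000.0, np.empty(0), 2.0, 0.0,
                            0.005, 0.05, 1.0, *s, v_out)
        assert abs(y[_crn.IV] - v0) < 0.5

    def test_deterministic(self):
        a = cell.resting_state(AF)
        b = cell.resting_state(AF)
        np.testing.assert_array_equal(a, b)

    def test_gates_and_concentrations_valid(self, af_resting):
        cell.validate_state(af_resting)  # raises on violation


class TestIonicCurrent:
    def test_zero_scale_kills_current(self, baseline_resting):
        zeroed = RemodelingParams(scale_Ito=0.0)
        _, cur = cell.ionic_current(baseline_resting, zeroed)
        assert cur["I_to"] == 0.0

    @given(st.floats(0.05, 4.0), st.floats(0.05, 4.0),
           st.floats(0.05, 4.0), st.floats(0.05, 4.0))
    def test_scaling_linearity(self, s_to, s_kur, s_cal, s_k1):
        # use a depolarized probe state where all four currents are active
        y = cell.resting_state(BASE)
        y = cell.step_cell(y, BASE, i_stim=-40.0, dt=0.05)
        for _ in range(60):
            y = cell.step_cell(y, BASE, dt=0.05)
        _, ref = cell.ionic_current(y, BASE)
        _, cur = cell.ionic_current(
            y, RemodelingParams(s_to, s_kur, s_cal, s_k1))
        assert cur["I_to"] == pytest.approx(s_to * ref["I_to"], rel=1e-12)
        assert cur["I_Kur"] == pytest.approx(s_kur * ref["I_Kur"], rel=1e-12)
        assert cur["I_CaL"] == pytest.approx(s_cal * ref["I_CaL"], rel=1e-12)
        assert cur["I_K1"] == pytest.approx(s_k1 * ref["I_K1"], rel=1e-12)

    def test_af_preset_ik1_is_150pct(self, af_resting):
        _, base = cell.ionic_current(af_resting, BASE)
        _, af = cell.ionic_current(af_resting, AF)
        assert af["I_K1"] == pytest.approx(1.5 * base["I_K1"], rel=1e-12)

    def test_invalid_gate_rejected(self, baseline_resting):
        y = baseline_resting.copy()
        y[_crn.IM] = 1.5
        with pytest.raises(cell.CellError, match="outside"):
            cell.ionic_current(y, BASE)


class TestStepCell:
    def test_rest_is_fixed_point(self, af_resting):
        y = cell.step_cell(af_resting, AF, i_stim=0.0, dt=0.05)
        assert abs(y[_crn.IV] - af_resting[_crn.IV]) < 1e-3

    def test_suprathreshold_stimulus_fires(self, af_resting):
        y = af_resting.copy()
        t = 0.0
        while t < 2.0:  # 2-ms stimulus
            y = cell.step_cell(y, AF, i_stim=-40.0, dt=0.05)
            t += 0.05
        while t < 5.0:
            y = cell.step_cell(y, AF, dt=0.05)
            t += 0.05
            if y[_crn.IV] > 0.0:
                break
        assert y[_crn.IV] > 0.0

    def test_dt_out_of_range_rejected(self, af_resting):
        with pytest.raises(ValueError):
            cell.step_cell(af_resting, AF, dt=0.2)

    def test_halving_dt_changes_v_little(self, af_resting):
        # convergence contract: 1 ms of integration, dt vs dt/2
        out = {}
        for dt in (0.05, 0.025):
            y = af_resting.copy()
            t = 0.0
            while t < 1.0 - 1e-9:
                y = cell.step_cell(y, AF, i_stim=-20.0, dt=dt)
                t += dt
            out[dt] = y[_crn.IV]
        assert abs(out[0.05] - out[0.025]) < 0.01


class TestPacing:
    def test_subthreshold_no_upstroke(self):
        thr = cell.diastolic_threshold(AF)
        tr = cell.pace_cell(AF, 500.0, 1, stim_amplitude=0.25 * thr)
        assert len(cell._find_upstrokes(tr)) == 0

    def test_trace_structure(self):
        tr = cell.pace_cell(AF, 400.0, 3)
        assert len(tr.stim_times) == 3
        assert np.all(np.diff(tr.stim_times) == 400.0)
        cell.validate_state  # trace sampled uniformly by construction
        assert tr.dt == pytest.approx(0.2)

    def test_apd_self_convergence_across_step_caps(self):
        """APD90 with max step 0.05 ms vs uniform 0.005 ms differs < 1 ms."""
        s = AF.as_tuple()
        apds = []
        for dt_hi in (0.05, 0.005):
            y = cell.resting_state(AF)
            n = int(500.0 / 0.1) + 1
            v = np.empty(n)
            _crn.integrate_cell(y, 0.0, 500.0, np.array([10.0]), 2.0, -25.0,
                                0.005, dt_hi, 0.1, *s, v)
            apds.append(cell.measure_apd90(
                cell.APTrace(0.1 * np.arange(n), v)))
        assert abs(apds[0] - apds[1]) < 1.0

    def test_identity_apd90_matches_generic_ode_solver(self):
        """Cross-check the custom integrator against scipy's LSODA."""
        from scipy.integrate import solve_ivp
        y0 = cell.resting_state(BASE)
        s = BASE.as_tuple()

        def rhs(t, y):
            i_stim = -25.0 if 10.0 <= t < 12.0 else 0.0
            return _crn.rhs(t, y, i_stim, s)

        t_eval = np.arange(0.0, 450.0, 0.2)
        sol = solve_ivp(rhs, (0.0, 450.0), y0, method="LSODA",
                        t_eval=t_eval, rtol=1e-7, atol=1e-9, max_step=1.0)
        apd_ref = cell.measure_apd90(cell.APTrace(sol.t, sol.y[0]))

        n = int(450.0 / 0.2) + 1
        v = np.empty(n)
        y = y0.copy()
        _crn.integrate_cell(y, 0.0, 450.0, np.array([10.0]), 2.0, -25.0,
                            0.005, 0.05, 0.2, *s, v)
        apd = cell.measure_apd90(cell.APTrace(0.2 * np.arange(n), v))
        assert apd == pytest.approx(apd_ref, abs=2.0)

    def test_gates_bounded_after_pacing(self):
        y = cell.resting_state(AF)
        s = AF.as_tuple()
        v = np.empty(1001)
        _crn.integrate_cell(y, 0.0, 1000.0, np.array([10.0, 510.0]), 2.0,
                            -25.0, 0.005, 0.05, 1.0, *s, v)
        cell.validate_state(y)

    def test_restitution_monotone(self):
        apd_fast = cell.measure_apd90(cell.pace_cell(AF, 300.0, 10))
        apd_slow = cell.measure_apd90(cell.pace_cell(AF, 800.0, 10))
        assert apd_fast < apd_slow


class TestMeasureApd90:
    def test_triangle_pulse(self):
        # baseline -80 mV, instant rise to +40, linear fall over 300 ms
        dt = 0.5
        t = np.arange(0.0, 400.0, dt)
        v = np.full_like(t, -80.0)
        fall = (t >= 50.0) & (t < 350.0)
        v[fall] = 40.0 - 120.0 * (t[fall] - 50.0) / 300.0
        apd = cell.measure_apd90(cell.APTrace(t, v))
        assert apd == pytest.approx(270.0, abs=1.5)

    def test_flat_trace_undefined(self):
        t = np.arange(0.0, 1000.0, 1.0)
        with pytest.raises(cell.CellError, match="undefined"):
            cell.measure_apd90(cell.APTrace(t, np.full_like(t, -81.0)))

    def test_unrepolarized_beat_skipped(self):
        with pytest.raises(cell.CellError):
            # rise then hold depolarized forever: never repolarizes
            t = np.arange(0.0, 500.0, 0.5)
            v = np.where(t < 10.0, -80.0, 20.0)
            cell.measure_apd90(cell.APTrace(t, v))


def test_aptrace_rejects_nonuniform_times():
    with pytest.raises(ValueError):
        cell.APTrace(np.array([0.0, 1.0, 3.0]), np.zeros(3))


def test_aptrace_csv_roundtrip(tmp_path):
    tr = cell.APTrace(np.arange(5.0), np.linspace(-80, 20, 5))
    path = tmp_path / "trace.csv"
    tr.to_csv(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(arr[:, 1], tr.voltages, rtol=1e-5)
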