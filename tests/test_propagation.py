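"""Monodomain solver: operator contracts, conservation, CV, calibration."""

import numpy as np
import pytest

from lafib import cell, geometry as G, propagation as P
from lafib._crn import IV, N_STATE

AF = cell.PRESETS["af_remodeled"]


@pytest.fixture(scope="module")
def fine_sheet():
    return G.make_sheet(41, 41, 0.5)


@pytest.fixture(scope="module")
def fine_operator(fine_sheet):
    return P.build_diffusion_operator(fine_sheet, P.DiffusionField(1.0))


class TestOperator:
    def test_constant_field_in_kernel(self, fine_sheet, fine_operator):
        v = np.full(fine_sheet.n_nodes, 3.7)
        out = fine_operator @ v
        assert np.max(np.abs(out)) < 1e-9 * np.abs(fine_operator.data).max()

    def test_linear_field_harmonic(self, fine_sheet, fine_operator):
        v = fine_sheet.points[:, 0].copy()
        out = fine_operator @ v
        interior = ~fine_sheet.boundary
        assert np.max(np.abs(out[interior])) < 1e-3 * np.abs(
            fine_operator.data).max()

    def test_quadratic_field_laplacian(self, fine_sheet, fine_operator):
        v = fine_sheet.points[:, 0] ** 2
        out = fine_operator @ v
        # keep well away from the no-flux boundary
        p = fine_sheet.points
        inner = ((p[:, 0] > 4) & (p[:, 0] < 16)
                 & (p[:, 1] > 4) & (p[:, 1] < 16))
        np.testing.assert_allclose(out[inner], 2.0, rtol=0.05)

    def test_masked_nodes_have_zero_rows_and_columns(self, fine_sheet):
        mask = np.ones(fine_sheet.n_nodes, dtype=bool)
        dead = np.arange(100, 140)
        mask[dead] = False
        A = P.build_diffusion_operator(fine_sheet, P.DiffusionField(1.0, mask))
        dense_rows = np.abs(A[dead]).sum()
        dense_cols = np.abs(A[:, dead]).sum()
        assert dense_rows == 0 and dense_cols == 0

    def test_rows_sum_to_zero(self, fine_operator):
        rowsum = np.asarray(fine_operator.sum(axis=1)).ravel()
        assert np.max(np.abs(rowsum)) < 1e-9 * np.abs(
            fine_operator.data).max()


class TestConservation:
    def test_pure_diffusion_conserves_area_weighted_mean(self, fine_sheet,
                                                         fine_operator):
        rng = np.random.default_rng(0)
        v = rng.uniform(-80, 20, fine_sheet.n_nodes)
        w = fine_sheet.node_area
        total0 = float(w @ v)
        dt = 0.02
        for _ in range(500):
            v = v + dt * 0.1 * (fine_operator @ v)
        assert float(w @ v) == pytest.approx(total0, rel=1e-6)


class TestStepping:
    def test_fencepost_frames(self):
        mesh = G.make_sheet(4, 4, 1.0)
        sim = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        rec = sim.run(10.0)
        assert rec.V.shape[0] == 11

    def test_homogeneous_rest_stays_constant(self):
        mesh = G.make_sheet(6, 6, 1.0)
        sim = P.Simulator(mesh, P.DiffusionField(0.2), AF)
        rec = sim.run(50.0)
        assert np.max(np.abs(rec.V[-1] - rec.V[0])) < 1e-3

    def test_decoupled_matches_isolated_cell(self):
        """D = 0: every node evolves exactly as a single cell."""
        mesh = G.make_sheet(3, 3, 1.0)
        sim = P.Simulator(mesh, P.DiffusionField(0.0), AF)
        sim.add_stimulus(P.StimulusEvent(np.arange(9), 10.0, 2.0, 25.0))
        rec = sim.run(400.0)
        # exact-formula integrator at the same fixed step
        import lafib._crn as _crn
        y = cell.resting_state(AF)
        n = 401
        v = np.empty(n)
        _crn.integrate_cell(y, 0.0, 400.0, np.array([10.0]), 2.0, -25.0,
                            sim.dt, sim.dt, 1.0, *AF.as_tuple(), v)
        assert np.max(np.abs(rec.V[:, 4] - v)) < 0.5
        apd_t = cell.measure_apd90(cell.APTrace(rec.times, rec.V[:, 4]))
        apd_c = cell.measure_apd90(cell.APTrace(np.arange(n, dtype=float), v))
        assert apd_t == pytest.approx(apd_c, abs=1.0)

    def test_point_stimulus_expands_radially(self):
        mesh = G.make_sheet(21, 21, 0.5)
        center = 10 * 21 + 10
        sim = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        near = np.nonzero(np.linalg.norm(
            mesh.points - mesh.points[center], axis=1) <= 1.0)[0]
        sim.add_stimulus(P.StimulusEvent(near, 5.0, 2.0, 60.0))
        rec = sim.run(60.0)
        d = np.linalg.norm(mesh.points - mesh.points[center], axis=1)
        act = np.array([P.activation_time(rec, i) for i in range(len(d))])
        rings = np.digitize(d, [1.5, 3.0, 4.5, 6.0])
        means = [act[rings == k].mean() for k in range(5)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_checkpoint_resume_bit_reproducible(self):
        mesh = G.make_sheet(11, 5, 0.5)
        stim = P.StimulusEvent(np.arange(5) * 11, 10.0, 2.0, 40.0)

        sim_a = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        sim_a.add_stimulus(stim)
        sim_a.run(200.0, record=False)
        rec_a = sim_a.run(100.0)

        sim_b = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        sim_b.add_stimulus(stim)
        sim_b.run(200.0, record=False)
        ck = sim_b.checkpoint()
        sim_c = P.Simulator(mesh, P.DiffusionField(0.1), AF, init=ck)
        sim_c.add_stimulus(stim)
        rec_c = sim_c.run(100.0)
        np.testing.assert_allclose(rec_a.V, rec_c.V, atol=1e-9)

    def test_blowup_reported_with_time_and_node(self):
        mesh = G.make_sheet(4, 4, 1.0)
        sim = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        sim.state.S[:, IV] = 250.0  # absurd initial potential
        sim._vbuf[:] = 250.0
        sim.add_stimulus(P.StimulusEvent(np.arange(16), 0.0, 50.0, -4000.0))
        with pytest.raises(P.SimulationError, match="blow-up at t="):
            sim.run(20.0)

    def test_checkpoint_shape_validated(self):
        mesh = G.make_sheet(4, 4, 1.0)
        bad = P.TissueState(np.zeros((3, N_STATE)), 0.0)
        with pytest.raises(ValueError):
            P.Simulator(mesh, P.DiffusionField(0.1), AF, init=bad)


class TestCV:
    def test_default_diffusion_hits_04(self):
        cv = P.cv_on_strip(P.DEFAULT_DIFFUSION)
        assert cv == pytest.approx(0.4, rel=0.05)

    def test_zero_distance_probes_rejected(self, paced_sheet_recordings):
        rec = paced_sheet_recordings[500.0]
        with pytest.raises(ValueError, match="coincident"):
            P.measure_cv(rec, 3, 3)

    def test_never_activating_probe_raises(self):
        mesh = G.make_sheet(6, 3, 1.0)
        sim = P.Simulator(mesh, P.DiffusionField(0.1), AF)
        rec = sim.run(50.0)  # never stimulated
        with pytest.raises(P.NoCaptureError):
            P.measure_cv(rec, 0, 5)

    def test_calibration_monotone_in_target(self):
        d4, _ = P.calibrate_diffusion(0.4, 0.25, AF)
        d5, _ = P.calibrate_diffusion(0.5, 0.25, AF)
        d6, _ = P.calibrate_diffusion(0.6, 0.25, AF)
        assert d4 < d5 < d6


def test_step_tissue_single_step_matches_simulator():
    mesh = G.make_sheet(4, 4, 1.0)
    field = P.DiffusionField(0.1)
    sim = P.Simulator(mesh, field, AF, record_interval=0.05, dt_max=0.05)
    state0 = sim.checkpoint()
    out = P.step_tissue(state0, mesh, field, AF, dt=0.05)
    sim.run(0.05, record=False)
    np.testing.assert_allclose(out.S, sim.checkpoint().S, atol=1e-12)
    assert out.t == pytest.approx(0.05)
    with pytest.raises(ValueError):
        P.step_tissue(state0, mesh, field, AF, dt=0.2)


def test_stable_dt_respects_cfl_and_sampling():
    mesh = G.make_sheet(21, 5, 0.25)
    A = P.build_diffusion_operator(mesh, P.DiffusionField(1.0))
    dt = P.stable_dt(A, D=0.3, record_interval=1.0)
    max_diag = np.abs(A.diagonal()).max()
    assert 0.3 * dt * max_diag < 0.5
    assert round(1.0 / dt, 6) == int(round(1.0 / dt))


def test_diffusion_field_validation():
    with pytest.raises(ValueError):
        P.DiffusionField(-1.0)
    with pytest.raises(ValueError):
        P.StimulusEvent(np.array([], dtype=int), 0.0, 2.0)
    with pytest.raises(ValueError):
        P.StimulusEvent(np.array([1]), 0.0, 0.0)
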