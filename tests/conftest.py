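"""Shared fixtures.

Heavy simulation products (paced-sheet recordings, the scaled-down study)
are session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lafib import cell, dfmap, geometry, propagation, protocol

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


AF = cell.PRESETS["af_remodeled"]
AFC = cell.PRESETS["af_calibrated"]
BASE = cell.PRESETS["baseline"]


@pytest.fixture(scope="session")
def af_resting():
    return cell.resting_state(AF)


@pytest.fixture(scope="session")
def baseline_resting():
    return cell.resting_state(BASE)


#: Short-APD remodeling variant (stronger ICaL block) used for the pacing
#: identity checks: the study's AF presets conduct 2:1 beyond the pacing
#: margin at a 200-ms cycle length (tissue refractoriness exceeds the CL),
#: so "captured tissue" at 5 Hz needs a substrate with APD90 well below
#: 200 ms.  This variant conducts 1:1 at all three tested rates.
SHORT_APD = cell.RemodelingParams(0.2, 0.5, 0.3, 1.5)


def pace_sheet(cycle_length: float, duration_ms: float,
               nx: int = 21, ny: int = 6, dx: float = 1.0,
               remodeling=SHORT_APD) -> propagation.APRecording:
    """Small planar sheet paced from the left edge at a fixed cycle length."""
    mesh = geometry.make_sheet(nx, ny, dx)
    sim = propagation.Simulator(mesh, propagation.DiffusionField(0.1),
                                remodeling)
    pace = np.nonzero(mesh.points[:, 0] <= 2 * dx)[0]
    n_beats = int(np.ceil(duration_ms / cycle_length)) + 1
    for k in range(n_beats):
        sim.add_stimulus(propagation.StimulusEvent(
            pace, 10.0 + cycle_length * k, 2.0, 40.0))
    return sim.run(float(np.ceil(duration_ms)))


@pytest.fixture(scope="session")
def paced_sheet_recordings():
    """Recordings of a captured sheet at CL 200/250/500 ms (>= 6 s each)."""
    return {cl: pace_sheet(cl, 6200.0) for cl in (200.0, 250.0, 500.0)}


@pytest.fixture(scope="session")
def la_mesh():
    return geometry.make_synthetic_la(geometry.SyntheticLAParams(seed=1))


@pytest.fixture(scope="session")
def calibrated_d_la():
    """Diffusion coefficient calibrated to 0.4 m/s at the default LA edge."""
    D, _ = propagation.calibrate_diffusion(
        0.4, geometry.SyntheticLAParams().target_edge_length_mm, AFC)
    return D


@pytest.fixture(scope="session")
def study_report(tmp_path_factory):
    """The scaled-down study: 3 geometries x 3 windows x 3 fractions."""
    from lafib.config import StudyConfig
    from lafib.study import run_study
    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(n_geometries=3, global_seed=1,
                      induction_mode="reentrant", n_windows=3,
                      window_length_ms=2000.0, window_start_ms=1000.0,
                      follow_ms=3000.0, baseline_follow=False,
                      out_dir=str(out))
    return run_study(cfg)
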