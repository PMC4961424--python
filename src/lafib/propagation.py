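"""Monodomain reaction-diffusion on surface meshes.

dV/dt = D lap(V) - (I_ion + I_stim)/Cm with the Courtemanche reaction term.
The surface Laplacian is a cotangent-weighted Laplace-Beltrami operator with
barycentric lumped mass (negative cotangent weights clamped to zero), which
satisfies zero row sums (no-flux boundaries) and conserves the area-weighted
mean of V under pure diffusion.  Time integration is explicit
(forward Euler for V and concentrations, Rush-Larsen for gates) at a fixed
step chosen from the diffusion CFL bound within [0.005, 0.05] ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import _crn, _kernels, cell
from .cell import RemodelingParams, PRESETS
from .geometry import SurfaceMesh, make_sheet

__all__ = [
    "DiffusionField", "StimulusEvent", "TissueState", "APRecording",
    "SimulationError", "NoCaptureError",
    "build_diffusion_operator", "Simulator", "run_simulation", "step_tissue",
    "measure_cv", "calibrate_diffusion", "cv_on_strip",
    "DEFAULT_DIFFUSION", "DEFAULT_EDGE_MM",
]

#: Calibration-strip edge length (mm) used for the delivered defaults.
DEFAULT_EDGE_MM = 0.25

#: Default diffusion coefficient (mm^2/ms): calibrated once with
#: ``calibrate_diffusion(0.4, DEFAULT_EDGE_MM, PRESETS["af_remodeled"])`` so a
#: planar wave on a 0.25-mm strip of AF-remodeled tissue conducts at 0.4 m/s.
DEFAULT_DIFFUSION = 0.092724609375


class SimulationError(RuntimeError):
    pass


class NoCaptureError(SimulationError):
    pass


@dataclass
class DiffusionField:
    """Homogeneous gap-junctional coupling with a per-node conduction mask."""

    D: float = DEFAULT_DIFFUSION      # mm^2/ms
    conducting: np.ndarray = None     # (n,) bool; False = non-conducting
    Cm: float = _crn.CM               # pF

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("D must be >= 0")

    def for_mesh(self, mesh: SurfaceMesh) -> "DiffusionField":
        if self.conducting is None:
            return DiffusionField(self.D, np.ones(mesh.n_nodes, dtype=bool), self.Cm)
        if len(self.conducting) != mesh.n_nodes:
            raise ValueError("conduction mask length != number of nodes")
        return DiffusionField(self.D, np.asarray(self.conducting, bool), self.Cm)


@dataclass
class StimulusEvent:
    """Current injection into a node set: onset/duration in ms, pA/pF.

    ``amplitude`` is the magnitude of the depolarizing (inward) current.
    """

    nodes: np.ndarray
    onset: float
    duration: float
    amplitude: float = 40.0

    def __post_init__(self):
        self.nodes = np.atleast_1d(np.asarray(self.nodes, dtype=np.int64))
        if self.nodes.size == 0:
            raise ValueError("stimulus node set is empty")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")


@dataclass
class TissueState:
    """Full solver state: one ionic state vector per node plus current time."""

    S: np.ndarray        # (n, 21)
    t: float             # ms

    def copy(self) -> "TissueState":
        return TissueState(self.S.copy(), self.t)

    def save(self, path) -> None:
        """Checkpoint file: full float64 state vectors with time stamp."""
        np.savez_compressed(path, S=self.S.astype(np.float64),
                            t=np.float64(self.t))

    @classmethod
    def load(cls, path) -> "TissueState":
        with np.load(path) as f:
            return cls(f["S"], float(f["t"]))


@dataclass
class APRecording:
    """Node x time membrane-potential matrix at a fixed sampling interval."""

    times: np.ndarray          # (n_frames,) ms
    V: np.ndarray              # (n_frames, n_nodes) float32, mV
    mesh: SurfaceMesh = None
    meta: dict = dc_field(default_factory=dict)

    @property
    def fs(self) -> float:
        """Sampling rate in kHz (samples per ms)."""
        return 1.0 / float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> "APRecording":
        m = (self.times >= t0 - 1e-9) & (self.times < t1 - 1e-9)
        if not np.any(m):
            raise ValueError(f"window [{t0}, {t1}) outside recording")
        return APRecording(self.times[m], self.V[m], self.mesh, dict(self.meta))

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("V", data=self.V, compression="gzip")
            f.create_dataset("t", data=self.times)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path, mesh=None) -> "APRecording":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(f["t"][:], f["V"][:], mesh, dict(f.attrs))


def build_diffusion_operator(mesh: SurfaceMesh,
                             field: DiffusionField) -> sp.csr_matrix:
    """Mass-lumped cotangent Laplacian (1/mm^2), masked to conducting nodes.

    Rows sum to zero over conducting nodes; non-conducting nodes have all-zero
    rows and columns, so they exchange no flux with any neighbor.
    """
    field = field.for_mesh(mesh)
    p = mesh.points
    t = mesh.triangles
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    clamped = 0
    for k in range(3):
        i = t[:, k]
        j = t[:, (k + 1) % 3]
        o = t[:, (k + 2) % 3]
        u = p[i] - p[o]
        v = p[j] - p[o]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-12)
        neg = cot < 0
        clamped += int(neg.sum())
        cot = np.where(neg, 0.0, cot)
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    if clamped:
        warnings.warn(f"{clamped} negative cotangent weights clamped to zero",
                      RuntimeWarning, stacklevel=2)
    W = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    mask = field.conducting
    keep = sp.diags(mask.astype(float))
    W = keep @ W @ keep
    diag = np.asarray(W.sum(axis=1)).ravel()
    L = W - sp.diags(diag)
    A = sp.diags(1.0 / mesh.node_area) @ L
    A = A.tocsr()
    A.eliminate_zeros()
    if mask.sum() > 1:
        sub = mesh.adjacency()[mask][:, mask]
        if connected_components(sub, directed=False)[0] > 1:
            warnings.warn("conducting subgraph is disconnected",
                          RuntimeWarning, stacklevel=2)
    return A


def stable_dt(A: sp.csr_matrix, D: float, record_interval: float = 1.0,
              dt_max: float = 0.05, safety: float = 0.9) -> float:
    """Largest admissible step <= dt_max dividing the sampling interval.

    Explicit-diffusion bound: D * dt * max|diag(A)| < 0.5.
    """
    max_diag = float(np.abs(A.diagonal()).max()) if A.nnz else 0.0
    lim = dt_max if D * max_diag == 0 else min(
        dt_max, safety * 0.5 / (D * max_diag))
    n_sub = int(np.ceil(record_interval / lim - 1e-12))
    dt = record_interval / n_sub
    if dt < 0.005 - 1e-12:
        # below the usual operating range; stability wins over the nominal
        # bounds but fine meshes get expensive quickly
        warnings.warn(f"CFL-stable step {dt:.4g} ms is below 0.005 ms",
                      RuntimeWarning, stacklevel=2)
    return dt


class Simulator:
    """Explicit monodomain integrator on a surface mesh.

    Stimuli are registered with :meth:`add_stimulus`; :meth:`run` advances
    the tissue and returns an :class:`APRecording` (the initial frame plus
    one frame per ``record_interval``).  :meth:`checkpoint` captures the full
    solver state so trials (e.g. ablations) can branch from a saved instant;
    resuming from a checkpoint is bit-exact with an uninterrupted run.
    """

    def __init__(self, mesh: SurfaceMesh, field: DiffusionField = None,
                 remodeling: RemodelingParams = PRESETS["af_remodeled"],
                 record_interval: float = 1.0,
                 init: TissueState | None = None,
                 dt_max: float = 0.05):
        self.mesh = mesh
        self.field = (field or DiffusionField()).for_mesh(mesh)
        self.remodeling = remodeling
        self.record_interval = float(record_interval)
        self.A = build_diffusion_operator(mesh, self.field)
        self.dt = stable_dt(self.A, self.field.D, self.record_interval,
                            dt_max=dt_max)
        n = mesh.n_nodes
        if init is None:
            y0 = cell.resting_state(remodeling)
            self.state = TissueState(np.tile(y0, (n, 1)), 0.0)
        else:
            if init.S.shape != (n, _crn.N_STATE):
                raise ValueError("checkpoint does not match mesh size")
            self.state = init.copy()
        self._events: list[StimulusEvent] = []
        self._tab = _kernels.voltage_tables(self.dt)
        self._sig = _kernels.sigmoid_table()
        self._vbuf = np.ascontiguousarray(self.state.S[:, 0])
        self._work = [np.zeros(n) for _ in range(6)]

    # -- stimuli -------------------------------------------------------------

    def add_stimulus(self, event: StimulusEvent) -> None:
        if event.nodes.max() >= self.mesh.n_nodes:
            raise ValueError("stimulus node outside mesh")
        self._events.append(event)

    def add_stimuli(self, events) -> None:
        for e in events:
            self.add_stimulus(e)

    def _event_arrays(self):
        evs = self._events
        if not evs:
            z = np.zeros(0, dtype=np.int64)
            return z, np.zeros(1, dtype=np.int64), np.zeros(0), np.zeros(0), np.zeros(0)
        nodes = np.concatenate([e.nodes for e in evs])
        ptr = np.zeros(len(evs) + 1, dtype=np.int64)
        ptr[1:] = np.cumsum([len(e.nodes) for e in evs])
        on = np.array([e.onset for e in evs])
        off = np.array([e.onset + e.duration for e in evs])
        amp = np.array([-abs(e.amplitude) for e in evs])
        return nodes, ptr, on, off, amp

    # -- time stepping -------------------------------------------------------

    def run(self, duration: float, record: bool = True) -> APRecording | None:
        """Advance by ``duration`` ms; optionally return the recording."""
        if duration <= 0:
            raise ValueError("duration must be > 0")
        n_samples = int(round(duration / self.record_interval))
        if abs(n_samples * self.record_interval - duration) > 1e-6:
            raise ValueError("duration must be a multiple of record_interval")
        n = self.mesh.n_nodes
        sample_every = int(round(self.record_interval / self.dt))
        v_samples = np.empty((n_samples, n), dtype=np.float32)
        nodes, ptr, on, off, amp = self._event_arrays()
        s = self.remodeling.as_tuple()
        lap, istim, e_na, e_k, e_ca, fnak = self._work
        refresh_every = max(1, int(round(0.5 / self.dt)))
        v0 = self._vbuf.astype(np.float32)
        t0 = self.state.t
        bad = _kernels.run_chunk(
            self.state.S, self._vbuf, self.field.conducting,
            self.A.indptr, self.A.indices, self.A.data, self.field.D,
            self._tab, self._sig, s[0], s[1], s[2], s[3], s[4], s[5],
            self.dt, t0, nodes, ptr, on, off, amp,
            sample_every, v_samples,
            lap, istim, e_na, e_k, e_ca, fnak, refresh_every)
        if bad:
            t_bad = t0 + bad * self.dt
            node = int(np.argmax(np.abs(self._vbuf)))
            raise SimulationError(
                f"simulation blow-up at t={t_bad:.3f} ms, node {node}")
        self.state.t = t0 + n_samples * self.record_interval
        if not record:
            return None
        times = t0 + self.record_interval * np.arange(n_samples + 1)
        V = np.vstack([v0[None, :], v_samples])
        return APRecording(times, V, self.mesh,
                           {"D": self.field.D, "dt": self.dt,
                            "remodeling": s})

    def checkpoint(self) -> TissueState:
        self.state.S[:, 0] = self._vbuf
        return self.state.copy()


def step_tissue(state: TissueState, mesh: SurfaceMesh, field: DiffusionField,
                remodeling: RemodelingParams, stimuli=(),
                dt: float = 0.05) -> TissueState:
    """Advance a tissue state by one step of length ``dt`` (ms).

    Convenience wrapper over :class:`Simulator` for single-step use; batch
    work should drive a Simulator directly.
    """
    if not 0.005 - 1e-12 <= dt <= 0.05 + 1e-12:
        raise ValueError("dt must lie in [0.005, 0.05] ms")
    sim = Simulator(mesh, field, remodeling, record_interval=dt, init=state,
                    dt_max=dt)
    sim.add_stimuli(stimuli)
    sim.run(dt, record=False)
    return sim.checkpoint()


def run_simulation(mesh: SurfaceMesh, field: DiffusionField,
                   remodeling: RemodelingParams, stimuli,
                   duration: float, record_interval: float = 1.0,
                   init: TissueState | None = None) -> APRecording:
    """One-shot harness: build a :class:`Simulator`, stimulate, record."""
    sim = Simulator(mesh, field, remodeling, record_interval, init=init)
    sim.add_stimuli(stimuli)
    return sim.run(duration)


# ---------------------------------------------------------------------------
# conduction velocity
# ---------------------------------------------------------------------------

def activation_time(rec: APRecording, node: int, t_min: float = 0.0,
                    threshold: float = -40.0) -> float:
    """First upward crossing of ``threshold`` after ``t_min`` (interpolated)."""
    v = rec.V[:, node].astype(float)
    t = rec.times
    ok = t >= t_min
    v = v[ok]
    t = t[ok]
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    if len(up) == 0:
        raise NoCaptureError(f"node {node} never activates after t={t_min}")
    k = up[0]
    frac = (threshold - v[k]) / (v[k + 1] - v[k])
    return float(t[k] + frac * (t[k + 1] - t[k]))


def measure_cv(rec: APRecording, probe_a: int, probe_b: int,
               t_min: float = 0.0) -> float:
    """Conduction velocity (m/s) between two probes from activation times."""
    pa = rec.mesh.points[probe_a]
    pb = rec.mesh.points[probe_b]
    dist = float(np.linalg.norm(pb - pa))
    if dist <= 0:
        raise ValueError("probes are coincident")
    ta = activation_time(rec, probe_a, t_min)
    tb = activation_time(rec, probe_b, t_min)
    if tb == ta:
        raise SimulationError("zero conduction delay between probes")
    return dist / abs(tb - ta)  # mm/ms == m/s


def _strip_for_resolution(h: float) -> tuple[SurfaceMesh, int, int, np.ndarray]:
    """Calibration strip, two central probes >= 10 mm apart, pacing column."""
    length = max(25.0, 40.0 * h)
    width = max(2.5, 4.0 * h)
    nx = int(round(length / h)) + 1
    ny = int(round(width / h)) + 1
    mesh = make_sheet(nx, ny, h)
    row = (ny // 2) * nx
    gap = max(1, int(round(0.4 * length / h)))
    i0 = (nx - gap) // 2
    probe_a = row + i0
    probe_b = row + i0 + gap
    # pace a patch >= 2 edges deep at the left end (a single column cannot
    # source enough current against diffusion at physiological D)
    depth = max(0.5, 2.0 * h)
    pace = np.nonzero(mesh.points[:, 0] <= depth + 1e-9)[0]
    return mesh, probe_a, probe_b, pace


def cv_on_strip(D: float, resolution_mm: float = DEFAULT_EDGE_MM,
                remodeling: RemodelingParams = PRESETS["af_remodeled"],
                cycle_length: float = 500.0, n_beats: int = 4,
                stim_amplitude: float = 40.0, dt_max: float = 0.05) -> float:
    """Longitudinal CV on a planar strip paced from one end.

    The strip is paced at ``cycle_length`` for ``n_beats`` (the last beat is
    the measured one, after three conditioning beats by default) and CV is
    read from -40-mV activation times at two central probes.
    """
    mesh, pa, pb, pace = _strip_for_resolution(resolution_mm)
    field = DiffusionField(D)
    sim = Simulator(mesh, field, remodeling, dt_max=dt_max)
    onsets = 10.0 + cycle_length * np.arange(n_beats)
    for t_on in onsets:
        sim.add_stimulus(StimulusEvent(pace, t_on, 2.0, stim_amplitude))
    tail = 4.0 * np.linalg.norm(mesh.points[pb] - mesh.points[pa]) / max(D, 1e-6) ** 0.5
    duration = float(onsets[-1] + max(150.0, min(tail, 600.0)))
    duration = np.ceil(duration)
    rec = sim.run(duration)
    return measure_cv(rec, pa, pb, t_min=float(onsets[-1]))


_calib_cache: dict[tuple, tuple[float, float]] = {}


def calibrate_diffusion(target_cv: float,
                        resolution_mm: float = DEFAULT_EDGE_MM,
                        remodeling: RemodelingParams = PRESETS["af_remodeled"],
                        rel_tol: float = 0.02,
                        ) -> tuple[float, float]:
    """Bisect D until the strip CV matches ``target_cv`` (m/s) within tol.

    Returns ``(D, achieved_cv)``; cached per (target, resolution, remodeling).
    """
    if target_cv <= 0:
        raise ValueError("target CV must be positive")
    key = (round(target_cv, 4), round(resolution_mm, 5), remodeling.as_tuple())
    if key in _calib_cache:
        return _calib_cache[key]

    def f(d):
        try:
            return cv_on_strip(d, resolution_mm, remodeling)
        except NoCaptureError:
            return 0.0  # propagation failure: treat as CV too low

    # CV scales ~ sqrt(D): start from the shipped default calibration
    d0 = DEFAULT_DIFFUSION * (target_cv / 0.4) ** 2
    tried = {d0: f(d0)}
    d_lo = d_hi = d0
    for _ in range(12):
        if tried[d_lo] >= target_cv:
            d_lo /= 2
            tried[d_lo] = f(d_lo)
        elif tried[d_hi] < target_cv:
            d_hi *= 2
            tried[d_hi] = f(d_hi)
        else:
            break
    if not (tried[d_lo] < target_cv <= tried[d_hi]):
        raise SimulationError(
            f"calibration bracket failure for CV {target_cv} m/s; "
            f"scanned D in [{min(tried):.4g}, {max(tried):.4g}]")
    best = min(tried.items(), key=lambda kv: abs(kv[1] - target_cv))
    for _ in range(24):
        if abs(best[1] - target_cv) <= rel_tol * target_cv:
            break
        d_mid = 0.5 * (d_lo + d_hi)
        cv = f(d_mid)
        if abs(cv - target_cv) < abs(best[1] - target_cv):
            best = (d_mid, cv)
        if cv < target_cv:
            d_lo = d_mid
        else:
            d_hi = d_mid
    if abs(best[1] - target_cv) > rel_tol * target_cv:
        raise SimulationError(
            f"calibration did not converge: best CV {best[1]:.4f} m/s "
            f"for target {target_cv}")
    _calib_cache[key] = best
    return best
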