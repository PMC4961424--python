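"""End-to-end scaled-down study: geometries -> AF -> DF windows -> ablation -> stats.

Per synthetic geometry ("patient"): calibrate coupling to the CV target,
obtain sustained AF (ramp-pacing induction, with the documented
phase-distributed reentrant initialization as fallback), record the DF
analysis windows with end-of-window checkpoints, compute DF maps and the
windows x sections % High DF Area table, run independent ablation trials at
each area fraction from each checkpoint, and optionally follow the unablated
baseline.  Across geometries the statistical pipeline is applied and all
tables are persisted as CSV/JSON (plus optional VTK scalar fields).

Completed geometries are written to the output directory as they finish and
are skipped on re-runs with an identical configuration (crash-resume).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import ablation, dfmap, geometry, propagation, protocol, stats
from .cell import PRESETS
from .config import StudyConfig

log = logging.getLogger("lafib.study")

_FLOAT_FMT = "%.8g"


@dataclass
class GeometryResult:
    """Per-geometry products of the study pipeline."""

    seed: int
    complete: bool
    af_source: str                    # 'ramp' | reentry variant name | 'none'
    af_terminated_ms: float | None
    region_table: pd.DataFrame | None   # windows x R1..R10, % High DF Area
    cov: np.ndarray | None              # per-region temporal CoV (%)
    friedman: tuple | None              # (statistic, p)
    trials: list = dc_field(default_factory=list)
    baseline_termination_s: dict = dc_field(default_factory=dict)
    df_maps: dict = dc_field(default_factory=dict)      # in-memory only
    checkpoints: dict = dc_field(default_factory=dict)  # in-memory only


@dataclass
class StudyReport:
    config: StudyConfig
    geometries: list
    trials_df: pd.DataFrame | None
    outcome_table: pd.DataFrame | None
    cov_table: pd.DataFrame | None
    stats: dict


def _config_digest(cfg: StudyConfig) -> str:
    d = json.loads(cfg.to_json())
    d.pop("out_dir", None)
    d.pop("export_vtk", None)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _acquire_af(mesh, field, remodeling, cfg: StudyConfig, edge_mm: float):
    """Sustained-AF state with t reset to 0, or (None, 'none')."""
    if cfg.induction_mode in ("ramp", "auto"):
        prot = protocol.straight_pacing(mesh, beats_per_cl=cfg.beats_per_cl)
        res = protocol.induce_af(mesh, field, remodeling, prot,
                                 max_follow_ms=3000.0)
        if res.induced and res.self_termination_ms is None:
            state = res.final_state
            state.t = 0.0
            return state, "ramp"
        log.info("ramp pacing did not induce sustained AF")
    if cfg.induction_mode in ("reentrant", "auto"):
        state, variant = protocol.initiate_reentry(mesh, field, remodeling,
                                                   edge_mm)
        if state is not None:
            state.t = 0.0
            return state, variant
    return None, "none"


def _collect_windows(sim, windows, mesh):
    """Run to the last window end; return (recordings, checkpoints, term_ms)."""
    win_list = list(windows)
    end_ms = win_list[-1][1]
    tracker = protocol._QuietTracker(protocol.TERMINATION_QUIET_MS, 1.0)
    recs, ckpts = {}, {}
    buf = []
    n_chunks = int(np.ceil(end_ms / 1000.0))
    for c in range(n_chunks):
        t0 = c * 1000.0
        rec = sim.run(1000.0)
        if tracker.feed(rec.V[1:].max(axis=1), t0):
            return recs, ckpts, tracker.terminated_at
        if any(a < t0 + 1000.0 and t0 < b for a, b in win_list):
            buf.append(rec)
        for idx, (a, b) in enumerate(win_list):
            if abs(b - (t0 + 1000.0)) < 1e-6:
                frames = [r for r in buf if r.times[0] >= a - 1e-6]
                times = np.concatenate([r.times[:-1] for r in frames])
                V = np.vstack([r.V[:-1] for r in frames])
                recs[idx] = propagation.APRecording(times, V, mesh,
                                                    dict(rec.meta))
                ckpts[idx] = sim.checkpoint()
                buf = [r for r in buf
                       if any(r.times[-1] > a2 and r.times[0] < b2
                              for a2, b2 in win_list[idx + 1:])]
    return recs, ckpts, None


def run_geometry(cfg: StudyConfig, index: int, D: float) -> GeometryResult:
    seed = cfg.geometry_seed(index)
    remodeling = PRESETS[cfg.remodeling_preset]
    params = geometry.SyntheticLAParams(
        seed=seed, target_edge_length_mm=cfg.edge_mm,
        **cfg.geometry_overrides)
    mesh = geometry.make_synthetic_la(params)
    field = propagation.DiffusionField(D)
    state, source = _acquire_af(mesh, field, remodeling, cfg, cfg.edge_mm)
    if state is None:
        log.warning("geometry %d: no sustained AF; flagged incomplete", seed)
        return GeometryResult(seed, False, "none", None, None, None, None)

    sim = propagation.Simulator(mesh, field, remodeling, init=state)
    windows = cfg.windows()
    recs, ckpts, term_ms = _collect_windows(sim, windows, mesh)
    conducting = sim.field.conducting

    df_maps = {}
    rows = {}
    for idx in sorted(recs):
        w = windows.windows[idx]
        dm = dfmap.compute_df_map(recs[idx], w, cfg.df_band_hz, conducting)
        df_maps[idx] = dm
        mask10 = dfmap.high_df_mask(dm, mesh.node_area, 0.10, conducting)
        rows[f"T{idx + 1}"] = dfmap.regional_proportions(
            mask10, mesh.region, mesh.node_area)
    table = None
    cov = None
    fried = None
    if rows:
        table = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[f"R{r}" for r in range(1, geometry.N_REGIONS + 1)])
        if len(rows) >= 2:
            cov = np.array([stats.temporal_cov(table[c]) for c in table.columns])
            if len(rows) >= 2 and table.shape[1] >= 3:
                fried = stats.friedman_consistency(table)

    trials = []
    baseline = {}
    for idx in sorted(df_maps):
        ck = ckpts[idx]
        for frac in cfg.fractions:
            tr = ablation.run_ablation_trial(
                mesh, field, remodeling, ck, df_maps[idx], frac,
                follow_ms=cfg.follow_ms, window_index=idx,
                classify_seed=cfg.global_seed)
            tr.meta.update(geometry_seed=seed)
            trials.append(tr)
        if cfg.baseline_follow:
            baseline[idx] = ablation.follow_unablated(
                mesh, field, remodeling, ck, follow_ms=cfg.follow_ms,
                classify_seed=cfg.global_seed)

    complete = len(recs) == len(windows.windows)
    return GeometryResult(seed, complete, source, term_ms, table, cov, fried,
                          trials, baseline, df_maps, ckpts)


def _geometry_to_json(g: GeometryResult) -> dict:
    return {
        "seed": g.seed, "complete": g.complete, "af_source": g.af_source,
        "af_terminated_ms": g.af_terminated_ms,
        "region_table": None if g.region_table is None
        else g.region_table.round(8).to_dict(orient="split"),
        "cov": None if g.cov is None else [None if not np.isfinite(c) else
                                           round(float(c), 8) for c in g.cov],
        "friedman": None if g.friedman is None
        else [round(float(x), 10) for x in g.friedman],
        "trials": [{"window": t.window_index, "fraction": t.fraction,
                    "outcome": t.outcome.label,
                    "event_time_s": t.outcome.event_time_s} for t in g.trials],
        "baseline_termination_s": {str(k): v
                                   for k, v in g.baseline_termination_s.items()},
    }


def _geometry_from_json(d: dict) -> GeometryResult:
    table = d["region_table"]
    if table is not None:
        table = pd.DataFrame(table["data"], index=table["index"],
                             columns=table["columns"])
    cov = d["cov"]
    if cov is not None:
        cov = np.array([np.nan if c is None else c for c in cov])
    trials = [ablation.AblationTrial(
        fraction=t["fraction"],
        outcome=ablation.AblationOutcome(t["outcome"], t["event_time_s"]),
        window_index=t["window"], meta={"geometry_seed": d["seed"]})
        for t in d["trials"]]
    return GeometryResult(d["seed"], d["complete"], d["af_source"],
                          d["af_terminated_ms"], table, cov,
                          None if d["friedman"] is None else tuple(d["friedman"]),
                          trials,
                          {int(k): v for k, v in
                           d["baseline_termination_s"].items()})


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run (or resume) the full scaled-down study and persist all outputs."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    digest = _config_digest(cfg)
    cfg.to_json(os.path.join(cfg.out_dir, "config.json"))
    remodeling = PRESETS[cfg.remodeling_preset]
    D, cv = propagation.calibrate_diffusion(cfg.cv_target_m_s, cfg.edge_mm,
                                            remodeling)
    log.info("calibrated D=%.5f mm^2/ms (CV %.4f m/s)", D, cv)

    geoms = []
    for i in range(cfg.n_geometries):
        seed = cfg.geometry_seed(i)
        cache = os.path.join(cfg.out_dir, f"geometry_{seed}.json")
        if os.path.exists(cache):
            with open(cache) as f:
                d = json.load(f)
            if d.get("_digest") == digest:
                log.info("geometry %d: loaded from %s", seed, cache)
                geoms.append(_geometry_from_json(d))
                continue
        try:
            g = run_geometry(cfg, i, D)
        except propagation.SimulationError as exc:
            log.error("geometry %d failed: %s", seed, exc)
            g = GeometryResult(seed, False, "error", None, None, None, None)
        d = _geometry_to_json(g)
        d["_digest"] = digest
        with open(cache, "w") as f:
            json.dump(d, f, indent=1, sort_keys=True)
        geoms.append(g)

    # study-level tables and statistics
    all_trials = [t for g in geoms for t in g.trials]
    trials_df = None
    outcome_table = None
    study_stats: dict = {"calibrated_D_mm2_ms": D, "achieved_cv_m_s": cv}
    if all_trials:
        base_by_key = {(g.seed, w): dur for g in geoms
                       for w, dur in g.baseline_termination_s.items()}
        trials_df = pd.DataFrame(
            [{"geometry_seed": t.meta.get("geometry_seed"),
              "window": t.window_index, "fraction": t.fraction,
              "outcome": t.outcome.label,
              "event_time_s": t.outcome.event_time_s,
              "af_baseline_duration_s": base_by_key.get(
                  (t.meta.get("geometry_seed"), t.window_index))}
             for t in all_trials])
        outcome_table = ablation.tabulate_outcomes(all_trials)
        collapsed = np.column_stack([
            outcome_table["AF_maintained"].to_numpy(),
            (outcome_table["AT_conversion"]
             + outcome_table["AF_terminated"]).to_numpy()])
        if collapsed.shape[0] >= 2:
            study_stats["outcome_chi2"], study_stats["outcome_p"] = \
                stats.chi_square_outcomes(collapsed)
    cov_rows = {g.seed: g.cov for g in geoms if g.cov is not None}
    cov_table = None
    if cov_rows:
        cov_table = pd.DataFrame.from_dict(
            cov_rows, orient="index",
            columns=[f"R{r}" for r in range(1, geometry.N_REGIONS + 1)])
        finite = cov_table.to_numpy()[np.isfinite(cov_table.to_numpy())]
        study_stats["mean_temporal_cov_pct"] = float(finite.mean()) \
            if len(finite) else None
        if cov_table.shape[0] >= 1:
            groups = [cov_table[c].to_numpy() for c in cov_table.columns]
            try:
                h, p = stats.kruskal_regions(groups)
                study_stats["kruskal_H"], study_stats["kruskal_p"] = h, p
            except ValueError:
                pass
            try:
                study_stats["group_ttest"] = stats.grouped_cov_ttest(cov_table)
            except ValueError:
                pass
    frieds = {g.seed: g.friedman for g in geoms if g.friedman is not None}
    study_stats["friedman_per_geometry"] = {
        str(k): [float(v[0]), float(v[1])] for k, v in frieds.items()}
    if frieds:
        study_stats["fraction_friedman_significant"] = float(
            np.mean([p < 0.05 for _, p in frieds.values()]))

    report = StudyReport(cfg, geoms, trials_df, outcome_table, cov_table,
                         study_stats)
    _persist(report, digest)
    return report


def _persist(report: StudyReport, digest: str) -> None:
    cfg = report.config
    out = cfg.out_dir
    artifacts = {"config": "config.json"}
    for g in report.geometries:
        if g.region_table is not None:
            fn = f"region_table_{g.seed}.csv"
            g.region_table.to_csv(os.path.join(out, fn),
                                  float_format=_FLOAT_FMT)
            artifacts[f"region_table_{g.seed}"] = fn
        artifacts[f"geometry_{g.seed}"] = f"geometry_{g.seed}.json"
    if report.trials_df is not None:
        report.trials_df.to_csv(os.path.join(out, "trials.csv"), index=False,
                                float_format=_FLOAT_FMT)
        artifacts["trials"] = "trials.csv"
    if report.outcome_table is not None:
        report.outcome_table.to_csv(os.path.join(out, "outcome_table.csv"),
                                    float_format=_FLOAT_FMT)
        artifacts["outcome_table"] = "outcome_table.csv"
    if report.cov_table is not None:
        report.cov_table.to_csv(os.path.join(out, "cov_table.csv"),
                                float_format=_FLOAT_FMT)
        artifacts["cov_table"] = "cov_table.csv"
    with open(os.path.join(out, "report.json"), "w") as f:
        json.dump(report.stats, f, indent=2, sort_keys=True, default=float)
    artifacts["report"] = "report.json"
    manifest = {"digest": digest, "artifacts": artifacts}
    with open(os.path.join(out, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
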