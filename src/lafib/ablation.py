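"""Virtual ablation of high-DF areas and outcome tabulation.

Ablation renders the targeted nodes non-conducting (zero flux with every
neighbor, ionic dynamics frozen), emulating transmural radiofrequency
lesions.  Trials branch independently from a saved checkpoint taken at the
end of a DF analysis window, follow the tissue for 30 s (configurable), and
classify the outcome: AF terminated (activity ceases), AF converted to
organized atrial tachycardia, or AF maintained.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cell import RemodelingParams, PRESETS
from .dfmap import DFMap, high_df_mask
from .geometry import SurfaceMesh
from .propagation import APRecording, DiffusionField, Simulator, TissueState
from .protocol import (TERMINATION_QUIET_MS, _QuietTracker, classify_rhythm)

__all__ = [
    "AblationOutcome", "AblationTrial", "apply_ablation",
    "run_ablation_trial", "follow_unablated", "tabulate_outcomes",
    "OUTCOME_LABELS",
]

OUTCOME_LABELS = ("AF_maintained", "AT_conversion", "AF_terminated")


@dataclass
class AblationOutcome:
    """Trial classification with the event time (s after ablation)."""

    label: str
    event_time_s: float | None = None

    def __post_init__(self):
        if self.label not in OUTCOME_LABELS:
            raise ValueError(f"unknown outcome label {self.label}")


@dataclass
class AblationTrial:
    """One independent (checkpoint, area-fraction) virtual-ablation trial."""

    fraction: float
    outcome: AblationOutcome
    window_index: int = -1
    mask: np.ndarray = None
    meta: dict = dc_field(default_factory=dict)


def apply_ablation(field: DiffusionField, mask: np.ndarray) -> DiffusionField:
    """Non-conduction condition on the masked nodes; the input is unmodified."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty ablation mask")
    if field.conducting is None:
        conducting = ~mask
    else:
        conducting = np.asarray(field.conducting, bool) & ~mask
    return DiffusionField(field.D, conducting, field.Cm)


def _follow(mesh: SurfaceMesh, field: DiffusionField,
            remodeling: RemodelingParams, checkpoint: TissueState,
            follow_ms: float, classify_seed: int,
            record_interval: float = 1.0,
            watch_mask: np.ndarray = None,
            ) -> tuple[str, float | None, float | None, int]:
    """Run follow-up from a checkpoint.

    Returns (final label, t_quiet_s, t_at_s, watched upstroke count).
    Termination is called after 200 ms of tissue-wide silence; the AT
    criterion is evaluated on sliding 2-s windows each second, and the final
    label comes from the last 2 s.  Times are relative to the checkpoint.
    ``watch_mask`` nodes (e.g. ablated ones) get their upstrokes counted.
    """
    from .protocol import upstroke_counts
    init = checkpoint.copy()
    t_start = init.t
    sim = Simulator(mesh, field, remodeling, record_interval, init=init)
    tracker = _QuietTracker(TERMINATION_QUIET_MS, record_interval)
    n_chunks = int(np.ceil(follow_ms / 1000.0))
    prev: APRecording | None = None
    first_at: float | None = None
    last_label = "AF"
    watched = 0
    conducting = sim.field.conducting
    for c in range(n_chunks):
        rec = sim.run(1000.0)
        if watch_mask is not None:
            watched += int(upstroke_counts(rec)[watch_mask].sum())
        if tracker.feed(rec.V[1:].max(axis=1), float(rec.times[0])):
            return ("AF_terminated",
                    (tracker.terminated_at - t_start) / 1000.0, first_at,
                    watched)
        if prev is not None:
            times = np.concatenate([prev.times[:-1], rec.times])
            V = np.vstack([prev.V[:-1], rec.V])
            two_s = APRecording(times, V, mesh, dict(rec.meta))
            label = classify_rhythm(two_s, (times[0], times[-1] + record_interval),
                                    conducting=conducting,
                                    seed=classify_seed).label
            last_label = label
            if label == "AT" and first_at is None:
                first_at = (float(times[-1]) - t_start) / 1000.0
        prev = rec
    return last_label, None, first_at, watched


def run_ablation_trial(mesh: SurfaceMesh, field: DiffusionField,
                       remodeling: RemodelingParams,
                       checkpoint: TissueState, df_map: DFMap,
                       fraction: float, follow_ms: float = 30000.0,
                       window_index: int = -1,
                       classify_seed: int = 0) -> AblationTrial:
    """Ablate the top-``fraction`` DF area at a window-end checkpoint.

    The trial resumes from the checkpoint with the high-DF mask of that
    window's DF map rendered non-conducting, follows ``follow_ms``, and
    classifies the result: AF_terminated if activity ceases (event time =
    onset of silence), AT_conversion if the final 2 s are organized (event
    time = first time the AT criterion held), else AF_maintained.
    """
    field = field.for_mesh(mesh)
    mask = high_df_mask(df_map, mesh.node_area, fraction,
                        conducting=field.conducting)
    ablated = apply_ablation(field, mask)
    label, t_quiet, t_at, abl_ups = _follow(mesh, ablated, remodeling,
                                            checkpoint, follow_ms,
                                            classify_seed, watch_mask=mask)
    if label == "AF_terminated":
        outcome = AblationOutcome("AF_terminated", t_quiet)
    elif label == "AT":
        outcome = AblationOutcome("AT_conversion", t_at)
    else:
        outcome = AblationOutcome("AF_maintained", None)
    return AblationTrial(fraction=fraction, outcome=outcome,
                         window_index=window_index, mask=mask,
                         meta={"follow_ms": follow_ms,
                               "ablated_upstrokes": abl_ups})


def follow_unablated(mesh: SurfaceMesh, field: DiffusionField,
                     remodeling: RemodelingParams, checkpoint: TissueState,
                     follow_ms: float = 30000.0,
                     classify_seed: int = 0) -> float | None:
    """Baseline continuation: time (s) to spontaneous termination, or None.

    Run from the same checkpoint without ablation, for the comparison of
    baseline AF duration between trials that did and did not terminate.
    """
    label, t_quiet, _, _ = _follow(mesh, field.for_mesh(mesh), remodeling,
                                   checkpoint, follow_ms, classify_seed)
    return t_quiet if label == "AF_terminated" else None


def tabulate_outcomes(trials) -> pd.DataFrame:
    """Fraction x outcome contingency table with per-fraction rates.

    Rows are ablation fractions; columns the three outcome counts, their
    percentages, and ``changed_or_terminated_pct`` =
    100 * (AT_conversion + AF_terminated) / total.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to tabulate")
    fracs = sorted({t.fraction for t in trials})
    rows = []
    for f in fracs:
        sub = [t for t in trials if t.fraction == f]
        n = len(sub)
        counts = {lab: sum(1 for t in sub if t.outcome.label == lab)
                  for lab in OUTCOME_LABELS}
        row = {"fraction": f, "n": n}
        for lab in OUTCOME_LABELS:
            row[lab] = counts[lab]
            row[f"{lab}_pct"] = 100.0 * counts[lab] / n
        row["changed_or_terminated_pct"] = (
            100.0 * (counts["AT_conversion"] + counts["AF_terminated"]) / n)
        rows.append(row)
    return pd.DataFrame(rows).set_index("fraction")
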