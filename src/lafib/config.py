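"""Study configuration: serializable description of a full scaled-down run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .cell import PRESETS
from .dfmap import AnalysisWindows, DEFAULT_BAND


@dataclass
class StudyConfig:
    """Everything a study run depends on; (config, seed) fixes every output.

    The desk-scale defaults are deliberately small; ``full_scale=True``
    restores the study-grade schedule (nine 6-s DF windows at 30-s intervals
    and 30-s post-ablation follow-ups), which is hours of compute.
    """

    n_geometries: int = 3
    global_seed: int = 1
    edge_mm: float = 2.0
    geometry_overrides: dict = field(default_factory=dict)
    cv_target_m_s: float = 0.4
    remodeling_preset: str = "af_calibrated"
    beats_per_cl: int = 8
    induction_mode: str = "auto"        # "ramp" | "reentrant" | "auto"
    n_windows: int = 3
    window_length_ms: float = 3000.0
    window_start_ms: float = 1000.0
    df_band_hz: tuple = DEFAULT_BAND
    fractions: tuple = (0.10, 0.15, 0.20)
    follow_ms: float = 6000.0
    baseline_follow: bool = True
    out_dir: str = "lafib_study"
    export_vtk: bool = False
    full_scale: bool = False

    def __post_init__(self):
        self.df_band_hz = tuple(self.df_band_hz)
        self.fractions = tuple(self.fractions)
        if self.remodeling_preset not in PRESETS:
            raise ValueError(f"unknown remodeling preset {self.remodeling_preset}")
        if self.induction_mode not in ("ramp", "reentrant", "auto"):
            raise ValueError("induction_mode must be ramp, reentrant or auto")
        if self.full_scale:
            self.n_windows = 9
            self.window_length_ms = 6000.0
            self.window_start_ms = 30000.0
            self.follow_ms = 30000.0
        for name in ("window_length_ms", "window_start_ms"):
            v = getattr(self, name)
            if abs(v / 1000.0 - round(v / 1000.0)) > 1e-9:
                raise ValueError(f"{name} must be a whole number of seconds")
        if not all(0 < f < 1 for f in self.fractions):
            raise ValueError("ablation fractions must be in (0, 1)")

    def windows(self) -> AnalysisWindows:
        if self.full_scale:
            return AnalysisWindows.full_schedule()
        L = self.window_length_ms
        t0 = self.window_start_ms
        return AnalysisWindows(tuple((t0 + k * L, t0 + (k + 1) * L)
                                     for k in range(self.n_windows)))

    def geometry_seed(self, index: int) -> int:
        return int(self.global_seed + index)

    # -- serialization -------------------------------------------------------

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["df_band_hz"] = list(self.df_band_hz)
        d["fractions"] = list(self.fractions)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "StudyConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        return cls(**d)

    def __eq__(self, other):
        if not isinstance(other, StudyConfig):
            return NotImplemented
        return dataclasses.asdict(self) == dataclasses.asdict(other)
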