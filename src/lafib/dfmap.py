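"""Dominant-frequency (DF) mapping and high-DF-area extraction.

Per node, the DF of an analysis window is the frequency of the highest peak
of the power spectrum of the virtual action potential (mean-removed,
Hann-windowed periodogram), searched within a physiologic band (default
1-20 Hz).  The "high DF area" is the top fraction of conducting tissue
*area* ranked by nodal DF (ties broken deterministically), and regional
proportions report, per LA section, the percentage of the section's area
covered by the high-DF mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .geometry import SurfaceMesh, N_REGIONS
from .propagation import APRecording

__all__ = [
    "AnalysisWindows", "DFMap", "power_spectrum", "dominant_frequency",
    "compute_df_map", "high_df_mask", "regional_proportions",
    "high_df_region_table", "DEFAULT_BAND", "MIN_PTP_MV",
]

#: DF search band (Hz): excludes DC leakage; upper bound well above AF rates.
DEFAULT_BAND = (1.0, 20.0)

#: Peak-to-peak voltage (mV) below which a node is considered silent in the
#: window and carries the undefined-DF sentinel (NaN).
MIN_PTP_MV = 5.0


@dataclass(frozen=True)
class AnalysisWindows:
    """Non-overlapping, equal-length DF analysis windows [(t0, t1), ...] ms."""

    windows: tuple

    def __post_init__(self):
        w = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", w)
        if not w:
            raise ValueError("at least one window required")
        lengths = {round(b - a, 6) for a, b in w}
        if len(lengths) != 1 or min(lengths) <= 0:
            raise ValueError("windows must have equal positive length")
        for (a0, b0), (a1, _) in zip(w, w[1:]):
            if a1 < b0:
                raise ValueError("windows must be non-overlapping and ordered")

    @classmethod
    def full_schedule(cls, n_windows: int = 9, length_ms: float = 6000.0,
                       every_ms: float = 30000.0) -> "AnalysisWindows":
        """Full-scale schedule: T1-T9, 6-s windows every 30 s of AF."""
        return cls(tuple((k * every_ms, k * every_ms + length_ms)
                         for k in range(1, n_windows + 1)))

    @property
    def length_ms(self) -> float:
        a, b = self.windows[0]
        return b - a

    @property
    def resolution_hz(self) -> float:
        return 1000.0 / self.length_ms

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass
class DFMap:
    """Per-node dominant frequency (Hz) for one analysis window.

    Silent nodes carry NaN and are never selected into high-DF masks.
    """

    df: np.ndarray             # (n,) Hz, NaN = undefined
    window: tuple              # (t0, t1) ms
    resolution_hz: float
    peak_power: np.ndarray = None

    @property
    def n_defined(self) -> int:
        return int(np.sum(np.isfinite(self.df)))


def power_spectrum(trace: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed Hann-windowed periodogram.  ``fs`` in Hz.

    Returns (frequencies Hz, power) with grid spacing 1/duration.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if len(trace) < 2 * fs:
        raise ValueError("need at least 2 s of data for a spectrum")
    freqs, pxx = periodogram(trace, fs=fs, window="hann", detrend="constant")
    return freqs, pxx


def dominant_frequency(trace: np.ndarray, fs: float,
                       band: tuple = DEFAULT_BAND,
                       min_ptp: float = MIN_PTP_MV) -> float:
    """Frequency (Hz) of the highest spectral peak within ``band``.

    Ties break toward the lower frequency.  Returns NaN for silent traces
    (peak-to-peak < ``min_ptp``) or when the band holds no power.
    """
    f_lo, f_hi = band
    if f_hi > fs / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) < min_ptp:
        return float("nan")
    freqs, pxx = power_spectrum(trace, fs)
    sel = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if not np.any(sel) or pxx[sel].max() <= 0:
        return float("nan")
    return float(freqs[sel][int(np.argmax(pxx[sel]))])


def compute_df_map(rec: APRecording, window: tuple,
                   band: tuple = DEFAULT_BAND,
                   conducting: np.ndarray = None,
                   min_ptp: float = MIN_PTP_MV) -> DFMap:
    """One DF per conducting node over ``window`` = (t0, t1) ms."""
    sub = rec.window(*window)
    fs = sub.fs * 1000.0  # kHz -> Hz
    V = sub.V.astype(float)
    n = V.shape[1]
    f_lo, f_hi = band
    freqs, _ = power_spectrum(V[:, 0], fs)
    sel = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    # vectorized periodogram across nodes
    _, pxx = periodogram(V, fs=fs, window="hann", detrend="constant", axis=0)
    pk = np.argmax(pxx[sel], axis=0)
    df = freqs[sel][pk]
    peak_power = pxx[sel][pk, np.arange(n)]
    silent = np.ptp(V, axis=0) < min_ptp
    df = np.where(silent | (peak_power <= 0), np.nan, df)
    if conducting is not None:
        df = np.where(conducting, df, np.nan)
    res = 1000.0 / (window[1] - window[0])
    return DFMap(df=df, window=tuple(window), resolution_hz=res,
                 peak_power=peak_power)


def high_df_mask(df_map: DFMap | np.ndarray, node_areas: np.ndarray,
                 fraction: float, conducting: np.ndarray = None) -> np.ndarray:
    """Boolean mask of the highest-DF tissue covering ``fraction`` of area.

    Nodes are ranked by DF descending (ties by node index ascending) and
    selected greedily until the cumulative lumped node area first reaches
    ``fraction`` times the total conducting area.  Undefined-DF nodes are
    never selected.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    df = df_map.df if isinstance(df_map, DFMap) else np.asarray(df_map, float)
    node_areas = np.asarray(node_areas, float)
    eligible = np.isfinite(df)
    if conducting is not None:
        eligible &= conducting
    if not np.any(eligible):
        raise ValueError("all-sentinel DF map: no eligible node")
    total = node_areas[eligible].sum() if conducting is None \
        else node_areas[conducting].sum()
    target = fraction * total
    idx = np.nonzero(eligible)[0]
    # sort by (-df, index): lexsort with last key primary
    order = idx[np.lexsort((idx, -df[idx]))]
    csum = np.cumsum(node_areas[order])
    k = int(np.searchsorted(csum, target - 1e-12)) + 1
    k = min(k, len(order))
    mask = np.zeros(len(df), dtype=bool)
    mask[order[:k]] = True
    return mask


def regional_proportions(mask: np.ndarray, region: np.ndarray,
                         node_areas: np.ndarray) -> np.ndarray:
    """Per-section percentage: 100 * (high-DF area in section) / (section area).

    Returns a length-10 array indexed R1..R10.
    """
    out = np.empty(N_REGIONS)
    for r in range(1, N_REGIONS + 1):
        in_r = region == r
        area = node_areas[in_r].sum()
        if area <= 0:
            raise ValueError(f"zero-area region R{r}")
        out[r - 1] = 100.0 * node_areas[in_r & mask].sum() / area
    return out


def high_df_region_table(df_maps: list, mesh: SurfaceMesh, fraction: float = 0.10,
                         conducting: np.ndarray = None) -> pd.DataFrame:
    """Windows x regions table of % High DF Area (rows T1.., columns R1..R10)."""
    rows = {}
    for k, dm in enumerate(df_maps, start=1):
        mask = high_df_mask(dm, mesh.node_area, fraction, conducting)
        rows[f"T{k}"] = regional_proportions(mask, mesh.region, mesh.node_area)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"R{r}" for r in range(1, N_REGIONS + 1)])
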