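"""Dominant-frequency mapping: spectra, argmax, high-DF masks, proportions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lafib import dfmap
from lafib.dfmap import AnalysisWindows, DFMap
from lafib.propagation import APRecording


def sine(freq, fs=1000.0, seconds=6.0, amp=20.0):
    t = np.arange(0, seconds, 1.0 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


class TestPowerSpectrum:
    def test_pure_tone_peak(self):
        f, p = dfmap.power_spectrum(sine(5.0), 1000.0)
        assert f[np.argmax(p)] == pytest.approx(5.0, abs=1e-9)

    def test_constant_signal_no_power(self):
        f, p = dfmap.power_spectrum(np.full(6000, 3.0), 1000.0)
        assert np.allclose(p, 0.0)

    def test_dominant_amplitude_wins(self):
        sig = sine(4.0, amp=2.0) + sine(7.0, amp=1.0)
        f, p = dfmap.power_spectrum(sig, 1000.0)
        assert f[np.argmax(p)] == pytest.approx(4.0, abs=1e-9)

    def test_grid_spacing_is_inverse_duration(self):
        f, _ = dfmap.power_spectrum(sine(5.0, seconds=6.0), 1000.0)
        assert f[1] - f[0] == pytest.approx(1.0 / 6.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            dfmap.power_spectrum(np.zeros(500), 1000.0)


class TestDominantFrequency:
    def test_pulse_train_fundamental(self):
        # 200-ms period pulse train over 6 s -> 5 Hz fundamental
        t = np.arange(0, 6.0, 0.001)
        sig = np.where((t % 0.2) < 0.05, 20.0, -80.0)
        assert dfmap.dominant_frequency(sig, 1000.0) == pytest.approx(5.0)

    def test_sine_tone(self):
        assert dfmap.dominant_frequency(sine(5.0), 1000.0) == pytest.approx(5.0)

    def test_silent_trace_sentinel(self):
        assert np.isnan(dfmap.dominant_frequency(np.zeros(6000), 1000.0))

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dfmap.dominant_frequency(sine(5.0), 30.0, band=(1.0, 20.0))

    def test_matches_bruteforce_argmax_on_random_signals(self):
        """100 random multi-tone signals: band search == global argmax."""
        rng = np.random.default_rng(42)
        fs = 200.0
        for _ in range(100):
            n_tones = rng.integers(1, 5)
            freqs = rng.uniform(1.5, 19.5, n_tones)
            amps = rng.uniform(0.5, 5.0, n_tones)
            amps[rng.integers(n_tones)] += 5.0  # unambiguous peak
            t = np.arange(0, 4.0, 1.0 / fs)
            sig = sum(a * np.sin(2 * np.pi * f * t + rng.uniform(0, 6))
                      for a, f in zip(amps, freqs))
            sig = sig + 10.0  # DC offset removed by detrending
            got = dfmap.dominant_frequency(sig, fs, min_ptp=0.0)
            f_all, p_all = dfmap.power_spectrum(sig, fs)
            expect = f_all[np.argmax(p_all)]
            if 1.0 <= expect <= 20.0:
                assert got == pytest.approx(expect, abs=1e-12)


class TestAnalysisWindows:
    def test_full_schedule(self):
        w = AnalysisWindows.full_schedule()
        assert len(w) == 9
        assert w.windows[0] == (30000.0, 36000.0)
        assert w.windows[-1] == (270000.0, 276000.0)
        assert w.resolution_hz == pytest.approx(1.0 / 6.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindows(((0.0, 2000.0), (1000.0, 3000.0)))

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindows(((0.0, 2000.0), (2000.0, 5000.0)))


def _recording(n_nodes, seconds, fn):
    t = np.arange(0, seconds * 1000.0, 1.0)
    V = np.stack([fn(i, t / 1000.0) for i in range(n_nodes)], axis=1)
    return APRecording(t, V.astype(np.float32))


class TestComputeDFMap:
    def test_nodewise_tones(self):
        rec = _recording(5, 4.0, lambda i, ts: 20 * np.sin(
            2 * np.pi * (3.0 + i) * ts))
        dm = dfmap.compute_df_map(rec, (0.0, 4000.0))
        np.testing.assert_allclose(dm.df, [3, 4, 5, 6, 7], atol=1e-9)

    def test_window_outside_recording(self):
        rec = _recording(2, 3.0, lambda i, ts: 20 * np.sin(2 * np.pi * 4 * ts))
        with pytest.raises(ValueError, match="outside"):
            dfmap.compute_df_map(rec, (5000.0, 8000.0))

    def test_silent_node_carries_sentinel(self):
        rec = _recording(3, 4.0, lambda i, ts: np.zeros_like(ts) if i == 1
                         else 20 * np.sin(2 * np.pi * 4 * ts))
        dm = dfmap.compute_df_map(rec, (0.0, 4000.0))
        assert np.isnan(dm.df[1])
        assert dm.n_defined == 2

    def test_stationary_rhythm_identical_windows(self, paced_sheet_recordings):
        rec = paced_sheet_recordings[250.0]
        a = dfmap.compute_df_map(rec, (1000.0, 3000.0))
        b = dfmap.compute_df_map(rec, (3000.0, 5000.0))
        np.testing.assert_array_equal(a.df, b.df)


class TestHighDFMask:
    def test_clear_separation(self):
        df = np.where(np.arange(100) < 10, 8.0, 5.0)
        mask = dfmap.high_df_mask(df, np.ones(100), 0.10)
        assert mask[:10].all() and not mask[10:].any()

    def test_uniform_map_tie_break_lowest_index(self):
        mask = dfmap.high_df_mask(np.full(50, 6.0), np.ones(50), 0.10)
        assert mask[:5].all() and not mask[5:].any()

    def test_area_within_one_granule(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(0.5, 2.0, 400)
        df = rng.uniform(2, 9, 400)
        for frac in (0.10, 0.15, 0.20):
            mask = dfmap.high_df_mask(df, areas, frac)
            sel = areas[mask].sum()
            target = frac * areas.sum()
            assert sel >= target - 1e-9
            assert sel - target <= areas.max() + 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    def test_nesting_10_15_20(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        df = rng.uniform(2, 9, n)
        areas = rng.uniform(0.5, 2.0, n)
        m10 = dfmap.high_df_mask(df, areas, 0.10)
        m15 = dfmap.high_df_mask(df, areas, 0.15)
        m20 = dfmap.high_df_mask(df, areas, 0.20)
        assert not np.any(m10 & ~m15)
        assert not np.any(m15 & ~m20)

    def test_sentinel_nodes_never_selected(self):
        df = np.array([np.nan, 8.0, 7.0, np.nan, 6.0])
        mask = dfmap.high_df_mask(df, np.ones(5), 0.4)
        assert not mask[0] and not mask[3]

    def test_all_sentinel_rejected(self):
        with pytest.raises(ValueError, match="sentinel"):
            dfmap.high_df_mask(np.full(4, np.nan), np.ones(4), 0.1)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            dfmap.high_df_mask(np.ones(4), np.ones(4), 1.2)


class TestRegionalProportions:
    def _mesh_like(self):
        region = np.repeat(np.arange(1, 11), 10).astype(np.int16)
        areas = np.ones(100)
        return region, areas

    def test_mask_confined_to_one_region(self):
        region, areas = self._mesh_like()
        mask = region == 6
        props = dfmap.regional_proportions(mask, region, areas)
        assert props[5] == pytest.approx(100.0)
        assert np.sum(props) == pytest.approx(100.0)

    def test_full_mask_everywhere_100(self):
        region, areas = self._mesh_like()
        props = dfmap.regional_proportions(np.ones(100, bool), region, areas)
        np.testing.assert_allclose(props, 100.0)

    def test_area_identity(self):
        rng = np.random.default_rng(1)
        region, _ = self._mesh_like()
        areas = rng.uniform(0.5, 2.0, 100)
        mask = rng.random(100) < 0.3
        props = dfmap.regional_proportions(mask, region, areas)
        total = sum(props[r - 1] / 100.0 * areas[region == r].sum()
                    for r in range(1, 11))
        assert total == pytest.approx(areas[mask].sum(), rel=1e-9)

    def test_zero_area_region_rejected(self):
        region = np.ones(10, dtype=np.int16)  # only R1 present
        with pytest.raises(ValueError, match="zero-area"):
            dfmap.regional_proportions(np.zeros(10, bool), region, np.ones(10))


def test_high_df_region_table_shape(paced_sheet_recordings):
    rec = paced_sheet_recordings[250.0]
    maps = [dfmap.compute_df_map(rec, (1000.0, 3000.0))]
    mesh = rec.mesh.copy()
    # give the sheet a fake 10-section labeling
    mesh.region = (np.arange(mesh.n_nodes) % 10 + 1).astype(np.int16)
    table = dfmap.high_df_region_table(maps, mesh, 0.10)
    assert table.shape == (1, 10)
    assert ((table.values >= 0) & (table.values <= 100)).all()
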