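"""Filtering, Teager-Kaiser energy, onset detection, and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from graspdecode.preprocess import (
    FilterSpec,
    WindowSpec,
    bandpass,
    detect_onset,
    filter_recording,
    labels_from_fsr,
    n_windows,
    segment,
    segment_array,
    tke,
    window_labels,
)

FS = 1000.0


def analytic_gain(freq: float, spec: FilterSpec = FilterSpec()) -> float:
    """Magnitude response of the Butterworth band-pass at one frequency."""
    sos = sp_signal.butter(spec.order, spec.band, btype="bandpass", fs=FS, output="sos")
    _, h = sp_signal.sosfreqz(sos, worN=[freq], fs=FS)
    gain = np.abs(h[0])
    return gain**2 if spec.mode == "zero-phase" else gain


class TestBandpass:
    def test_dc_is_rejected(self):
        y = bandpass(np.full(4000, 7.0))
        mid = y[1000:3000]
        assert np.max(np.abs(mid)) < 1e-6 * 7.0

    @pytest.mark.parametrize(
        "freq, expected_band",
        [(100.0, (0.99, 1.01)), (5.0, (0.0, 0.05))],
    )
    def test_tone_steady_state_matches_analytic_response(self, freq, expected_band):
        t = np.arange(int(4 * FS)) / FS
        y = bandpass(np.sin(2 * np.pi * freq * t))
        # sqrt(2) * RMS estimates the amplitude without sampling-grid bias
        amplitude = np.sqrt(2) * np.sqrt(np.mean(y[1500:3500] ** 2))
        lo, hi = expected_band
        assert lo <= amplitude <= hi
        assert amplitude == pytest.approx(analytic_gain(freq), rel=0.01)

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 2000))
        a, b = 2.5, -0.7
        combined = bandpass(a * x + b * y)
        separate = a * bandpass(x) + b * bandpass(y)
        np.testing.assert_allclose(combined, separate, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(1000), FilterSpec(band=(20.0, 600.0)), FS)

    def test_causal_mode_differs_from_zero_phase(self, rng):
        x = rng.standard_normal(2000)
        causal = bandpass(x, FilterSpec(mode="causal"))
        zero_phase = bandpass(x, FilterSpec(mode="zero-phase"))
        assert not np.allclose(causal, zero_phase)


class TestTke:
    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(1000):
            x = rng.standard_normal(rng.integers(3, 40))
            expected = np.array(
                [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)]
            )
            got = tke(x)
            # agreement to machine precision (vectorization may differ by 1 ulp)
            np.testing.assert_allclose(got[1:-1], expected, rtol=1e-13, atol=1e-15)
            assert got[0] == got[1] and got[-1] == got[-2]

    def test_constant_series_has_zero_energy(self):
        assert np.all(tke(np.full(50, 3.3)) == 0.0)

    def test_sinusoid_energy_is_constant_amplitude_squared_sine_squared(self):
        x = np.sin(0.3 * np.arange(100))
        psi = tke(x)
        np.testing.assert_allclose(psi[1:-1], np.sin(0.3) ** 2, atol=1e-12)
        assert psi[1] == pytest.approx(0.08733, abs=5e-6)

    def test_unit_impulse(self):
        assert tke(np.array([0.0, 1.0, 0.0]))[1] == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            tke(np.array([1.0, 2.0]))


class TestDetectOnset:
    def test_clean_step_detected_at_crossing(self):
        series = np.concatenate([np.zeros(1000), np.full(1000, 10.0)])
        assert detect_onset(series, FS) == [(1000, 2000)]

    def test_flat_series_yields_nothing(self):
        assert detect_onset(np.zeros(3000), FS) == []

    def test_short_blips_are_debounced(self):
        series = np.zeros(3000)
        series[1500:1520] = 5.0  # 20 ms < 50 ms debounce
        assert detect_onset(series, FS) == []

    def test_nearby_runs_are_merged(self):
        series = np.zeros(3000)
        series[1500:1600] = 5.0
        series[1630:1730] = 5.0  # 30 ms gap < 50 ms
        assert detect_onset(series, FS) == [(1500, 1730)]

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_with_zero_mean_baseline(self, scale):
        rng = np.random.default_rng(7)
        series = rng.standard_normal(1500)
        series -= series[:1000].mean()  # zero-mean baseline: threshold scales
        series[1200:1400] += 50.0
        assert detect_onset(series * scale, FS) == detect_onset(series, FS)

    def test_fsr_onset_matches_simulated_contact(self, short_session):
        runs = detect_onset(short_session.fsr, FS)
        assert len(runs) == len(short_session.contact_intervals)
        for (on, off), (true_on, true_off) in zip(runs, short_session.contact_intervals):
            assert abs(on - true_on) <= 60
            assert abs(off - true_off) <= 60


class TestLabelsFromFsr:
    def test_flat_fsr_gives_all_rest(self):
        assert np.all(labels_from_fsr(np.zeros(3000), 4, FS) == 0)

    def test_single_step_gives_one_contiguous_run(self):
        fsr = np.concatenate([np.zeros(1200), np.full(800, 1.0), np.zeros(1000)])
        labels = labels_from_fsr(fsr, 5, FS)
        changes = np.flatnonzero(np.diff(labels))
        assert len(changes) == 2
        assert set(labels) == {0, 5}

    def test_session_runs_overlap_true_intervals(self, full_session):
        labels = full_session.labels
        edges = np.flatnonzero(np.diff(np.concatenate(([0], (labels > 0).astype(int), [0]))))
        runs = edges.reshape(-1, 2)
        assert len(runs) == 30
        for (on, off), (true_on, true_off) in zip(runs, full_session.contact_intervals):
            overlap = max(0, min(off, true_off) - max(on, true_on))
            assert overlap / (true_off - true_on) >= 0.95

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            labels_from_fsr(np.zeros(2000), 7, FS)


class TestSegment:
    def test_window_count_examples(self):
        assert n_windows(1000, 100, 50) == 19
        assert n_windows(1000, 100, 100) == 10

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(min_value=100, max_value=5000),
        length=st.integers(min_value=10, max_value=400),
        step=st.integers(min_value=1, max_value=400),
    )
    def test_window_count_formula(self, n, length, step):
        if step > length or n < length:
            return
        data = np.zeros((2, n))
        windows, _, _ = segment_array(data, np.zeros(n, dtype=int), WindowSpec(length, step), FS)
        assert windows.shape[0] == (n - length) // step + 1

    def test_recording_windows_are_10_by_100(self, short_session):
        windows, ts, labels = segment(short_session, WindowSpec(100.0, 50.0))
        assert windows.shape[1:] == (10, 100)
        assert len(ts) == len(labels) == windows.shape[0]
        np.testing.assert_array_equal(np.diff(ts), 50.0)
        # EMG stacked above FMG
        np.testing.assert_array_equal(windows[0, :5], short_session.emg[:, :100])
        np.testing.assert_array_equal(windows[0, 5:], short_session.fmg[:, :100])

    def test_majority_label_with_grasp_tiebreak(self):
        labels = np.array([0] * 50 + [3] * 50)
        assert window_labels(labels, 100, 100)[0] == 3  # tie -> grasp
        labels = np.array([0] * 51 + [3] * 49)
        assert window_labels(labels, 100, 100)[0] == 0

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            segment_array(np.zeros((2, 50)), np.zeros(50, dtype=int), WindowSpec(100.0, 50.0), FS)


def test_filter_recording_modes(short_session):
    both = filter_recording(short_session)
    fmg_kept = filter_recording(short_session, filter_fmg=False)
    assert not np.allclose(both.fmg, short_session.fmg)
    np.testing.assert_array_equal(fmg_kept.fmg, short_session.fmg)
    # labels and FSR untouched either way
    np.testing.assert_array_equal(both.labels, short_session.labels)
    np.testing.assert_array_equal(both.fsr, short_session.fsr)
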