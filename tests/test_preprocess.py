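"""Wiener denoising, normalization, false-peak elimination, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import toeplitz

import cardiopyramid as cp
from cardiopyramid.preprocess import (
    FalsePeakConfig,
    NormalizationConfig,
    SegmentationConfig,
    WienerConfig,
    estimate_noise_variance,
    wiener_taps,
)
from cardiopyramid.records import SignalRecord
from cardiopyramid.synthetic import murmur_band_power


def _ar1(n, a=0.9, seed=0):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = a * x[i - 1] + e[i]
    return x, rng


class TestWiener:
    def test_noiseless_identity_taps(self):
        """With zero noise the Wiener-Hopf solution is the identity tap e0."""
        r = np.array([2.0, 1.2, 0.7, 0.3])
        taps = wiener_taps(r, r)
        e0 = np.zeros(4)
        e0[0] = 1.0
        np.testing.assert_allclose(taps, e0, atol=1e-12)

    def test_noiseless_signal_passthrough(self):
        # a linear ramp has constant first differences, so the MAD noise
        # estimate is exactly zero and the filter must be the identity
        x = np.linspace(0.0, 5.0, 4000)
        assert estimate_noise_variance(x) == 0.0
        y, taps = cp.wiener_filter(x, WienerConfig(order_p=8), return_taps=True)
        np.testing.assert_allclose(taps, np.eye(8)[0], atol=1e-9)
        np.testing.assert_allclose(y, x, atol=1e-8)

    def test_worked_2x2_solve(self):
        """r_xx=(2,1), sigma^2=1: [[2,1],[1,2]] psi = (1,1) => psi=(1/3,1/3)."""
        taps = wiener_taps(np.array([2.0, 1.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(taps, [1 / 3, 1 / 3], rtol=1e-12)

    def test_toeplitz_residual(self, rng):
        """Taps always satisfy the stated system to tiny residual."""
        for _ in range(20):
            r = rng.standard_normal(8)
            r[0] = np.abs(r[0]) + 8.0  # diagonally dominant -> well-posed
            rhs = rng.standard_normal(8)
            taps = wiener_taps(r, rhs)
            assert np.max(np.abs(toeplitz(r) @ taps - rhs)) < 1e-8

    def test_mse_reduction_ar1(self):
        """Denoising beats doing nothing on AR(1)+white noise, most seeds."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            clean, rng = _ar1(20000, a=0.9, seed=seed)
            noise = rng.standard_normal(clean.size) * clean.std()  # 0 dB SNR
            noisy = clean + noise
            den = cp.wiener_filter(noisy, WienerConfig(order_p=32))
            if np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2):
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_frame_based_variant_runs(self):
        clean, rng = _ar1(12000, seed=1)
        noisy = clean + rng.standard_normal(clean.size)
        out = cp.wiener_filter(noisy, WienerConfig(order_p=16, frame_len=4000))
        assert out.shape == noisy.shape
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_reference_segment_noise_model(self):
        clean, rng = _ar1(16000, seed=2)
        noise = rng.standard_normal(clean.size)
        noisy = clean + noise
        noisy[:2000] = noise[:2000]  # marked noise-only stretch
        cfg = WienerConfig(order_p=16, noise_model="reference_segment", noise_segment=(0, 2000))
        out = cp.wiener_filter(noisy, cfg)
        tail = slice(2000, None)
        assert np.mean((out[tail] - clean[tail]) ** 2) < np.mean((noisy[tail] - clean[tail]) ** 2)

    def test_too_short_input(self):
        with pytest.raises(ValueError, match="short"):
            cp.wiener_filter(np.zeros(100), WienerConfig(order_p=32))

    def test_bad_config(self):
        with pytest.raises(ValueError):
            WienerConfig(order_p=0)
        with pytest.raises(ValueError):
            WienerConfig(order_p=32, frame_len=10)


class TestMinMaxNormalize:
    def test_endpoints_forced(self):
        np.testing.assert_allclose(cp.minmax_normalize(np.array([0.0, 5.0, 10.0])), [0, 0.5, 1])

    def test_linearity_to_other_range(self):
        got = cp.minmax_normalize(np.array([2.0, 4.0, 6.0]), NormalizationConfig(0.0, 10.0))
        np.testing.assert_allclose(got, [0, 5, 10])

    def test_idempotent_on_unit_range(self, rng):
        x = rng.standard_normal(200)
        once = cp.minmax_normalize(x)
        twice = cp.minmax_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_input_guarded(self, caplog):
        got = cp.minmax_normalize(np.full(5, 3.0), NormalizationConfig(-1.0, 1.0))
        np.testing.assert_array_equal(got, np.full(5, -1.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(lambda v: max(v) > min(v)))
    def test_output_range_exact(self, values):
        out = cp.minmax_normalize(np.array(values))
        assert out.min() == 0.0 and out.max() == 1.0


class TestFalsePeakElimination:
    def test_clean_ecg_unchanged(self, clean_ecg_30s):
        cleaned, peaks = cp.false_peak_elimination(clean_ecg_30s.samples, 2000.0, "ECG")
        assert peaks.n_false == 0
        np.testing.assert_array_equal(cleaned, clean_ecg_30s.samples)

    def test_injected_spikes_removed_r_peaks_kept(self, clean_ecg_30s):
        """>= 9/10 injected 5x-amplitude spikes flagged; >= 95% R peaks kept."""
        fs = 2000.0
        x = clean_ecg_30s.samples.copy()
        r_peaks = clean_ecg_30s.meta["r_peaks"]
        rng = np.random.default_rng(21)
        amp = 5.0 * np.abs(x).max()
        width = 8  # 4 ms
        spike_pos = []
        while len(spike_pos) < 10:
            p = int(rng.integers(1000, x.size - 1000))
            if np.min(np.abs(r_peaks - p)) > 400 and all(abs(p - q) > 800 for q in spike_pos):
                spike_pos.append(p)
                k = np.arange(p - 2 * width, p + 2 * width + 1)
                x[k] += amp * np.exp(-0.5 * ((k - p) / width) ** 2)
        cleaned, peaks = cp.false_peak_elimination(x, fs, "ECG")
        flagged = peaks.indices[peaks.is_false]
        hit = sum(np.min(np.abs(flagged - p)) <= 50 for p in spike_pos) if flagged.size else 0
        assert hit >= 9
        kept = peaks.indices[~peaks.is_false]
        retained = sum(np.min(np.abs(kept - r)) <= 50 for r in r_peaks) if kept.size else 0
        assert retained >= 0.95 * r_peaks.size
        # spikes actually removed from the waveform
        for p in spike_pos:
            if flagged.size and np.min(np.abs(flagged - p)) <= 50:
                assert np.abs(cleaned[p - 50 : p + 50]).max() < 0.8 * amp

    def test_all_zero_signal(self):
        x = np.zeros(8000)
        cleaned, peaks = cp.false_peak_elimination(x, 2000.0, "ECG")
        assert peaks.indices.size == 0
        np.testing.assert_array_equal(cleaned, x)

    def test_locality_of_repair(self, clean_ecg_30s):
        """Samples further than 100 ms from any flagged peak are untouched."""
        fs = 2000.0
        x = clean_ecg_30s.samples.copy()
        p = 30000
        x[p - 8 : p + 9] += 5.0 * np.abs(x).max()
        cleaned, peaks = cp.false_peak_elimination(x, fs, "ECG")
        half = int(0.1 * fs)
        mask = np.ones(x.size, bool)
        for q in peaks.indices[peaks.is_false]:
            mask[max(q - half, 0) : q + half + 1] = False
        np.testing.assert_array_equal(cleaned[mask], x[mask])

    def test_too_short_input(self):
        with pytest.raises(ValueError, match="2 s"):
            cp.false_peak_elimination(np.zeros(100), 2000.0, "ECG")


class TestSegmentation:
    def test_table_extremes(self):
        """35.92-s positive -> 4 windows; 8.98-s negative -> 1 window."""
        fs = 2000.0
        pos = SignalRecord("p", "ECG", np.zeros(int(35.92 * fs)), fs, label="positive")
        neg = SignalRecord("n", "ECG", np.zeros(int(8.98 * fs)), fs, label="negative")
        assert cp.segment_signal(pos).n_segments == 4
        assert cp.segment_signal(neg).n_segments == 1

    def test_short_record_skipped(self):
        rec = SignalRecord("s", "ECG", np.zeros(1000), 2000.0, label="negative")
        arc = cp.segment_signal(rec)
        assert arc.n_segments == 0

    def test_provenance_and_content(self):
        fs = 100.0
        x = np.arange(int(20 * fs), dtype=float)
        rec = SignalRecord("r", "ECG", x, fs, label="negative")
        arc = cp.segment_signal(rec, SegmentationConfig(window_s=8, stride_negative_s=3))
        assert [p[1] for p in arc.provenance] == [0, 300, 600, 900, 1200]
        np.testing.assert_array_equal(arc.segments[2], x[600:1400])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        L=st.integers(800, 8000),
        stride=st.integers(50, 1200),
        positive=st.booleans(),
    )
    def test_count_matches_brute_force(self, L, stride, positive):
        """Window count equals brute-force enumeration of start positions."""
        fs = 100.0
        w = 800  # 8 s at 100 Hz
        label = "positive" if positive else "negative"
        cfg = SegmentationConfig(
            window_s=8.0, stride_positive_s=stride / fs, stride_negative_s=stride / fs
        )
        rec = SignalRecord("r", "ECG", np.zeros(L), fs, label=label)
        arc = cp.segment_signal(rec, cfg)
        brute = len([s for s in range(0, L, stride) if s + w <= L])
        assert arc.n_segments == brute


class TestChainPreservesClassSignal:
    def test_separability_survives_preprocessing(self, small_cohort):
        """The murmur-band power-fraction AUC moves < 10% through the chain."""
        from sklearn.metrics import roc_auc_score

        _, pairs, _ = small_cohort

        def frac(x):
            tot = float(np.mean(np.asarray(x, float) ** 2))
            return murmur_band_power(x, 2000.0) / tot if tot > 0 else 0.0

        y_raw = [p.label != "negative" for _, p in pairs]
        raw_auc = roc_auc_score(y_raw, [frac(p.samples) for _, p in pairs])
        archives = cp.archives_from_pairs(pairs)
        arc = archives["PCG"]
        post_auc = roc_auc_score(
            [l != "negative" for l in arc.labels],
            [frac(s.astype(float)) for s in arc.segments],
        )
        assert abs(post_auc - raw_auc) < 0.10 * raw_auc
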