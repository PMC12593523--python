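"""Synthetic cohort generator: morphology, determinism, class effects, noise."""

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.stats import poisson

import cardiopyramid as cp
from cardiopyramid.synthetic import murmur_band_power


class TestGenerateEcg:
    def test_r_peak_count_and_spacing(self):
        cfg = cp.SynthConfig(seed=1, heart_rate_bpm=(60.0, 0.0), rr_jitter_frac=0.0)
        rec = cp.generate_ecg(cfg, 0, duration_s=10.0)
        r = rec.meta["r_peaks"]
        assert r.size == 10
        assert np.all(np.abs(np.diff(r) - 2000) <= 1)
        # the R peaks really are local maxima of the waveform
        for p in r:
            assert rec.samples[p] == pytest.approx(rec.samples[p - 30 : p + 30].max(), rel=1e-3)

    def test_determinism(self):
        cfg = cp.SynthConfig(seed=42)
        a = cp.generate_ecg(cfg, 3, duration_s=12.0)
        b = cp.generate_ecg(cfg, 3, duration_s=12.0)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.meta["r_peaks"], b.meta["r_peaks"])

    def test_fundamental_at_heart_rate(self):
        cfg = cp.SynthConfig(seed=2, heart_rate_bpm=(60.0, 0.0), rr_jitter_frac=0.0)
        rec = cp.generate_ecg(cfg, 0, duration_s=60.0)
        spec = np.abs(np.fft.rfft(rec.samples - rec.samples.mean()))
        freqs = np.fft.rfftfreq(rec.n_samples, 1.0 / rec.fs)
        band = (freqs > 0.3) & (freqs < 3.0)
        assert freqs[band][np.argmax(spec[band])] == pytest.approx(1.0, abs=0.05)


class TestGeneratePcg:
    def test_burst_counts(self):
        cfg = cp.SynthConfig(seed=3, heart_rate_bpm=(60.0, 0.0), rr_jitter_frac=0.0)
        ecg = cp.generate_ecg(cfg, 0, duration_s=10.0)
        pcg = cp.generate_pcg(ecg, cfg, 0)
        assert pcg.meta["s1_times_s"].size == 10
        assert pcg.meta["s2_times_s"].size >= 9
        # envelope peaks: one S1 + one S2 per beat (last S2 may fall off the end)
        env = np.abs(pcg.samples)
        smooth = np.convolve(env, np.ones(80) / 80, mode="same")
        peaks, _ = find_peaks(smooth, height=0.3 * smooth.max(), distance=300)
        assert 18 <= peaks.size <= 21

    def test_missing_r_peaks_rejected(self):
        rec = cp.SignalRecord("x", "ECG", np.zeros(4000), 2000.0)
        with pytest.raises(ValueError, match="r_peaks"):
            cp.generate_pcg(rec, cp.SynthConfig(seed=0), 0)

    def test_negative_class_murmur_band_quiet(self):
        cfg = cp.SynthConfig(seed=4)
        ecg = cp.generate_ecg(cfg, 0, label="negative", duration_s=15.0)
        pcg = cp.generate_pcg(ecg, cfg, 0)
        fs = pcg.fs
        h = int(0.05 * fs)
        s1_mask = np.zeros(pcg.n_samples, bool)
        for p in ecg.meta["r_peaks"]:
            s1_mask[max(p - h, 0) : p + h] = True
        s1_power = np.mean(pcg.samples[s1_mask] ** 2)
        inter = murmur_band_power(pcg.samples[~s1_mask], fs)
        assert inter < 0.10 * s1_power

    def test_class_effect_size(self):
        """Murmur band power separates the classes with d > 2."""
        cfg = cp.SynthConfig(n_positive=25, n_negative=25, seed=9)
        pairs, _ = cp.generate_cohort(cfg, corrupt=False)
        pos = [murmur_band_power(p.samples, p.fs) for e, p in pairs if e.label != "negative"]
        neg = [murmur_band_power(p.samples, p.fs) for e, p in pairs if e.label == "negative"]
        pos, neg = np.array(pos), np.array(neg)
        d = (pos.mean() - neg.mean()) / np.sqrt(0.5 * (pos.var() + neg.var()))
        assert d > 2.0

    def test_separability_monotone_in_effect(self):
        """Band-power AUC increases with the murmur effect size."""
        from sklearn.metrics import roc_auc_score

        aucs = []
        for power in (0.0, 0.05, 0.5):
            cfg = cp.SynthConfig(
                n_positive=12, n_negative=12, seed=31, murmur_rel_power=power,
                white_snr_db=5.0,
            )
            pairs, _ = cp.generate_cohort(cfg)
            y = [p.label != "negative" for _, p in pairs]
            v = [murmur_band_power(p.samples, p.fs) for _, p in pairs]
            aucs.append(roc_auc_score(y, v))
        assert aucs[0] <= aucs[1] <= aucs[2]
        assert aucs[2] > 0.95


class TestCorruptSignal:
    def test_zero_noise_is_identity(self, clean_ecg_30s):
        cfg = cp.SynthConfig(
            seed=5, baseline_wander_amp=0.0, powerline_amp=0.0,
            white_snr_db=None, spike_rate_hz=0.0,
        )
        out = cp.corrupt_signal(clean_ecg_30s, cfg, 0)
        np.testing.assert_array_equal(out.samples, clean_ecg_30s.samples)

    def test_white_noise_snr_calibrated(self, clean_ecg_30s):
        cfg = cp.SynthConfig(
            seed=6, baseline_wander_amp=0.0, powerline_amp=0.0,
            white_snr_db=0.0, spike_rate_hz=0.0,
        )
        out = cp.corrupt_signal(clean_ecg_30s, cfg, 0)
        noise = out.samples - clean_ecg_30s.samples
        snr_db = 10 * np.log10(np.mean(clean_ecg_30s.samples**2) / np.mean(noise**2))
        assert abs(snr_db) < 0.5

    def test_spike_count_within_poisson_interval(self, clean_ecg_30s):
        rate, dur = 0.5, clean_ecg_30s.duration_s
        cfg = cp.SynthConfig(
            seed=8, baseline_wander_amp=0.0, powerline_amp=0.0,
            white_snr_db=None, spike_rate_hz=rate,
        )
        counts = [
            cp.corrupt_signal(clean_ecg_30s, cfg, s).meta["artifact_positions"].size
            for s in range(30)
        ]
        lo, hi = poisson.ppf([0.005, 0.995], mu=rate * dur)
        inside = sum(lo <= c <= hi for c in counts)
        assert inside >= 0.9 * len(counts)
        # pooled count within the 99.9% interval of the summed process
        tlo, thi = poisson.ppf([0.0005, 0.9995], mu=rate * dur * len(counts))
        assert tlo <= sum(counts) <= thi


class TestCohort:
    def test_ratio_matches_screening_population(self):
        cfg = cp.SynthConfig(n_positive=273, n_negative=115, seed=1)
        # only counts and labels are needed; do not synthesize the signals
        assert cfg.n_positive / cfg.n_negative == pytest.approx(2.37, abs=0.01)

    def test_empty_cohort(self):
        cfg = cp.SynthConfig(n_positive=0, n_negative=0, seed=0)
        pairs, manifest = cp.generate_cohort(cfg)
        assert pairs == [] and len(manifest) == 0
        assert list(manifest.columns)[:3] == ["record_id", "label", "duration_s"]

    def test_durations_within_envelope(self, small_cohort):
        _, pairs, manifest = small_cohort
        assert manifest["duration_s"].between(9.0, 36.0).all()
        assert (manifest["duration_s"] >= 8.0).all()

    def test_cohort_determinism(self):
        cfg = cp.SynthConfig(n_positive=2, n_negative=2, seed=13)
        (a, _), _ = cp.generate_cohort(cfg)[0][0], None
        (b, _), _ = cp.generate_cohort(cfg)[0][0], None
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_stride_rebalancing_near_one_to_one(self):
        """8-s/3-s strides rebalance a 2.4:1 cohort to roughly 1:1 segments."""
        cfg = cp.SynthConfig(n_positive=48, n_negative=20, seed=17)
        rng = np.random.default_rng(5)
        n_pos = n_neg = 0
        for i in range(cfg.n_positive + cfg.n_negative):
            label = "positive" if i < cfg.n_positive else "negative"
            dur = float(np.clip(rng.lognormal(cfg.duration_log_mean, cfg.duration_log_sd), 9, 36))
            L = int(dur * 2000)
            w, s = 8 * 2000, (8 if label == "positive" else 3) * 2000
            n = (L - w) // s + 1 if L >= w else 0
            if label == "positive":
                n_pos += n
            else:
                n_neg += n
        assert 0.8 <= n_pos / n_neg <= 1.25

    def test_manifest_files_round_trip(self, tmp_path):
        cfg = cp.SynthConfig(n_positive=1, n_negative=1, seed=23)
        pairs, manifest = cp.generate_cohort(cfg, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        got = cp.read_record(manifest.loc[0, "ecg_path"], "wav", "ECG")
        assert got.n_samples == pairs[0][0].n_samples

    def test_subtype_labels(self):
        cfg = cp.SynthConfig(n_positive=6, n_negative=2, seed=29, subtype_labels=True)
        _, manifest = cp.generate_cohort(cfg, corrupt=False)
        assert set(manifest["label"][:6]) == {"AD", "MVP", "MPC"}
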