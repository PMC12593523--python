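"""Denoise a corrupted ECG and remove injected spike artifacts.

A clean synthetic ECG is corrupted with baseline wander, powerline
interference, white noise and spike artifacts; the example then runs the
Wiener filter and false-peak elimination and reports how much closer the
cleaned signal is to the clean reference, and how many injected spikes were
caught.
"""

import numpy as np

import cardiopyramid as cp

base = cp.SynthConfig(seed=3, heart_rate_bpm=(65.0, 0.0), spike_rate_hz=0.3)
clean = cp.generate_ecg(base, subject_seed=0, label="negative", duration_s=30.0)
noisy = cp.corrupt_signal(clean, base, subject_seed=0)
spikes = noisy.meta["artifact_positions"]

denoised = cp.wiener_filter(noisy.samples)
cleaned, peaks = cp.false_peak_elimination(denoised, noisy.fs, "ECG")

mse_before = np.mean((noisy.samples - clean.samples) ** 2)
mse_after = np.mean((cleaned - clean.samples) ** 2)
flagged = peaks.indices[peaks.is_false]
caught = sum(np.min(np.abs(flagged - p)) <= 50 for p in spikes) if flagged.size else 0

print(f"injected spikes: {spikes.size}, flagged false and repaired: {caught}")
print(f"MSE vs clean reference  before: {mse_before:.5f}   after: {mse_after:.5f}")
print("the Wiener taps solve the Toeplitz normal equations; the spike repair")
print("replaces only +/-100 ms around each flagged peak, so QRS morphology away")
print("from artifacts is untouched")
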