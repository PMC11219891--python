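"""Generate a noisy two-class ECG, denoise it, and measure the cleanup.

The record carries baseline wander at 0.3 Hz, 50 Hz mains interference and
white noise, then is 11-bit quantized over a 10 mV range.  The denoiser is
the integer-comb cascade: a subtraction high-pass kills the drift, a
moving-sum comb with a zero on the mains line kills the interference.
"""

import numpy as np
from scipy.signal import periodogram

from ecgkit import (
    NoiseSpec, add_noise, denoise, generate_record, make_rhythm, quantize,
)

fs = 500.0
rhythm = make_rhythm(20.0, mean_rr_s=0.8, ectopic_rate=0.1, seed=1)
clean = generate_record(20.0, fs, rhythm, seed=1)
noisy = quantize(add_noise(clean, NoiseSpec(
    baseline=(0.5, 0.3), powerline=(50.0, 0.5, 2), white_sd=0.02, seed=1)))
restored = denoise(noisy, mode="iir", powerline_hz=50.0)


def bin_db(x, f):
    fr, P = periodogram(x, fs)
    return 10 * np.log10(P[np.argmin(np.abs(fr - f))])


print(f"record: {len(noisy)} samples, {len(noisy.annotations)} beats")
for f, what in ((50.0, "mains"), (0.3, "baseline drift")):
    drop = bin_db(noisy.lead(), f) - bin_db(restored.lead(), f)
    print(f"{what} ({f:g} Hz): suppressed by {drop:.1f} dB")
# dB figures are periodogram-bin power before minus after; > 20-40 dB means
# the contaminant is effectively gone while beats stay aligned.
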