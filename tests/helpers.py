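"""Independent oracle implementations used by the test suite.

These deliberately re-derive results through a different code path than
the library (whole-vector batch processing, explicit loops, closed
forms) so agreement is informative.
"""

import numpy as np
from scipy import signal

from swrloop.config import DetectionConfig
from swrloop.online import ThresholdSet


def batch_detect_oracle(ripple: np.ndarray, noise: np.ndarray,
                        thresholds: ThresholdSet,
                        config: DetectionConfig):
    """Non-streaming reference detector: filter/threshold the whole
    vector at once, then replay the crossing state machine.

    Returns a list of (sample_index, disposition) tuples.
    """
    fs = config.online_rate_hz
    w = max(int(round(config.rms_window_s * fs)), 1)

    def rms_of(x, band):
        lo, hi = config.clamped_band(band)
        sos = signal.butter(config.filter_order // 2, (lo, hi),
                            btype="bandpass", fs=fs, output="sos")
        f = signal.sosfilt(sos, x)
        padded = np.concatenate([np.zeros(w - 1), f ** 2])
        csum = np.concatenate([[0.0], np.cumsum(padded)])
        return np.sqrt((csum[w:] - csum[:-w]) / w)

    rms_r = rms_of(ripple, config.ripple_band_hz)
    rms_n = rms_of(noise, config.noise_band_hz)
    above = rms_r >= thresholds.ripple_rms_threshold
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))

    out = []
    last_fired = -np.inf
    for i in starts:
        t = i / fs
        if t - last_fired < config.lockout_s:
            out.append((i, "LOCKED_OUT"))
        elif rms_n[i] >= thresholds.noise_rms_threshold:
            out.append((i, "VETOED"))
        else:
            out.append((i, "FIRED"))
            last_fired = t
    return out


def renewal_nrem_fraction_oracle(duration_s, mean_nrem, mean_rem, mean_wake,
                                 n_sims, seed):
    """Brute-force epoch accumulation of the NREM time fraction.

    Simulates the NREM→REM→WAKE alternating-renewal cycle (starting in
    NREM) by direct dwell-time accumulation.
    """
    rng = np.random.default_rng(seed)
    means = [mean_nrem, mean_rem, mean_wake]
    fracs = []
    for _ in range(n_sims):
        t = 0.0
        nrem_time = 0.0
        idx = 0
        while t < duration_s:
            dwell = rng.exponential(means[idx % 3])
            end = min(t + dwell, duration_s)
            if idx % 3 == 0:
                nrem_time += end - t
            t = end
            idx += 1
        fracs.append(nrem_time / duration_s)
    return float(np.mean(fracs))


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Mean periodogram power of ``x`` inside [lo, hi] Hz."""
    freqs, pxx = signal.periodogram(x, fs=fs)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(pxx[sel].mean())


def fit_tone_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Least-squares amplitude of a sinusoid at ``freq`` in ``x``."""
    t = np.arange(x.size) / fs
    design = np.column_stack([np.sin(2 * np.pi * freq * t),
                              np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef))


def make_ripple_in_noise(rng, fs=500, dur_total_s=30.0, ripple_amp_sd=10.0,
                         ripple_dur_s=0.060, ripple_freq=180.0,
                         noise_sd=20.0, at_s=15.0):
    """White noise with one Hanning-windowed ripple burst inserted.

    The burst amplitude is ``ripple_amp_sd`` × the SD of the band-passed
    noise (measured), mirroring how event sizes are quoted in SD units.
    Returns (signal, onset_s, offset_s).
    """
    n = int(dur_total_s * fs)
    x = rng.standard_normal(n) * noise_sd
    sos = signal.butter(2, (150, 237.5), btype="bandpass", fs=fs,
                        output="sos")
    band_sd = signal.sosfiltfilt(sos, x).std()
    m = int(ripple_dur_s * fs)
    i0 = int(at_s * fs)
    t = np.arange(m) / fs
    x[i0:i0 + m] += (ripple_amp_sd * band_sd * np.hanning(m)
                     * np.sin(2 * np.pi * ripple_freq * t))
    return x, i0 / fs, (i0 + m) / fs
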