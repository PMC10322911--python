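"""Post hoc gold-standard SWR detection.

Raw 20 kHz signals are decimated to 500 Hz with an anti-aliasing FIR
low-pass, band-pass filtered in the ripple band (150–250 Hz, upper edge
clamped below Nyquist), squared, envelope-smoothed, and z-scored over
the whole recording (excluding stimulation-blanked samples). Candidate
events are local maxima of the normalized power exceeding 3 SD whose
edges are walked outward to the nearest sub-2-SD sample within a 150 ms
search window; overlapping candidates are merged; events shorter than
20 ms or longer than 200 ms are excluded to minimize artifacts.

Offline filtering is zero-phase (forward-backward), as is conventional
for post hoc analysis; only the online path is constrained to causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import OfflineConfig
from .errors import DegenerateSignalError, InvalidConfigError
from .online import StimTrain


def clipped_moments(p: np.ndarray, clip_z: float,
                    max_iter: int = 20) -> tuple[float, float]:
    """Background mean/SD of a power trace, iteratively excluding events.

    Samples above ``mean + clip_z·SD`` are removed and the moments
    re-estimated until the exclusion set stabilizes. Rare high-power
    events (ripples, artifacts) would otherwise inflate the SD and make
    the z-thresholds drift with event density; under an event-free
    Gaussian background the clipped moments stay close to the plain ones.
    """
    p = np.asarray(p, dtype=float)
    keep = np.isfinite(p)
    if keep.sum() < 2:
        raise DegenerateSignalError("too few samples for moment estimation")
    for _ in range(max_iter):
        mu, sd = p[keep].mean(), p[keep].std()
        if sd == 0:
            raise DegenerateSignalError("power trace has zero variance")
        new = np.isfinite(p) & (p <= mu + clip_z * sd)
        if new.sum() < 2 or np.array_equal(new, keep):
            break
        keep = new
    return float(mu), float(sd)


@dataclass(frozen=True)
class RippleEvent:
    """One detected SWR with half-open extent [onset, offset)."""

    onset_s: float
    peak_s: float
    offset_s: float
    peak_z: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def decimate_raw(raw_lfp: np.ndarray, raw_rate_hz: int,
                 target_rate_hz: int = 500) -> np.ndarray:
    """Anti-alias and downsample (20 kHz → 500 Hz in the standard path).

    The rate ratio must be an integer; output length is ``ceil(N / q)``.
    """
    if raw_rate_hz % target_rate_hz != 0:
        raise InvalidConfigError(
            f"raw rate {raw_rate_hz} is not an integer multiple of "
            f"{target_rate_hz}")
    q = raw_rate_hz // target_rate_hz
    if q == 1:
        return np.asarray(raw_lfp, dtype=float)
    return signal.resample_poly(np.asarray(raw_lfp, dtype=float), up=1,
                                down=q, axis=-1)


def normalized_squared(filtered_signal: np.ndarray,
                       smooth_window_s: float | None = None,
                       rate_hz: float | None = None,
                       blank_mask: np.ndarray | None = None) -> np.ndarray:
    """Square, optionally envelope-smooth, and z-score a filtered trace.

    Without smoothing this is the literal normalized squared signal
    (mean 0, SD 1 over non-blanked samples). ``blank_mask`` marks samples
    excluded from the moments; their z-values are returned as NaN.
    """
    x = np.asarray(filtered_signal, dtype=float)
    if x.ndim != 1 or x.size < 2 or not np.all(np.isfinite(x)):
        raise InvalidConfigError("signal must be a finite 1-D array, length > 1")
    p = x ** 2
    if smooth_window_s is not None:
        if rate_hz is None:
            raise InvalidConfigError("rate_hz required with smoothing")
        w = max(int(round(smooth_window_s * rate_hz)), 1)
        if w > 1:
            kernel = np.ones(w) / w
            p = np.convolve(p, kernel, mode="same")
    if blank_mask is not None:
        blank_mask = np.asarray(blank_mask, dtype=bool)
        if blank_mask.shape != p.shape:
            raise InvalidConfigError("blank mask shape mismatch")
        valid = p[~blank_mask]
    else:
        valid = p
    if valid.size < 2:
        raise DegenerateSignalError("too few non-blanked samples")
    mu, sd = valid.mean(), valid.std()
    if sd == 0:
        raise DegenerateSignalError("normalized squared signal has zero variance")
    z = (p - mu) / sd
    if blank_mask is not None:
        z[blank_mask] = np.nan
    return z


def blanking_mask(n_samples: int, rate_hz: float, stim_trains: list[StimTrain],
                  blanking_s: float) -> np.ndarray:
    """Samples within ±blanking_s of any stimulation pulse."""
    mask = np.zeros(n_samples, dtype=bool)
    for train in stim_trains:
        for onset in train.pulse_onsets_s:
            i0 = int(np.floor((onset - blanking_s) * rate_hz))
            i1 = int(np.ceil((onset + train.pulse_width_s + blanking_s)
                             * rate_hz))
            mask[max(i0, 0):min(i1, n_samples)] = True
    return mask


def detect_offline(lfp_500: np.ndarray, config: OfflineConfig | None = None,
                   stim_trains: list[StimTrain] | None = None,
                   valid_mask: np.ndarray | None = None
                   ) -> list[RippleEvent]:
    """Detect SWRs on a single 500 Hz channel; see the module docstring.

    ``stim_trains``, when given, blanks ±``blanking_s`` around every pulse:
    blanked samples are excluded from the z-scoring moments and cannot
    host peaks or supra-boundary extent. ``valid_mask`` (per-sample bool)
    restricts both the moments and event peaks to valid samples — pass
    the NREM mask to emulate the sleep-scored, curated gold standard of
    conventional post hoc analysis (SWRs are NREM events; states with a
    different background variance would otherwise distort the z-scale).
    """
    config = config or OfflineConfig()
    config.validate()
    fs = config.target_rate_hz
    x = np.asarray(lfp_500, dtype=float)
    if x.ndim != 1:
        raise InvalidConfigError("detect_offline expects a single channel")
    n = x.size

    nyq = fs / 2.0
    lo = min(config.ripple_band_hz[0], config.nyquist_clamp * nyq)
    hi = min(config.ripple_band_hz[1], config.nyquist_clamp * nyq)
    sos = signal.butter(config.filter_order // 2, (lo, hi), btype="bandpass",
                        fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)

    # ripple power via the squared analytic envelope: with the ripple band
    # abutting Nyquist at 500 Hz, squaring the real signal aliases the 2f
    # component down into 25–180 Hz beats that fragment events; the
    # analytic envelope is free of the 2f term
    p = np.abs(signal.hilbert(filt)) ** 2
    w = max(int(round(config.smooth_window_s * fs)), 1)
    if w > 1:
        p = np.convolve(p, np.ones(w) / w, mode="same")
    if stim_trains:
        mask = blanking_mask(n, fs, stim_trains, config.blanking_s)
        p = np.where(mask, np.nan, p)
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != p.shape:
            raise InvalidConfigError("valid_mask shape mismatch")
        p = np.where(valid_mask, p, np.nan)
    # z-score against background moments with the events themselves
    # excluded, so the 3/2 SD criteria track the baseline rather than the
    # (density-dependent) event tail; clipping well above peak_z leaves
    # the null mass untouched, so the iteration is stable
    mu, sd = clipped_moments(p, config.moment_clip_factor * config.peak_z)
    z = (p - mu) / sd
    z_clean = np.where(np.isnan(z), -np.inf, z)

    peaks, _ = signal.find_peaks(z_clean, height=config.peak_z, distance=w)
    if peaks.size == 0:
        return []

    # index sets below the boundary (blanked counts as below: events may
    # not extend through a blanked span)
    below = np.flatnonzero(~(z_clean >= config.boundary_z))
    max_reach = int(round(config.search_window_s * fs))

    spans: list[tuple[int, int, int]] = []  # (onset, offset_excl, peak_idx)
    for pk in peaks:
        j = np.searchsorted(below, pk)
        left_stop = below[j - 1] if j > 0 else -1
        onset = max(left_stop + 1, pk - max_reach, 0)
        right_stop = below[j] if j < below.size else n
        offset = min(right_stop, pk + max_reach + 1, n)
        spans.append((onset, offset, pk))

    # merge overlapping candidates and those separated by less than the
    # minimum inter-event gap (conventional minimum inter-ripple
    # separation; also re-joins events fragmented by mid-event envelope
    # dips), keeping the strongest peak
    gap = int(round(config.merge_gap_s * fs))
    spans.sort()
    merged: list[list[int]] = []
    for onset, offset, pk in spans:
        if merged and onset < merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], offset)
            if z_clean[pk] > z_clean[merged[-1][2]]:
                merged[-1][2] = pk
        else:
            merged.append([onset, offset, pk])

    lo_d, hi_d = config.duration_bounds_s
    events = []
    for onset, offset, pk in merged:
        dur = (offset - onset) / fs
        if lo_d <= dur <= hi_d:  # inclusive on both ends
            events.append(RippleEvent(onset_s=onset / fs, peak_s=pk / fs,
                                      offset_s=offset / fs,
                                      peak_z=float(z_clean[pk])))
    return events
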