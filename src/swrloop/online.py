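"""Causal, streaming two-channel SWR detection and stimulation scheduling.

The online path mirrors a real-time implementation: a forward-only
4th-order Butterworth band-pass per channel (150–250 Hz ripple band on
the hippocampal channel, 80–500 Hz on the noise reference, both clamped
below Nyquist at the 500 Hz online rate), a trailing 10 ms sliding RMS,
and a threshold state machine. A supra-threshold ripple-RMS excursion
produces exactly one log entry, decided at its first sample: FIRED when
the noise-reference RMS is sub-threshold at that sample, VETOED when it
is concurrently supra-threshold (shared broadband artifacts light up
both channels — "in the absence of the noise signal"), LOCKED_OUT
within the refractory period after the previous FIRED trigger. The
trigger time is the crossing time plus a configurable processing
latency. Filter group delay and RMS-window lag therefore contribute to
the measured trigger latency, as they do in hardware.

Processing is strictly causal: the signal is consumed in chunks with
filter and RMS state carried across chunk boundaries, so truncating the
input never changes triggers emitted before the truncation point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import MFB_TRAIN, VHC_PULSE, DetectionConfig, StimProtocol
from .errors import DegenerateSignalError, InvalidConfigError
from .synth import SyntheticSession

FIRED = "FIRED"
VETOED = "VETOED"
LOCKED_OUT = "LOCKED_OUT"


@dataclass(frozen=True)
class ThresholdSet:
    """Per-animal calibrated RMS thresholds (µV) and baseline moments."""

    ripple_rms_threshold: float
    noise_rms_threshold: float
    baseline_mean: tuple[float, float]  # (ripple ch, noise ch) RMS mean
    baseline_sd: tuple[float, float]

    def validate(self) -> None:
        if not np.all(np.isfinite([self.ripple_rms_threshold,
                                   self.noise_rms_threshold])):
            raise InvalidConfigError("thresholds must be finite")
        if (self.ripple_rms_threshold < self.baseline_mean[0]
                or self.noise_rms_threshold < self.baseline_mean[1]):
            raise InvalidConfigError("thresholds must be >= baseline mean")


@dataclass(frozen=True)
class Trigger:
    crossing_time_s: float
    trigger_time_s: float
    disposition: str


@dataclass
class TriggerLog:
    """Time-ordered log of every supra-threshold ripple-RMS excursion."""

    entries: list[Trigger]
    config: DetectionConfig

    def fired(self) -> list[Trigger]:
        return [t for t in self.entries if t.disposition == FIRED]

    def fired_times(self) -> np.ndarray:
        return np.array([t.trigger_time_s for t in self.fired()])


@dataclass(frozen=True)
class StimTrain:
    start_s: float
    pulse_onsets_s: tuple[float, ...]
    pulse_width_s: float

    @property
    def span_s(self) -> float:
        return (self.pulse_onsets_s[-1] - self.pulse_onsets_s[0]
                + self.pulse_width_s)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def causal_bandpass_sos(band: tuple[float, float], config: DetectionConfig):
    """SOS coefficients for the forward-only Butterworth band-pass."""
    lo, hi = config.clamped_band(band)
    return signal.butter(config.filter_order // 2, (lo, hi),
                         btype="bandpass", fs=config.online_rate_hz,
                         output="sos")


def trailing_rms(x: np.ndarray, window_samples: int,
                 carry_sq: np.ndarray | None = None) -> np.ndarray:
    """Trailing-window RMS with zero history before the first sample.

    ``carry_sq`` supplies the squared samples preceding ``x`` (streaming);
    its length must be ``window_samples - 1``.
    """
    w = window_samples
    sq = x.astype(float) ** 2
    if carry_sq is None:
        carry_sq = np.zeros(w - 1)
    padded = np.concatenate([carry_sq, sq])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    sums = csum[w:] - csum[:-w]
    return np.sqrt(np.maximum(sums, 0.0) / w)


# --------------------------------------------------------------------------
# threshold calibration
# --------------------------------------------------------------------------

def calibrate_thresholds(baseline_lfp: np.ndarray, config: DetectionConfig,
                         *, allow_degenerate: bool = False,
                         settle_s: float = 0.5) -> ThresholdSet:
    """Per-animal thresholds: mean + k·SD of the causal band-passed RMS.

    ``baseline_lfp`` is a (2, N) stimulation-free segment of at least
    60 s at the online rate, row 0 the ripple channel, row 1 the noise
    reference. The first ``settle_s`` of the RMS trace (filter start-up)
    is excluded from the moments.
    """
    config.validate()
    fs = config.online_rate_hz
    if baseline_lfp.ndim != 2 or baseline_lfp.shape[0] != 2:
        raise InvalidConfigError("baseline must be a (2, N) array")
    if baseline_lfp.shape[1] < 60 * fs:
        raise InvalidConfigError("baseline must be at least 60 s long")

    w = max(int(round(config.rms_window_s * fs)), 1)
    skip = int(settle_s * fs)
    means, sds, thresholds = [], [], []
    for ch, band, k in ((0, config.ripple_band_hz, config.threshold_k_ripple),
                        (1, config.noise_band_hz, config.threshold_k_noise)):
        sos = causal_bandpass_sos(band, config)
        filt = signal.sosfilt(sos, baseline_lfp[ch])
        rms = trailing_rms(filt, w)[skip:]
        mu, sd = float(rms.mean()), float(rms.std())
        if sd == 0 and not allow_degenerate:
            raise DegenerateSignalError(
                "baseline RMS has zero variance; pass allow_degenerate=True "
                "to calibrate on a constant baseline anyway")
        means.append(mu)
        sds.append(sd)
        thresholds.append(mu + k * sd)
    return ThresholdSet(ripple_rms_threshold=thresholds[0],
                        noise_rms_threshold=thresholds[1],
                        baseline_mean=(means[0], means[1]),
                        baseline_sd=(sds[0], sds[1]))


# --------------------------------------------------------------------------
# streaming detection
# --------------------------------------------------------------------------

def _session_arrays(session) -> tuple[np.ndarray, np.ndarray, int]:
    if isinstance(session, SyntheticSession):
        roles = session.channel_roles
        if "ripple_channel" not in roles or "noise_channel" not in roles:
            raise InvalidConfigError("channel-role metadata missing")
        return session.ripple_channel, session.noise_channel, session.sampling_rate_hz
    # bare (2, N) array: row 0 ripple, row 1 noise
    arr = np.asarray(session)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise InvalidConfigError(
            "recording must be a SyntheticSession or a (2, N) array")
    return arr[0], arr[1], 0


def stream_detect(session, thresholds: ThresholdSet, config: DetectionConfig,
                  *, chunk_s: float = 1.0) -> TriggerLog:
    """Run the causal threshold state machine over a recording.

    The recording must already be at the online rate (decimate raw 20 kHz
    data first). Emits one entry per supra-threshold ripple-RMS
    excursion; see the module docstring for the disposition rules.
    """
    config.validate()
    thresholds.validate()
    ripple, noise, fs = _session_arrays(session)
    if fs and fs != config.online_rate_hz:
        raise InvalidConfigError(
            f"recording rate {fs} != online rate {config.online_rate_hz}; "
            "decimate first")
    fs = config.online_rate_hz
    n = ripple.shape[0]
    w = max(int(round(config.rms_window_s * fs)), 1)
    chunk = max(int(round(chunk_s * fs)), w)

    sos_r = causal_bandpass_sos(config.ripple_band_hz, config)
    sos_n = causal_bandpass_sos(config.noise_band_hz, config)
    zi_r = np.zeros((sos_r.shape[0], 2))
    zi_n = np.zeros((sos_n.shape[0], 2))
    carry_r = np.zeros(w - 1)
    carry_n = np.zeros(w - 1)

    entries: list[Trigger] = []
    prev_above = False
    last_fired = -np.inf
    for start in range(0, n, chunk):
        seg_r = ripple[start:start + chunk]
        seg_n = noise[start:start + chunk]
        filt_r, zi_r = signal.sosfilt(sos_r, seg_r, zi=zi_r)
        filt_n, zi_n = signal.sosfilt(sos_n, seg_n, zi=zi_n)
        rms_r = trailing_rms(filt_r, w, carry_r)
        rms_n = trailing_rms(filt_n, w, carry_n)
        if w > 1:
            carry_r = np.concatenate([carry_r, filt_r ** 2])[-(w - 1):]
            carry_n = np.concatenate([carry_n, filt_n ** 2])[-(w - 1):]

        above = rms_r >= thresholds.ripple_rms_threshold
        prev = np.concatenate([[prev_above], above[:-1]])
        starts = np.flatnonzero(above & ~prev)
        for i in starts:
            t = (start + i) / fs
            if t - last_fired < config.lockout_s:
                disp = LOCKED_OUT
            elif rms_n[i] >= thresholds.noise_rms_threshold:
                disp = VETOED
            else:
                disp = FIRED
                last_fired = t
            entries.append(Trigger(
                crossing_time_s=t,
                trigger_time_s=t + config.processing_latency_s,
                disposition=disp))
        if len(above):
            prev_above = bool(above[-1])
    return TriggerLog(entries=entries, config=config)


# --------------------------------------------------------------------------
# stimulation
# --------------------------------------------------------------------------

def schedule_stimulation(trigger_log: TriggerLog,
                         protocol: StimProtocol) -> list[StimTrain]:
    """One stimulation train per FIRED trigger, starting at trigger time.

    MFB trains carry 14 pulse onsets at multiples of 1/140 s (nominal
    100 ms span); VHC yields a single 0.5 ms pulse.
    """
    protocol.validate()
    if protocol.kind not in (MFB_TRAIN, VHC_PULSE):  # pragma: no cover
        raise InvalidConfigError(f"unknown protocol {protocol.kind!r}")
    trains = []
    for trig in trigger_log.fired():
        t0 = trig.trigger_time_s
        if protocol.n_pulses == 1:
            onsets = (t0,)
        else:
            period = 1.0 / protocol.rate_hz
            onsets = tuple(t0 + k * period for k in range(protocol.n_pulses))
        trains.append(StimTrain(start_s=t0, pulse_onsets_s=onsets,
                                pulse_width_s=protocol.pulse_width_s))
    return trains


def render_stimulus_artifact(lfp: np.ndarray, trains: list[StimTrain],
                             rate_hz: float, artifact_gain: float,
                             saturation_uv: float = 1500.0) -> np.ndarray:
    """Superimpose saturating square stimulation transients on both channels.

    Each pulse adds ``artifact_gain × saturation_uv`` during its width
    (clipped to ±saturation); samples outside pulses are untouched. With
    gain 0 the signal is returned unchanged (copy).
    """
    out = np.array(lfp, dtype=float, copy=True)
    if artifact_gain == 0:
        return out
    n = out.shape[-1]
    for train in trains:
        for onset in train.pulse_onsets_s:
            i0 = int(round(onset * rate_hz))
            i1 = max(int(round((onset + train.pulse_width_s) * rate_hz)), i0 + 1)
            if i0 >= n or i1 <= 0:
                continue  # pulse past the recording edge: nothing to contaminate
            sl = slice(max(i0, 0), min(i1, n))
            out[..., sl] = np.clip(out[..., sl] + artifact_gain * saturation_uv,
                                   -saturation_uv, saturation_uv)
    return out
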