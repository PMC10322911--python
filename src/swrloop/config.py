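"""Configuration dataclasses shared across the pipeline.

All times are seconds from recording start, sample indices are 0-based and
intervals are half-open ``[onset, offset)``. Voltages are µV. Ripple
amplitudes are dimensionless, expressed in units of the standard deviation
of the band-pass-filtered NREM background on the ripple channel (its RMS,
since the band signal is zero-mean), so that per-animal threshold
calibration in SD units is meaningful across simulated sessions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import InvalidConfigError

STATE_LABELS = ("NREM", "REM", "WAKE")

#: Online/raw sampling rates the acquisition layout admits.
VALID_RATES = (500, 20_000)


@dataclass(frozen=True)
class StateConfig:
    """Alternating-renewal sleep architecture: NREM → REM → WAKE → NREM.

    Dwell times are exponential with the given means. A mean of 0 removes
    the state from the cycle (e.g. ``rem=0, wake=0`` yields one NREM epoch
    spanning the whole recording).
    """

    mean_dwell_nrem_s: float = 480.0
    mean_dwell_rem_s: float = 60.0
    mean_dwell_wake_s: float = 90.0
    start_state: str = "NREM"

    def validate(self) -> None:
        dwells = (self.mean_dwell_nrem_s, self.mean_dwell_rem_s,
                  self.mean_dwell_wake_s)
        if any(d < 0 for d in dwells):
            raise InvalidConfigError("state dwell-time means must be >= 0")
        if all(d == 0 for d in dwells):
            raise InvalidConfigError("at least one state must have a positive dwell mean")
        if self.start_state not in STATE_LABELS:
            raise InvalidConfigError(f"unknown state label {self.start_state!r}")
        if self.mean_dwell(self.start_state) == 0:
            raise InvalidConfigError("start_state has zero dwell mean")

    def mean_dwell(self, label: str) -> float:
        return {"NREM": self.mean_dwell_nrem_s,
                "REM": self.mean_dwell_rem_s,
                "WAKE": self.mean_dwell_wake_s}[label]


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to synthesize one ground-truthed LFP session."""

    duration_s: float = 1800.0
    sampling_rate_hz: int = 500
    state: StateConfig = field(default_factory=StateConfig)

    # background: Gaussian 1/f^alpha noise, per-state SD scaling
    background_sd_uv: float = 40.0
    background_alpha: float = 1.0
    state_sd_scale: tuple[float, float, float] = (1.0, 0.8, 1.2)  # NREM, REM, WAKE

    # ripples: Poisson in NREM, Hanning-windowed sinusoid + sharp wave
    ripple_rate_hz: float = 0.35
    ripple_duration_s: tuple[float, float] = (0.030, 0.090)
    ripple_freq_hz: tuple[float, float] = (160.0, 230.0)
    amplitude_median_z: float = 5.0
    amplitude_sigma_ln: float = 0.39860
    amplitude_clip_z: tuple[float, float] = (1.5, 40.0)
    sharpwave_rel_amp: float = 1.0
    sharpwave_dur_factor: float = 1.5

    # broadband artifact transients, shared by both channels; the first
    # artifact_clear_s stay artifact-free, emulating the curated low-noise
    # baseline thresholds are calibrated on
    artifact_rate_hz: float = 0.05
    artifact_amplitude_z: float = 8.0
    artifact_duration_s: tuple[float, float] = (0.004, 0.010)
    artifact_clear_s: float = 60.0

    def validate(self) -> None:
        self.state.validate()
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if self.sampling_rate_hz not in VALID_RATES:
            raise InvalidConfigError(
                f"sampling_rate_hz must be one of {VALID_RATES}")
        if self.ripple_rate_hz < 0:
            raise InvalidConfigError("ripple_rate_hz must be >= 0")
        if self.artifact_rate_hz < 0:
            raise InvalidConfigError("artifact_rate_hz must be >= 0")
        if self.background_sd_uv <= 0:
            raise InvalidConfigError("background_sd_uv must be positive")
        lo, hi = self.ripple_duration_s
        if not (0.020 <= lo <= hi <= 0.120):
            raise InvalidConfigError(
                "ripple durations must sit inside [0.020, 0.120] s")


@dataclass(frozen=True)
class DetectionConfig:
    """Online (streaming) detector parameters.

    The ripple band's nominal upper edge (250 Hz) equals Nyquist at the
    500 Hz online rate, where a filter edge is ill-defined; edges are
    clamped to ``nyquist_clamp``×Nyquist before filter design. Defaults
    not fixed by the acquisition protocol (RMS window, filter order,
    lockout, threshold multipliers) are explicit, reproducible choices.
    """

    ripple_band_hz: tuple[float, float] = (150.0, 250.0)
    noise_band_hz: tuple[float, float] = (80.0, 500.0)
    online_rate_hz: int = 500
    rms_window_s: float = 0.010
    threshold_k_ripple: float = 4.0
    threshold_k_noise: float = 4.0
    lockout_s: float = 0.250
    processing_latency_s: float = 0.010
    filter_order: int = 4  # poles of the Butterworth band-pass
    nyquist_clamp: float = 0.95

    def validate(self) -> None:
        for lo, hi in (self.ripple_band_hz, self.noise_band_hz):
            if not (0 < lo < hi):
                raise InvalidConfigError("band edges must be positive and ordered")
        if self.online_rate_hz <= 0 or self.rms_window_s <= 0:
            raise InvalidConfigError("rate and RMS window must be positive")
        if self.lockout_s < 0 or self.processing_latency_s < 0:
            raise InvalidConfigError("lockout and latency must be >= 0")

    def clamped_band(self, band: tuple[float, float]) -> tuple[float, float]:
        nyq = self.online_rate_hz / 2.0
        lo, hi = band
        return (min(lo, self.nyquist_clamp * nyq), min(hi, self.nyquist_clamp * nyq))


@dataclass(frozen=True)
class OfflineConfig:
    """Post hoc gold-standard detector parameters.

    Peaks of the normalized squared (smoothed) ripple-band signal must
    exceed ``peak_z`` SD; event edges are walked outward to the nearest
    sub-``boundary_z`` sample, at most ``search_window_s`` away; events
    outside ``duration_bounds_s`` (inclusive) are discarded.
    """

    target_rate_hz: int = 500
    ripple_band_hz: tuple[float, float] = (150.0, 250.0)
    boundary_z: float = 2.0
    peak_z: float = 3.0
    search_window_s: float = 0.150
    duration_bounds_s: tuple[float, float] = (0.020, 0.200)
    blanking_s: float = 0.010
    smooth_window_s: float = 0.010
    merge_gap_s: float = 0.0       # optional min inter-event separation merge
    moment_clip_factor: float = 2.0  # clip moments at clip_factor × peak_z
    filter_order: int = 4
    nyquist_clamp: float = 0.95

    def validate(self) -> None:
        if not self.boundary_z < self.peak_z:
            raise InvalidConfigError("boundary_z must be < peak_z")
        lo, hi = self.duration_bounds_s
        if not (0 < lo < hi):
            raise InvalidConfigError("duration bounds must be positive and ordered")
        if self.search_window_s <= 0:
            raise InvalidConfigError("search_window_s must be positive")


# --- stimulation protocols -------------------------------------------------

MFB_TRAIN = "MFB_TRAIN"
VHC_PULSE = "VHC_PULSE"


@dataclass(frozen=True)
class StimProtocol:
    """Stimulation delivered on each trigger.

    ``MFB_TRAIN``: rewarding medial-forebrain-bundle train — fourteen 1 ms,
    100 µA square pulses at 140 Hz (nominal 100 ms span).
    ``VHC_PULSE``: single 0.5 ms pulse on the ventral hippocampal
    commissure (voltage-controlled, 5–15 V), which aborts the ongoing SWR.
    """

    kind: str = MFB_TRAIN
    n_pulses: int = 14
    pulse_width_s: float = 0.001
    rate_hz: float = 140.0
    amplitude: float = 100.0  # µA for MFB (current mode), V for VHC

    @classmethod
    def mfb_train(cls) -> "StimProtocol":
        return cls(kind=MFB_TRAIN, n_pulses=14, pulse_width_s=0.001,
                   rate_hz=140.0, amplitude=100.0)

    @classmethod
    def vhc_pulse(cls, voltage: float = 10.0) -> "StimProtocol":
        if not 5.0 <= voltage <= 15.0:
            raise InvalidConfigError("VHC amplitude must be within 5–15 V")
        return cls(kind=VHC_PULSE, n_pulses=1, pulse_width_s=0.0005,
                   rate_hz=0.0, amplitude=voltage)

    def validate(self) -> None:
        if self.kind not in (MFB_TRAIN, VHC_PULSE):
            raise InvalidConfigError(f"unknown stimulation protocol {self.kind!r}")
        if self.n_pulses < 1 or self.pulse_width_s <= 0:
            raise InvalidConfigError("pulses must be >= 1 with positive width")
        if self.n_pulses > 1:
            if self.rate_hz <= 0:
                raise InvalidConfigError("multi-pulse trains need a positive rate")
            if self.pulse_width_s > 1.0 / self.rate_hz:
                raise InvalidConfigError("pulses within a train must not overlap")


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Synthetic fear-extinction trajectories, one decay rate per group.

    Per-tone freezing follows
    ``clip(test_cs * exp(-rate * (session-1)) + noise, 0, 100)``;
    closed-loop (CL) animals decay faster and show little renewal/remote
    recovery, mirroring the qualitative group structure of the study.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NS": 9, "OL": 9, "CL": 9})
    decay_rate: dict[str, float] = field(
        default_factory=lambda: {"NS": 0.30, "OL": 0.32, "CL": 0.60})
    test_cs_mean: float = 70.0
    test_cs_sd: float = 10.0
    test_cs_range: tuple[float, float] = (40.0, 95.0)
    tone_noise_sd: float = 5.0
    tones_per_session: int = 20
    max_sessions: int = 7
    renewal_increment: dict[str, float] = field(
        default_factory=lambda: {"NS": 25.0, "OL": 25.0, "CL": 5.0})
    remote_increment: dict[str, float] = field(
        default_factory=lambda: {"NS": 20.0, "OL": 18.0, "CL": 3.0})
    reinstatement_increment: dict[str, float] = field(
        default_factory=lambda: {"NS": 25.0, "OL": 22.0, "CL": 8.0})

    def validate(self) -> None:
        if any(r < 0 for r in self.decay_rate.values()):
            raise InvalidConfigError("decay rates must be >= 0")
        if self.tone_noise_sd < 0:
            raise InvalidConfigError("tone noise SD must be >= 0")
        if any(n < 1 for n in self.n_per_group.values()):
            raise InvalidConfigError("group sizes must be >= 1")
        if self.tones_per_session < 1 or self.max_sessions < 1:
            raise InvalidConfigError("session structure must be positive")


@dataclass(frozen=True)
class BehaviorConfig:
    """Extinction/remission scoring rules."""

    remission_threshold_pct: float = 20.0
    block_size: int = 5
    max_extinction_days: int = 7

    def validate(self) -> None:
        if not 0 < self.remission_threshold_pct < 100:
            raise InvalidConfigError("remission threshold must be in (0, 100)")
        if self.block_size < 1:
            raise InvalidConfigError("block size must be >= 1")


# --- (de)serialization -----------------------------------------------------

_CONFIG_TYPES = {}


def _register(cls):
    _CONFIG_TYPES[cls.__name__] = cls
    return cls


for _cls in (StateConfig, SessionConfig, DetectionConfig, OfflineConfig,
             StimProtocol, BehaviorGenConfig, BehaviorConfig):
    _register(_cls)


def to_dict(cfg) -> dict:
    """Recursively convert a config dataclass to a plain dict (tagged)."""
    d = dataclasses.asdict(cfg)
    d["__type__"] = type(cfg).__name__
    if isinstance(cfg, SessionConfig):
        d["state"]["__type__"] = "StateConfig"
    return d


def from_dict(d: dict):
    """Inverse of :func:`to_dict`."""
    d = dict(d)
    name = d.pop("__type__")
    cls = _CONFIG_TYPES[name]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in d.items():
        if key not in fields:
            raise InvalidConfigError(f"unknown field {key!r} for {name}")
        if isinstance(val, dict) and "__type__" in val:
            val = from_dict(val)
        elif isinstance(val, list):
            val = tuple(val) if not isinstance(val, dict) else val
        kwargs[key] = val
    return cls(**kwargs)


def dump_json(cfg, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(cfg), fh, indent=2, sort_keys=True)


def load_json(path):
    with open(path) as fh:
        return from_dict(json.load(fh))
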