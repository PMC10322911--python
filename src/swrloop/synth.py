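"""Ground-truthed synthetic data: LFP sessions and freezing trajectories.

The LFP generator emulates an hour-scale post-extinction rest recording:
a NREM-dominated alternating-renewal sleep architecture, Gaussian 1/f^α
background on two channels (a hippocampal ripple channel and a
ripple-free neocortical noise-reference channel), sharp-wave-ripple
events — a Hanning-windowed 160–230 Hz sinusoid riding on a negative
sharp-wave deflection — at Poisson times inside NREM on the ripple
channel only, and brief broadband artifact transients shared by both
channels. Ripple amplitudes are log-normal and expressed in units of the
SD of the band-pass-filtered NREM background (the baseline ripple-band
RMS), so threshold calibration in SD units transfers across seeds.

The behavior generator emulates per-animal fear-extinction trajectories:
per-tone freezing decays exponentially across sessions from the post
conditioning test level, with truncated-Gaussian per-tone noise, faster
decay and little fear recovery in the closed-loop (CL) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import (STATE_LABELS, BehaviorGenConfig, SessionConfig,
                     StateConfig)
from .errors import InvalidConfigError

_CYCLE = ("NREM", "REM", "WAKE")  # NREM precedes REM; brief wake closes a cycle


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSequence:
    """Non-overlapping, sorted, contiguous epochs covering [0, duration)."""

    epochs: tuple[tuple[float, float, str], ...]  # (start_s, end_s, label)

    @property
    def duration_s(self) -> float:
        return self.epochs[-1][1] if self.epochs else 0.0

    def label_at(self, t: float) -> str:
        for start, end, label in self.epochs:
            if start <= t < end:
                return label
        raise ValueError(f"time {t} outside state sequence")

    def mask(self, label: str, n_samples: int, rate_hz: float) -> np.ndarray:
        """Boolean per-sample mask of the given state."""
        out = np.zeros(n_samples, dtype=bool)
        for start, end, lab in self.epochs:
            if lab == label:
                i0 = int(np.ceil(start * rate_hz))
                i1 = min(int(np.ceil(end * rate_hz)), n_samples)
                out[i0:i1] = True
        return out

    def validate(self) -> None:
        prev_end = 0.0
        for start, end, label in self.epochs:
            if label not in STATE_LABELS:
                raise InvalidConfigError(f"unknown label {label!r}")
            if not np.isclose(start, prev_end) or end <= start:
                raise InvalidConfigError("epochs must be sorted and contiguous")
            prev_end = end


@dataclass(frozen=True)
class GroundTruthRipple:
    onset_s: float
    peak_s: float
    offset_s: float
    amplitude_z: float   # envelope peak, units of baseline ripple-band SD
    center_freq_hz: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SyntheticSession:
    """One simulated recording with complete ground-truth logs."""

    lfp: np.ndarray                       # (2, N) float64 µV
    sampling_rate_hz: int
    channel_roles: dict[str, int]         # {"ripple_channel": 0, "noise_channel": 1}
    truth: list[GroundTruthRipple]
    artifacts: list[tuple[float, float]]  # (start_s, end_s) on both channels
    states: StateSequence
    seed: int
    baseline_band_sd_uv: float = np.nan   # SD of band-passed NREM background

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.sampling_rate_hz

    @property
    def ripple_channel(self) -> np.ndarray:
        return self.lfp[self.channel_roles["ripple_channel"]]

    @property
    def noise_channel(self) -> np.ndarray:
        return self.lfp[self.channel_roles["noise_channel"]]


@dataclass
class FreezingDataset:
    """Per-animal freezing trajectories in long form.

    ``extinction`` has one row per animal × session × tone (% freezing in
    [0, 100]); the probe columns are 5-tone-block means.
    """

    animals: pd.DataFrame      # animal_id, group, test_cs_freezing
    extinction: pd.DataFrame   # animal_id, session, tone, freezing_pct
    probes: pd.DataFrame       # animal_id, renewal_pct, remote_pct, reinstatement_pct
    seed: int

    def animal_matrix(self, animal_id: str) -> np.ndarray:
        """(n_sessions, tones_per_session) freezing matrix for one animal."""
        sub = self.extinction[self.extinction.animal_id == animal_id]
        return (sub.pivot(index="session", columns="tone", values="freezing_pct")
                .sort_index().to_numpy())


# --------------------------------------------------------------------------
# sleep architecture
# --------------------------------------------------------------------------

def generate_state_sequence(duration_s: float, state_config: StateConfig,
                            seed: int) -> StateSequence:
    """Alternating-renewal WAKE/NREM/REM epochs with exponential dwells.

    The cycle order is NREM → REM → WAKE → NREM; states with zero dwell
    mean are skipped. Deterministic under a fixed seed.
    """
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    state_config.validate()

    cycle = [s for s in _CYCLE if state_config.mean_dwell(s) > 0]
    rng = np.random.default_rng(seed)
    idx = cycle.index(state_config.start_state)
    epochs: list[tuple[float, float, str]] = []
    t = 0.0
    while t < duration_s:
        label = cycle[idx % len(cycle)]
        dwell = rng.exponential(state_config.mean_dwell(label))
        end = min(t + dwell, duration_s)
        if end > t:
            epochs.append((t, end, label))
        t = end
        idx += 1
    # merge adjacent epochs with the same label (possible with 1-state cycles)
    merged: list[tuple[float, float, str]] = []
    for ep in epochs:
        if merged and merged[-1][2] == ep[2]:
            merged[-1] = (merged[-1][0], ep[1], ep[2])
        else:
            merged.append(ep)
    return StateSequence(epochs=tuple(merged))


# --------------------------------------------------------------------------
# LFP synthesis
# --------------------------------------------------------------------------

def _one_over_f_noise(n: int, alpha: float, rng: np.random.Generator,
                      rate_hz: float, f_floor_hz: float = 1.0) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^alpha spectrum (flat below f_floor)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shaping = np.ones_like(freqs)
    above = freqs > f_floor_hz
    shaping[above] = (f_floor_hz / freqs[above]) ** (alpha / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd == 0:
        raise InvalidConfigError("degenerate background noise")
    return x / sd


def _band_sos(band: tuple[float, float], rate_hz: float, order: int = 4,
              clamp: float = 0.95):
    nyq = rate_hz / 2.0
    lo = min(band[0], clamp * nyq)
    hi = min(band[1], clamp * nyq)
    return signal.butter(order // 2, (lo, hi), btype="bandpass",
                         fs=rate_hz, output="sos")


def _ripple_waveform(n: int, freq_hz: float, phase: float,
                     rate_hz: float) -> np.ndarray:
    """Unit-peak-envelope ripple: Hanning window × sinusoid."""
    t = np.arange(n) / rate_hz
    env = np.hanning(n)
    return env * np.sin(2 * np.pi * freq_hz * t + phase)


def _sharpwave_waveform(n: int) -> np.ndarray:
    """Unit-depth negative half-cosine deflection."""
    return -0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def synthesize_recording(session_config: SessionConfig,
                         seed: int) -> SyntheticSession:
    """Generate a two-channel ground-truthed LFP session.

    Channel 0 carries ripples, channel 1 is the ripple-free noise
    reference; broadband artifacts appear on both. Ripples are placed at
    Poisson times wholly inside NREM epochs with a 100 ms minimum gap
    between successive peaks (truth events stay non-overlapping).
    """
    cfg = session_config
    cfg.validate()
    fs = cfg.sampling_rate_hz
    n = int(round(cfg.duration_s * fs))
    rng = np.random.default_rng(seed)

    states = generate_state_sequence(cfg.duration_s, cfg.state,
                                     int(rng.integers(2**31)))
    nrem_mask = states.mask("NREM", n, fs)

    # per-state SD scaling vector
    scale = np.ones(n)
    for label, fac in zip(STATE_LABELS, cfg.state_sd_scale):
        scale[states.mask(label, n, fs)] = fac

    lfp = np.empty((2, n))
    for ch in range(2):
        lfp[ch] = (_one_over_f_noise(n, cfg.background_alpha, rng, fs)
                   * scale * cfg.background_sd_uv)

    # baseline ripple-band SD of the (pre-event) NREM background
    sos = _band_sos((150.0, 250.0), fs)
    band = signal.sosfiltfilt(sos, lfp[0])
    if nrem_mask.any():
        band_sd = float(band[nrem_mask].std())
    else:
        band_sd = float(band.std())
    if band_sd == 0:
        raise InvalidConfigError("degenerate ripple-band baseline")

    # --- ripples -----------------------------------------------------------
    truth: list[GroundTruthRipple] = []
    dur_lo, dur_hi = cfg.ripple_duration_s
    for ep_start, ep_end, label in states.epochs:
        if label != "NREM":
            continue
        ep_dur = ep_end - ep_start
        count = rng.poisson(cfg.ripple_rate_hz * ep_dur)
        if count == 0:
            continue
        peaks = np.sort(rng.uniform(ep_start + dur_hi / 2,
                                    ep_end - dur_hi / 2,
                                    size=count)) if ep_dur > dur_hi else np.array([])
        kept: list[float] = []
        for p in peaks:
            if not kept or p - kept[-1] >= 0.100:  # 100 ms peak separation
                kept.append(float(p))
        for peak_t in kept:
            dur = rng.uniform(dur_lo, dur_hi)
            freq = rng.uniform(*cfg.ripple_freq_hz)
            amp_z = float(np.exp(rng.normal(np.log(cfg.amplitude_median_z),
                                            cfg.amplitude_sigma_ln)))
            amp_z = float(np.clip(amp_z, *cfg.amplitude_clip_z))
            phase = rng.uniform(0, 2 * np.pi)

            n_rip = max(int(round(dur * fs)), 3)
            i0 = int(round((peak_t - dur / 2) * fs))
            i1 = i0 + n_rip
            if i0 < 0 or i1 > n:
                continue
            lfp[0, i0:i1] += amp_z * band_sd * _ripple_waveform(
                n_rip, freq, phase, fs)

            n_sw = max(int(round(dur * cfg.sharpwave_dur_factor * fs)), 3)
            j0 = int(round(peak_t * fs)) - n_sw // 2
            j1 = j0 + n_sw
            s0, s1 = max(j0, 0), min(j1, n)
            lfp[0, s0:s1] += (cfg.sharpwave_rel_amp * amp_z * band_sd
                              * _sharpwave_waveform(n_sw)[s0 - j0:s1 - j0])

            truth.append(GroundTruthRipple(
                onset_s=i0 / fs, peak_s=(i0 + n_rip // 2) / fs,
                offset_s=i1 / fs, amplitude_z=amp_z, center_freq_hz=freq))
    truth.sort(key=lambda r: r.onset_s)

    # --- shared broadband artifacts ----------------------------------------
    artifacts: list[tuple[float, float]] = []
    clear = min(cfg.artifact_clear_s, cfg.duration_s)
    n_art = rng.poisson(cfg.artifact_rate_hz * (cfg.duration_s - clear))
    art_starts = np.sort(rng.uniform(clear, cfg.duration_s, size=n_art))
    for start in art_starts:
        dur = rng.uniform(*cfg.artifact_duration_s)
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        if i1 >= n or i1 <= i0:
            continue
        m = i1 - i0
        env = np.hanning(m) if m > 2 else np.ones(m)
        burst = rng.standard_normal(m) * env
        wave = cfg.artifact_amplitude_z * band_sd * burst
        lfp[0, i0:i1] += wave
        lfp[1, i0:i1] += wave  # same transient couples into both channels
        artifacts.append((i0 / fs, i1 / fs))

    return SyntheticSession(
        lfp=lfp, sampling_rate_hz=fs,
        channel_roles={"ripple_channel": 0, "noise_channel": 1},
        truth=truth, artifacts=artifacts, states=states, seed=seed,
        baseline_band_sd_uv=band_sd)


# --------------------------------------------------------------------------
# freezing trajectories
# --------------------------------------------------------------------------

def generate_freezing_dataset(behavior_config: BehaviorGenConfig,
                              seed: int) -> FreezingDataset:
    """Synthesize per-animal extinction trajectories and recovery probes.

    Freezing on tone ``k`` of session ``s`` (1-based) is
    ``clip(test_cs * exp(-rate_g * (s - 1)) + eps, 0, 100)`` with
    ``eps ~ N(0, tone_noise_sd)``; probe blocks add a group-dependent
    recovery increment to the final-session level.
    """
    cfg = behavior_config
    cfg.validate()
    rng = np.random.default_rng(seed)

    animal_rows, ext_rows, probe_rows = [], [], []
    for group in sorted(cfg.n_per_group):
        rate = cfg.decay_rate[group]
        for i in range(cfg.n_per_group[group]):
            aid = f"{group}{i + 1:02d}"
            test = float(np.clip(rng.normal(cfg.test_cs_mean, cfg.test_cs_sd),
                                 *cfg.test_cs_range))
            animal_rows.append((aid, group, test))
            for s in range(1, cfg.max_sessions + 1):
                base = test * np.exp(-rate * (s - 1))
                noise = rng.normal(0, cfg.tone_noise_sd,
                                   size=cfg.tones_per_session)
                vals = np.clip(base + noise, 0.0, 100.0)
                for k, v in enumerate(vals, start=1):
                    ext_rows.append((aid, s, k, float(v)))
            final = test * np.exp(-rate * (cfg.max_sessions - 1))

            def probe(increment: dict[str, float]) -> float:
                v = final + increment[group] + rng.normal(0, cfg.tone_noise_sd)
                return float(np.clip(v, 0.0, 100.0))

            probe_rows.append((aid,
                               probe(cfg.renewal_increment),
                               probe(cfg.remote_increment),
                               probe(cfg.reinstatement_increment)))

    return FreezingDataset(
        animals=pd.DataFrame(animal_rows,
                             columns=["animal_id", "group", "test_cs_freezing"]),
        extinction=pd.DataFrame(ext_rows,
                                columns=["animal_id", "session", "tone",
                                         "freezing_pct"]),
        probes=pd.DataFrame(probe_rows,
                            columns=["animal_id", "renewal_pct", "remote_pct",
                                     "reinstatement_pct"]),
        seed=seed)
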