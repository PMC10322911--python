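"""Version-pinned benchmark fixtures.

``PAPER_REGIME`` is the packaged 30-minute NREM-dominated LFP fixture the
detection-rate and latency regime checks run on: 0.35 ripples/s in NREM,
log-normal amplitudes with median 5 SD and 10% of events below 3 SD
(σ_ln = (ln 5 − ln 3)/z₀.₉₀), shared broadband artifacts at 0.05/s with
8 SD amplitude, seeds 1–10. These parameters are fixed in version
control so regime summaries are stable across releases; they are a
calibrated stand-in for recordings whose true event statistics were
never published, not an estimate of any animal's physiology.

``run_benchmark_session`` executes the scoring pipeline the regime
checks share: synthesize → calibrate on the first 60 s → stream detect →
offline detect (clean signal) → match at 50 ms tolerance → rates and
latencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DetectionConfig, OfflineConfig, SessionConfig, StateConfig
from .evaluate import (DetectionRates, LatencySummary, detection_rates,
                       match_triggers, trigger_latencies)
from .offline import detect_offline
from .online import TriggerLog, calibrate_thresholds, stream_detect
from .synth import SyntheticSession, synthesize_recording

PAPER_REGIME = SessionConfig(
    duration_s=1800.0,
    sampling_rate_hz=500,
    state=StateConfig(mean_dwell_nrem_s=480.0, mean_dwell_rem_s=60.0,
                      mean_dwell_wake_s=90.0, start_state="NREM"),
    ripple_rate_hz=0.35,
    amplitude_median_z=5.0,
    amplitude_sigma_ln=0.39860,   # puts 10% of events below 3 SD
    artifact_rate_hz=0.05,
    artifact_amplitude_z=8.0,
)

BENCHMARK_SEEDS = tuple(range(1, 11))

#: Behavior fixture: closed-loop decay 2× the non-stimulated rate,
#: per-tone noise SD 5, nine animals per group (see BehaviorGenConfig
#: defaults, which ARE this fixture).
BEHAVIOR_SEEDS = tuple(range(1, 21))

CALIBRATION_S = 60.0
MATCH_TOLERANCE_S = 0.050


@dataclass
class SessionScore:
    """Per-session detection scoring on the benchmark."""

    seed: int
    rates: DetectionRates
    latency: LatencySummary
    n_truth: int
    n_offline: int
    n_fired: int
    n_vetoed: int


def run_benchmark_session(seed: int,
                          session_config: SessionConfig = PAPER_REGIME,
                          detection_config: DetectionConfig | None = None,
                          offline_config: OfflineConfig | None = None,
                          session: SyntheticSession | None = None
                          ) -> SessionScore:
    """Score one benchmark session (online vs offline reference)."""
    det_cfg = detection_config or DetectionConfig()
    off_cfg = offline_config or OfflineConfig()
    if session is None:
        session = synthesize_recording(session_config, seed)
    fs = session.sampling_rate_hz
    n = session.lfp.shape[1]
    n_cal = int(CALIBRATION_S * fs)
    baseline = np.vstack([session.ripple_channel[:n_cal],
                          session.noise_channel[:n_cal]])
    thresholds = calibrate_thresholds(baseline, det_cfg)
    log = stream_detect(session, thresholds, det_cfg)
    # gold standard and scoring restricted to NREM (ground-truth labels
    # stand in for sleep scoring + manual curation): SWRs are NREM events
    nrem = session.states.mask("NREM", n, fs)
    events = detect_offline(session.ripple_channel, off_cfg, valid_mask=nrem)
    nrem_log = TriggerLog(
        entries=[t for t in log.entries
                 if nrem[min(int(t.crossing_time_s * fs), n - 1)]],
        config=log.config)
    table = match_triggers(nrem_log, events, tolerance_s=MATCH_TOLERANCE_S)
    return SessionScore(
        seed=seed,
        rates=detection_rates(table),
        latency=trigger_latencies(table),
        n_truth=len(session.truth),
        n_offline=len(events),
        n_fired=len(log.fired()),
        n_vetoed=sum(t.disposition == "VETOED" for t in log.entries))


def run_benchmark(seeds=BENCHMARK_SEEDS, **kwargs) -> list[SessionScore]:
    return [run_benchmark_session(s, **kwargs) for s in seeds]


def mean_rates(scores: list[SessionScore]) -> tuple[float, float, float]:
    """Across-session mean (PD, FPD, MD) percentages."""
    pd_ = float(np.mean([s.rates.pd_pct for s in scores]))
    fpd = float(np.mean([s.rates.fpd_pct for s in scores]))
    md = float(np.mean([s.rates.md_pct for s in scores]))
    return pd_, fpd, md


def pooled_latency_mode_ms(scores: list[SessionScore]) -> float:
    """Left edge (ms) of the modal 1 ms bin of pooled PD latencies."""
    lats = np.concatenate([s.latency.latencies_s for s in scores])
    edges = np.arange(np.floor(lats.min() * 1000),
                      np.ceil(lats.max() * 1000) + 1)
    counts, _ = np.histogram(lats * 1000, bins=edges)
    return float(edges[int(np.argmax(counts))])
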