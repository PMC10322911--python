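"""End-to-end driver: simulate → detect → stimulate → score → behavior.

``run_pipeline`` chains every stage, writes all intermediate tables under
an output directory, and returns a JSON-serializable report carrying the
full configuration, a config hash, and the seeds, so a rerun with the
same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config as cfgmod
from . import io as bundle_io
from .behavior import group_summary, summarize_dataset
from .config import (BehaviorConfig, BehaviorGenConfig, DetectionConfig,
                     OfflineConfig, SessionConfig, StimProtocol)
from .benchmark import CALIBRATION_S, MATCH_TOLERANCE_S
from .errors import PipelineStageError, SwrLoopError
from .evaluate import (detection_rates, match_triggers, sleep_architecture,
                       trigger_latencies)
from .offline import decimate_raw, detect_offline
from .online import (calibrate_thresholds, render_stimulus_artifact,
                     schedule_stimulation, stream_detect)
from .synth import generate_freezing_dataset, synthesize_recording


@dataclass(frozen=True)
class PipelineConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    offline: OfflineConfig = field(default_factory=OfflineConfig)
    protocol: StimProtocol = field(default_factory=StimProtocol.mfb_train)
    behavior_gen: BehaviorGenConfig = field(default_factory=BehaviorGenConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    lfp_seed: int = 1
    behavior_seed: int = 1
    artifact_gain: float = 1.0
    match_tolerance_s: float = MATCH_TOLERANCE_S

    def to_dict(self) -> dict:
        return {
            "session": cfgmod.to_dict(self.session),
            "detection": cfgmod.to_dict(self.detection),
            "offline": cfgmod.to_dict(self.offline),
            "protocol": cfgmod.to_dict(self.protocol),
            "behavior_gen": cfgmod.to_dict(self.behavior_gen),
            "behavior": cfgmod.to_dict(self.behavior),
            "lfp_seed": self.lfp_seed,
            "behavior_seed": self.behavior_seed,
            "artifact_gain": self.artifact_gain,
            "match_tolerance_s": self.match_tolerance_s,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SwrLoopError as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full closed-loop simulation and analysis chain.

    Stages: synthesize LFP → write bundle → calibrate thresholds on the
    first 60 s → stream detect → schedule stimulation → render stimulus
    artifacts → (decimate if raw) → offline detect with stimulation
    blanking → match/score → behavior generation and remission summary.
    Returns the report dict (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    session = _stage("synthesize")(synthesize_recording)(
        config.session, config.lfp_seed)
    bundle_io.write_recording(session, out / "recording")

    fs = session.sampling_rate_hz
    n_cal = int(CALIBRATION_S * fs)
    if session.sampling_rate_hz != config.detection.online_rate_hz:
        online_lfp = _stage("decimate")(decimate_raw)(
            session.lfp, session.sampling_rate_hz,
            config.detection.online_rate_hz)
        fs_online = config.detection.online_rate_hz
        n_cal = int(CALIBRATION_S * fs_online)
    else:
        online_lfp = session.lfp
        fs_online = fs

    ripple = online_lfp[session.channel_roles["ripple_channel"]]
    noise = online_lfp[session.channel_roles["noise_channel"]]
    baseline = np.vstack([ripple[:n_cal], noise[:n_cal]])
    thresholds = _stage("calibrate")(calibrate_thresholds)(
        baseline, config.detection)
    log = _stage("stream_detect")(stream_detect)(
        np.vstack([ripple, noise]), thresholds, config.detection)
    bundle_io.write_triggers(log, out / "triggers.csv")

    trains = _stage("schedule_stimulation")(schedule_stimulation)(
        log, config.protocol)
    bundle_io.write_trains(trains, out / "trains.csv")

    contaminated = _stage("render_artifact")(render_stimulus_artifact)(
        np.vstack([ripple, noise]), trains, fs_online, config.artifact_gain)
    events = _stage("detect_offline")(detect_offline)(
        contaminated[0], config.offline, stim_trains=trains or None)
    bundle_io.write_events(events, out / "events.csv")

    table = _stage("match")(match_triggers)(
        log, events, tolerance_s=config.match_tolerance_s)
    rates = _stage("rates")(detection_rates)(table)
    latency = trigger_latencies(table)
    architecture = sleep_architecture(session.states)

    dataset = _stage("behavior_generate")(generate_freezing_dataset)(
        config.behavior_gen, config.behavior_seed)
    dataset.extinction.to_csv(out / "freezing.csv", index=False)
    results = _stage("behavior_summarize")(summarize_dataset)(
        dataset, config.behavior)
    summary = group_summary(results)
    summary.to_csv(out / "behavior_summary.csv", index=False)

    report = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seeds": {"lfp": config.lfp_seed, "behavior": config.behavior_seed},
        "counts": {
            "ground_truth_ripples": len(session.truth),
            "offline_events": len(events),
            "fired_triggers": len(log.fired()),
            "vetoed": sum(t.disposition == "VETOED" for t in log.entries),
            "locked_out": sum(t.disposition == "LOCKED_OUT"
                              for t in log.entries),
            "stim_trains": len(trains),
        },
        "rates_pct": {"PD": rates.pd_pct, "FPD": rates.fpd_pct,
                      "MD": rates.md_pct},
        "latency_ms": {
            "n": int(latency.latencies_s.size),
            "min": None if latency.empty else latency.min_s * 1000,
            "max": None if latency.empty else latency.max_s * 1000,
            "modal_bin": None if latency.empty else
                [e * 1000 for e in latency.modal_bin_s],
            "histogram_counts": latency.counts.tolist(),
            "bin_edges_ms": (latency.bin_edges_s * 1000).tolist(),
        },
        "sleep_architecture": architecture,
        "behavior": summary.to_dict(orient="records"),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
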