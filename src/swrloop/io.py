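"""Recording bundles and delimited-text tables.

A recording bundle is a directory holding the LFP as flat
channel-interleaved little-endian int16 (``lfp.dat``, frame = one sample
per channel, Amplipex-style) with a JSON sidecar (``metadata.json``:
channel count, sample count, sampling rate, µV/bit, channel roles, seed)
plus optional ground-truth/state/artifact tables as CSV with headers and
explicit units in the column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptBundleError
from .config import VALID_RATES
from .offline import RippleEvent
from .online import FIRED, StimTrain, TriggerLog
from .synth import GroundTruthRipple, StateSequence, SyntheticSession

DEFAULT_UV_PER_BIT = 0.05  # ±1638 µV full scale

LFP_FILE = "lfp.dat"
META_FILE = "metadata.json"


def write_recording(session: SyntheticSession, path: str | Path,
                    uv_per_bit: float = DEFAULT_UV_PER_BIT) -> Path:
    """Write a session as an int16 bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    quantized = np.clip(np.round(session.lfp / uv_per_bit),
                        -32768, 32767).astype("<i2")
    quantized.T.tofile(path / LFP_FILE)  # .T → channel-interleaved frames

    meta = {
        "n_channels": int(session.lfp.shape[0]),
        "n_samples": int(session.lfp.shape[1]),
        "sampling_rate_hz": int(session.sampling_rate_hz),
        "uv_per_bit": float(uv_per_bit),
        "channel_roles": session.channel_roles,
        "seed": int(session.seed),
        "baseline_band_sd_uv": float(session.baseline_band_sd_uv),
    }
    (path / META_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True))

    pd.DataFrame([(r.onset_s, r.peak_s, r.offset_s, r.amplitude_z,
                   r.center_freq_hz) for r in session.truth],
                 columns=["onset_s", "peak_s", "offset_s", "amplitude_z",
                          "center_freq_hz"]).to_csv(path / "truth.csv",
                                                    index=False,
                                                    float_format="%.17g")
    pd.DataFrame(session.artifacts, columns=["start_s", "end_s"]).to_csv(
        path / "artifacts.csv", index=False, float_format="%.17g")
    pd.DataFrame(list(session.states.epochs),
                 columns=["start_s", "end_s", "state"]).to_csv(
        path / "states.csv", index=False, float_format="%.17g")
    return path


def read_recording(path: str | Path) -> SyntheticSession:
    """Read a bundle back; inverse of :func:`write_recording`."""
    path = Path(path)
    meta_path = path / META_FILE
    if not meta_path.exists():
        raise CorruptBundleError(f"missing {META_FILE} in {path}")
    meta = json.loads(meta_path.read_text())
    n_ch, n_samp = meta["n_channels"], meta["n_samples"]
    if meta["sampling_rate_hz"] not in VALID_RATES:
        raise CorruptBundleError(
            f"unsupported sampling rate {meta['sampling_rate_hz']}")
    expected = n_ch * n_samp * 2
    actual = (path / LFP_FILE).stat().st_size
    if actual != expected:
        raise CorruptBundleError(
            f"{LFP_FILE} is {actual} bytes, metadata implies {expected}")
    raw = np.fromfile(path / LFP_FILE, dtype="<i2").reshape(n_samp, n_ch).T
    lfp = raw.astype(float) * meta["uv_per_bit"]

    def _table(name, builder, default):
        f = path / name
        if not f.exists():
            return default
        df = pd.read_csv(f, float_precision="round_trip")
        return builder(df) if len(df) else default

    truth = _table("truth.csv", lambda df: [
        GroundTruthRipple(*row) for row in df.itertuples(index=False)], [])
    artifacts = _table("artifacts.csv", lambda df: [
        (r.start_s, r.end_s) for r in df.itertuples(index=False)], [])
    states = _table("states.csv", lambda df: StateSequence(epochs=tuple(
        (r.start_s, r.end_s, r.state) for r in df.itertuples(index=False))),
        StateSequence(epochs=((0.0, n_samp / meta["sampling_rate_hz"],
                               "NREM"),)))

    return SyntheticSession(
        lfp=lfp, sampling_rate_hz=meta["sampling_rate_hz"],
        channel_roles=meta["channel_roles"], truth=truth,
        artifacts=artifacts, states=states, seed=meta.get("seed", 0),
        baseline_band_sd_uv=meta.get("baseline_band_sd_uv", float("nan")))


# --- tables ----------------------------------------------------------------

def write_triggers(log: TriggerLog, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([(t.crossing_time_s, t.trigger_time_s, t.disposition)
                  for t in log.entries],
                 columns=["crossing_s", "trigger_s", "disposition"]
                 ).to_csv(path, index=False)
    return path


def read_fired_times(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.loc[df.disposition == FIRED, "trigger_s"].to_numpy()


def write_events(events: list[RippleEvent], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([(e.onset_s, e.peak_s, e.offset_s, e.peak_z)
                  for e in events],
                 columns=["onset_s", "peak_s", "offset_s", "peak_z"]
                 ).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[RippleEvent]:
    df = pd.read_csv(path)
    return [RippleEvent(r.onset_s, r.peak_s, r.offset_s, r.peak_z)
            for r in df.itertuples(index=False)]


def write_trains(trains: list[StimTrain], path: str | Path) -> Path:
    path = Path(path)
    rows = [(t.start_s, t.pulse_width_s,
             ";".join(f"{p:.6f}" for p in t.pulse_onsets_s)) for t in trains]
    pd.DataFrame(rows, columns=["train_start_s", "pulse_width_s",
                                "pulse_onsets_s"]).to_csv(path, index=False)
    return path
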