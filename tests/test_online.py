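"""Streaming detector: calibration, state machine, causality, latency."""

import numpy as np
import pytest
from scipy import signal

import swrloop as sl
from swrloop.errors import DegenerateSignalError, InvalidConfigError
from swrloop.online import FIRED, LOCKED_OUT, VETOED, causal_bandpass_sos

from helpers import batch_detect_oracle


def _two_channel(n, rng=None, sd=1.0):
    if rng is None:
        return np.zeros((2, n))
    return rng.standard_normal((2, n)) * sd


class TestCalibration:
    def test_zero_baseline_raises_unless_allowed(self):
        cfg = sl.DetectionConfig()
        base = _two_channel(40_000)
        with pytest.raises(DegenerateSignalError):
            sl.calibrate_thresholds(base, cfg)
        th = sl.calibrate_thresholds(base, cfg, allow_degenerate=True)
        assert th.ripple_rms_threshold == 0.0

    def test_pure_tone_threshold_near_rms(self):
        """A long 200 Hz sinusoid has an (almost) constant RMS trace, so
        threshold ≈ passband gain × A/√2."""
        cfg = sl.DetectionConfig()
        fs = cfg.online_rate_hz
        amp = 50.0
        t = np.arange(70 * fs) / fs
        tone = amp * np.sin(2 * np.pi * 200.0 * t)
        base = np.vstack([tone, tone])
        th = sl.calibrate_thresholds(base, cfg)
        w, h = signal.sosfreqz(causal_bandpass_sos(cfg.ripple_band_hz, cfg),
                               worN=[200.0], fs=fs)
        expected = abs(h[0]) * amp / np.sqrt(2)
        assert th.baseline_sd[0] < 0.05 * th.baseline_mean[0]
        assert th.ripple_rms_threshold == pytest.approx(expected, rel=0.05)

    def test_matches_batch_moment_oracle(self, benchmark_session):
        """Threshold equals mean+4·SD computed independently over the
        whole filtered-RMS vector (±1%)."""
        cfg = sl.DetectionConfig()
        fs = cfg.online_rate_hz
        base = np.vstack([benchmark_session.ripple_channel[:60 * fs],
                          benchmark_session.noise_channel[:60 * fs]])
        th = sl.calibrate_thresholds(base, cfg)

        w = int(cfg.rms_window_s * fs)
        sos = causal_bandpass_sos(cfg.ripple_band_hz, cfg)
        filt = signal.sosfilt(sos, base[0])
        sq = np.concatenate([np.zeros(w - 1), filt ** 2])
        c = np.concatenate([[0.0], np.cumsum(sq)])
        rms = np.sqrt((c[w:] - c[:-w]) / w)[int(0.5 * fs):]
        expected = rms.mean() + cfg.threshold_k_ripple * rms.std()
        assert th.ripple_rms_threshold == pytest.approx(expected, rel=0.01)

    def test_short_baseline_rejected(self):
        with pytest.raises(InvalidConfigError):
            sl.calibrate_thresholds(_two_channel(1000), sl.DetectionConfig())


def _ripple_session(fs=500, dur_s=120.0, events=((60.0, 8.0),),
                    noise_burst_at=None, seed=0):
    """White-noise two-channel array with Hanning ripples on channel 0."""
    rng = np.random.default_rng(seed)
    n = int(dur_s * fs)
    lfp = rng.standard_normal((2, n)) * 20.0
    sos = signal.butter(2, (150, 237.5), btype="bandpass", fs=fs,
                        output="sos")
    band_sd = signal.sosfiltfilt(sos, lfp[0]).std()
    m = int(0.060 * fs)
    t = np.arange(m) / fs
    for at, amp in events:
        i0 = int(at * fs)
        lfp[0, i0:i0 + m] += (amp * band_sd * np.hanning(m)
                              * np.sin(2 * np.pi * 180.0 * t))
    if noise_burst_at is not None:
        i0 = int(noise_burst_at * fs)
        burst = rng.standard_normal(m) * 10.0 * band_sd * np.hanning(m)
        lfp[0, i0:i0 + m] += burst
        lfp[1, i0:i0 + m] += burst
    return lfp


class TestStreamDetect:
    def _detect(self, lfp, **cfg_kwargs):
        cfg = sl.DetectionConfig(**cfg_kwargs)
        th = sl.calibrate_thresholds(lfp[:, :60 * 500], cfg)
        return sl.stream_detect(lfp, th, cfg), cfg

    def test_single_ripple_fires_once_inside_event(self):
        lfp = _ripple_session(events=((80.0, 8.0),))
        log, cfg = self._detect(lfp)
        fired = [t for t in log.entries if t.disposition == FIRED
                 and 79.9 < t.crossing_time_s < 80.2]
        assert len(fired) == 1
        assert 80.0 <= fired[0].crossing_time_s <= 80.060
        assert fired[0].trigger_time_s == pytest.approx(
            fired[0].crossing_time_s + cfg.processing_latency_s)

    def test_concurrent_noise_burst_vetoes(self):
        """A ripple-band crossing during a shared broadband transient is
        vetoed: detection requires absence of the noise signal."""
        lfp = _ripple_session(events=(), noise_burst_at=80.0)
        log, _ = self._detect(lfp)
        near = [t for t in log.entries if 79.9 < t.crossing_time_s < 80.2]
        assert near and all(t.disposition == VETOED for t in near)

    def test_lockout_suppresses_second_ripple(self):
        lfp = _ripple_session(events=((80.0, 8.0), (80.110, 8.0)))
        log, _ = self._detect(lfp, lockout_s=0.200)
        near = [t for t in log.entries if 79.9 < t.crossing_time_s < 80.4]
        assert [t.disposition for t in near] == [FIRED, LOCKED_OUT]

    def test_fired_spacing_respects_lockout(self, benchmark_session):
        cfg = sl.DetectionConfig()
        fs = cfg.online_rate_hz
        base = np.vstack([benchmark_session.ripple_channel[:60 * fs],
                          benchmark_session.noise_channel[:60 * fs]])
        th = sl.calibrate_thresholds(base, cfg)
        log = sl.stream_detect(benchmark_session, th, cfg)
        fired = log.fired_times()
        assert np.all(np.diff(fired) >= cfg.lockout_s - 1e-9)

    def test_missing_channel_roles_rejected(self, benchmark_session):
        cfg = sl.DetectionConfig()
        th = sl.calibrate_thresholds(
            np.vstack([benchmark_session.ripple_channel[:30_000],
                       benchmark_session.noise_channel[:30_000]]), cfg)
        broken = sl.SyntheticSession(
            lfp=benchmark_session.lfp,
            sampling_rate_hz=benchmark_session.sampling_rate_hz,
            channel_roles={"ripple_channel": 0},  # noise channel deleted
            truth=[], artifacts=[], states=benchmark_session.states, seed=0)
        with pytest.raises(InvalidConfigError):
            sl.stream_detect(broken, th, cfg)

    def test_streaming_equals_batch_oracle(self, benchmark_session):
        cfg = sl.DetectionConfig()
        fs = cfg.online_rate_hz
        s = benchmark_session
        th = sl.calibrate_thresholds(
            np.vstack([s.ripple_channel[:60 * fs],
                       s.noise_channel[:60 * fs]]), cfg)
        log = sl.stream_detect(s, th, cfg, chunk_s=0.731)  # awkward chunking
        got = [(int(round(t.crossing_time_s * fs)), t.disposition)
               for t in log.entries]
        want = batch_detect_oracle(s.ripple_channel, s.noise_channel, th, cfg)
        assert got == want

    def test_causality_under_truncation(self):
        """Truncating the input never changes triggers emitted before the
        truncation point."""
        lfp = _ripple_session(events=((70.0, 8.0), (90.0, 6.0), (110.0, 9.0)))
        cfg = sl.DetectionConfig()
        th = sl.calibrate_thresholds(lfp[:, :60 * 500], cfg)
        full = sl.stream_detect(lfp, th, cfg).entries
        for cut_s in (75.0, 95.3, 100.017):
            cut = int(cut_s * 500)
            part = sl.stream_detect(lfp[:, :cut], th, cfg).entries
            expected = [t for t in full if t.crossing_time_s < cut_s]
            assert part == expected

    def test_latency_shifts_with_processing_latency(self):
        lfp = _ripple_session(events=((70.0, 8.0), (90.0, 6.0)))
        cfg0 = sl.DetectionConfig()
        cfg5 = sl.DetectionConfig(processing_latency_s=0.015)
        th = sl.calibrate_thresholds(lfp[:, :60 * 500], cfg0)
        t0 = sl.stream_detect(lfp, th, cfg0).fired_times()
        t5 = sl.stream_detect(lfp, th, cfg5).fired_times()
        assert np.allclose(t5 - t0, 0.005)


class TestStimulation:
    def test_mfb_train_structure(self):
        log = sl.TriggerLog(entries=[sl.Trigger(1.0, 1.010, FIRED)],
                            config=sl.DetectionConfig())
        trains = sl.schedule_stimulation(log, sl.StimProtocol.mfb_train())
        assert len(trains) == 1
        onsets = np.array(trains[0].pulse_onsets_s)
        assert onsets.size == 14
        assert np.allclose(np.diff(onsets), 1 / 140)
        assert onsets[-1] - onsets[0] == pytest.approx(13 / 140)
        assert trains[0].pulse_width_s == 0.001

    def test_vhc_single_pulse(self):
        log = sl.TriggerLog(entries=[sl.Trigger(1.0, 1.010, FIRED)],
                            config=sl.DetectionConfig())
        trains = sl.schedule_stimulation(log, sl.StimProtocol.vhc_pulse(10.0))
        assert len(trains) == 1
        assert trains[0].pulse_onsets_s == (1.010,)
        assert trains[0].pulse_width_s == 0.0005

    def test_empty_log_and_bad_protocol(self):
        log = sl.TriggerLog(entries=[], config=sl.DetectionConfig())
        assert sl.schedule_stimulation(log, sl.StimProtocol.mfb_train()) == []
        with pytest.raises(InvalidConfigError):
            sl.schedule_stimulation(log, sl.StimProtocol(kind="BURST"))
        with pytest.raises(InvalidConfigError):
            sl.StimProtocol.vhc_pulse(20.0)

    def test_artifact_rendering_local_and_gain_zero(self, rng):
        lfp = rng.standard_normal((2, 5000)) * 10
        log = sl.TriggerLog(entries=[sl.Trigger(4.0, 4.010, FIRED)],
                            config=sl.DetectionConfig())
        trains = sl.schedule_stimulation(log, sl.StimProtocol.mfb_train())
        assert np.array_equal(
            sl.render_stimulus_artifact(lfp, trains, 500, 0.0), lfp)
        out = sl.render_stimulus_artifact(lfp, trains, 500, 1.0)
        i0 = int(4.010 * 500)
        i1 = int((4.010 + 13 / 140 + 0.001) * 500) + 1
        assert not np.array_equal(out[:, i0:i1], lfp[:, i0:i1])
        pre = slice(0, i0 - 3)
        post = slice(i1 + 3, None)
        assert np.array_equal(out[:, pre], lfp[:, pre])
        assert np.array_equal(out[:, post], lfp[:, post])
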