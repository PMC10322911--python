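"""Synthetic LFP and behavior generators: structure, distributions, seeds."""

import numpy as np
import pytest
from scipy import stats

import swrloop as sl
from swrloop.config import BehaviorGenConfig, SessionConfig, StateConfig
from swrloop.errors import InvalidConfigError

from helpers import band_power, renewal_nrem_fraction_oracle


class TestStateSequence:
    def test_nrem_only_config_yields_single_epoch(self):
        cfg = StateConfig(mean_dwell_nrem_s=100.0, mean_dwell_rem_s=0.0,
                          mean_dwell_wake_s=0.0)
        seq = sl.generate_state_sequence(3600.0, cfg, seed=3)
        assert seq.epochs == ((0.0, 3600.0, "NREM"),)

    def test_seed_determinism(self):
        cfg = StateConfig()
        a = sl.generate_state_sequence(3600.0, cfg, seed=11)
        b = sl.generate_state_sequence(3600.0, cfg, seed=11)
        assert a.epochs == b.epochs
        c = sl.generate_state_sequence(3600.0, cfg, seed=12)
        assert c.epochs != a.epochs

    def test_epochs_contiguous_and_labelled(self):
        seq = sl.generate_state_sequence(3600.0, StateConfig(), seed=5)
        seq.validate()  # sorted, contiguous, known labels
        assert seq.duration_s == pytest.approx(3600.0)

    @pytest.mark.parametrize("bad", [
        dict(mean_dwell_nrem_s=-1.0),
        dict(mean_dwell_nrem_s=0.0, mean_dwell_rem_s=0.0,
             mean_dwell_wake_s=0.0),
        dict(start_state="SWS"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            sl.generate_state_sequence(100.0, StateConfig(**bad), seed=0)
        with pytest.raises(InvalidConfigError):
            sl.generate_state_sequence(-5.0, StateConfig(), seed=0)

    def test_nrem_fraction_matches_renewal_oracle(self):
        """Empirical NREM fraction agrees (±5 points) with brute-force
        epoch accumulation at 10× the simulation count."""
        cfg = StateConfig(mean_dwell_nrem_s=300.0, mean_dwell_rem_s=60.0,
                          mean_dwell_wake_s=120.0)
        fracs = []
        for seed in range(100):
            seq = sl.generate_state_sequence(3600.0, cfg, seed)
            nrem = sum(e - s for s, e, lab in seq.epochs if lab == "NREM")
            fracs.append(nrem / 3600.0)
        oracle = renewal_nrem_fraction_oracle(3600.0, 300.0, 60.0, 120.0,
                                              n_sims=1000, seed=999)
        assert abs(np.mean(fracs) - oracle) < 0.05


class TestSynthesizeRecording:
    def test_zero_ripple_rate_yields_empty_truth(self):
        cfg = SessionConfig(duration_s=120.0, ripple_rate_hz=0.0,
                            artifact_rate_hz=0.0)
        session = sl.synthesize_recording(cfg, 1)
        assert session.truth == []

    @pytest.mark.parametrize("bad", [dict(ripple_rate_hz=-0.1),
                                     dict(sampling_rate_hz=1000)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            sl.synthesize_recording(SessionConfig(**bad), 1)

    def test_poisson_event_counts(self):
        """Truth counts over pure NREM stay within 3√λ of the Poisson
        mean (the 100 ms dead time between peaks trims only a few %)."""
        cfg = SessionConfig(
            duration_s=1800.0, ripple_rate_hz=0.35, artifact_rate_hz=0.0,
            state=StateConfig(mean_dwell_nrem_s=100.0, mean_dwell_rem_s=0.0,
                              mean_dwell_wake_s=0.0))
        lam = 0.35 * 1800.0
        counts = [len(sl.synthesize_recording(cfg, seed).truth)
                  for seed in range(20)]
        assert all(abs(c - lam) < 3 * np.sqrt(lam) for c in counts)

    def test_ripples_only_in_nrem_on_ripple_channel(self, benchmark_session):
        s = benchmark_session
        for r in s.truth:
            assert s.states.label_at(r.onset_s) == "NREM"
            assert s.states.label_at(max(r.offset_s - 1e-3, 0)) == "NREM"
            assert r.onset_s < r.peak_s < r.offset_s
            assert 0.020 <= r.duration_s <= 0.120
        # ripple-band power is elevated on the ripple channel only
        fs = s.sampling_rate_hz
        ratios_r, ratios_n = [], []
        for r in s.truth[:80]:
            i0, i1 = int(r.onset_s * fs), int(r.offset_s * fs)
            m = i1 - i0
            j0 = i0 - 4 * m  # nearby pre-event window, same length
            if j0 < 0:
                continue
            for ch, out in ((s.ripple_channel, ratios_r),
                            (s.noise_channel, ratios_n)):
                ev = band_power(ch[i0:i1], fs, 150, 250)
                bg = band_power(ch[j0:j0 + m], fs, 150, 250)
                out.append(ev / bg)
        assert np.median(ratios_r) > 2.0   # events stand out in-band
        assert np.median(ratios_n) < 2.0   # reference channel does not

    def test_artifacts_on_both_channels(self, benchmark_session):
        s = benchmark_session
        fs = s.sampling_rate_hz
        assert len(s.artifacts) > 0
        # pooled power inside artifact windows is elevated on BOTH channels
        mask = np.zeros(s.lfp.shape[1], dtype=bool)
        for start, end in s.artifacts:
            mask[int(start * fs):int(end * fs)] = True
        for ch in (s.ripple_channel, s.noise_channel):
            inside = np.mean(ch[mask] ** 2)
            outside = np.mean(ch[~mask] ** 2)
            assert inside > 1.5 * outside

    def test_amplitudes_match_lognormal(self):
        """Kolmogorov–Smirnov distance to the configured log-normal < 0.1
        at n ≥ 500 (amplitudes pooled over fixture seeds)."""
        amps = []
        for seed in sl.BENCHMARK_SEEDS[:3]:
            s = sl.synthesize_recording(sl.PAPER_REGIME, seed)
            amps.extend(r.amplitude_z for r in s.truth)
        amps = np.asarray(amps[:1000])
        assert amps.size >= 500
        dist = stats.lognorm(s=sl.PAPER_REGIME.amplitude_sigma_ln,
                             scale=sl.PAPER_REGIME.amplitude_median_z)
        ks = stats.kstest(amps, dist.cdf).statistic
        assert ks < 0.1

    def test_seed_determinism(self):
        cfg = SessionConfig(duration_s=90.0)
        a = sl.synthesize_recording(cfg, 42)
        b = sl.synthesize_recording(cfg, 42)
        assert np.array_equal(a.lfp, b.lfp)
        assert a.truth == b.truth and a.artifacts == b.artifacts


class TestFreezingGenerator:
    def test_remission_day_matches_closed_form(self):
        """Zero-noise decay crosses the 20% remission line on the day the
        closed form predicts: reduction(s) = 100·exp(−rate·(s−1))."""
        rate = np.log(6) / 2  # day-3 reduction 100/6 ≈ 16.7% < 20, day-2 ≈ 40.8%
        cfg = BehaviorGenConfig(
            n_per_group={"NS": 1}, decay_rate={"NS": rate},
            test_cs_sd=0.0, test_cs_mean=80.0, tone_noise_sd=0.0,
            renewal_increment={"NS": 0.0}, remote_increment={"NS": 0.0},
            reinstatement_increment={"NS": 0.0})
        ds = sl.generate_freezing_dataset(cfg, 1)
        results = sl.summarize_dataset(ds)
        assert results[0].remission_day == 3
        assert results[0].reductions_pct[0] == pytest.approx(100.0)

    def test_values_clipped_and_structured(self):
        ds = sl.generate_freezing_dataset(BehaviorGenConfig(tone_noise_sd=40.0), 2)
        f = ds.extinction.freezing_pct
        assert f.between(0, 100).all()
        per = ds.extinction.groupby(["animal_id", "session"]).size()
        assert (per == 20).all()
        assert ds.extinction.session.max() <= 7

    def test_seed_determinism(self):
        a = sl.generate_freezing_dataset(BehaviorGenConfig(), 9)
        b = sl.generate_freezing_dataset(BehaviorGenConfig(), 9)
        assert a.extinction.equals(b.extinction)
        assert a.probes.equals(b.probes)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            sl.generate_freezing_dataset(
                BehaviorGenConfig(tone_noise_sd=-1.0), 1)
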