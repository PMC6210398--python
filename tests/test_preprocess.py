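"""Preprocessing tests: line removal, epoching, rejection, ICA, resampling."""

import numpy as np
import pandas as pd
import pytest

from boundless import preprocess
from boundless.config import AnalysisConfig
from boundless.io import RawRecording
from boundless.sensors import fibonacci_cap_array
from boundless.simulate import reduced_config, simulate_recording


def _toy_raw(signal_rows, sfreq=1000.0, labels=("SB1",), duration=None):
    data = np.atleast_2d(np.asarray(signal_rows, float))
    n_ch = data.shape[0]
    duration = duration or data.shape[1] / sfreq
    sensors = fibonacci_cap_array(n_ch, 0.1)
    sched = pd.DataFrame({
        "onset": [i * duration / len(labels) for i in range(len(labels))],
        "duration": [duration / len(labels)] * len(labels),
        "label": list(labels),
    })
    return RawRecording(data, sfreq, sensors, sched)


class TestLineNoise:
    def test_pure_line_sinusoid_removed(self):
        t = np.arange(0, 10, 1e-3)
        raw = _toy_raw([np.sin(2 * np.pi * 50 * t)])
        out = preprocess.remove_line_noise(raw, 50.0)
        assert np.sqrt((out.data**2).mean()) < 0.01 * np.sqrt((raw.data**2).mean())

    def test_signal_without_line_content_untouched(self, rng):
        # sum of record-periodic tones below 40 Hz: no 50 Hz content at all
        t = np.arange(5000) / 1000.0
        freqs = rng.choice(np.arange(2.0, 38.0, 0.2), 30, replace=False)
        phases = rng.uniform(0, 2 * np.pi, 30)
        x = np.sum([np.sin(2 * np.pi * f * t + ph)
                    for f, ph in zip(freqs, phases)], axis=0)
        raw = _toy_raw([x])
        out = preprocess.remove_line_noise(raw, 50.0)
        rel = np.sqrt(((out.data - raw.data) ** 2).mean()) / np.sqrt((raw.data**2).mean())
        assert rel < 1e-3

    def test_mixture_preserves_27hz_amplitude(self):
        t = np.arange(0, 10, 1e-3)
        x = 2.0 * np.sin(2 * np.pi * 27 * t) + 5.0 * np.sin(2 * np.pi * 50 * t)
        out = preprocess.remove_line_noise(_toy_raw([x]), 50.0)
        spec = np.fft.rfft(out.data[0])
        freqs = np.fft.rfftfreq(len(t), 1e-3)
        amp27 = 2 * np.abs(spec[np.argmin(np.abs(freqs - 27))]) / len(t)
        amp50 = 2 * np.abs(spec[np.argmin(np.abs(freqs - 50))]) / len(t)
        assert abs(amp27 - 2.0) < 0.02
        assert amp50 < 0.05

    def test_line_freq_above_nyquist_rejected(self):
        raw = _toy_raw([np.zeros(1000)], sfreq=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess.remove_line_noise(raw, 50.0)


class TestSegmentEpochs:
    def test_full_design_epoch_counts(self, rng):
        """60-s conditions with 3-s lead-in and 2-s epochs give 28 epochs
        per interval, 336 over 4 blocks x 3 conditions."""
        cfg = AnalysisConfig()
        sfreq = 64.0
        labels = ["SB1", "SB2", "SB3", "REST"] * 4
        raw = _toy_raw(rng.standard_normal((2, int(16 * 60 * sfreq))),
                       sfreq=sfreq, labels=labels)
        sb, rest = preprocess.segment_epochs(raw, cfg)
        assert sb.n_epochs == 336
        assert rest.n_epochs == 28 * 4
        assert set(np.unique(sb.block)) == {0, 1, 2, 3}
        assert sb.order_index.max() == 28 * 3  # within-block temporal rank

    def test_five_second_interval_single_epoch(self, rng):
        cfg = AnalysisConfig()
        raw = _toy_raw(rng.standard_normal((1, 5000)), sfreq=1000.0,
                       labels=["SB1"])
        sb, _ = preprocess.segment_epochs(raw, cfg)
        assert sb.n_epochs == 1

    def test_too_short_interval_raises(self, rng):
        cfg = AnalysisConfig()
        raw = _toy_raw(rng.standard_normal((1, 4000)), sfreq=1000.0,
                       labels=["SB1"])
        with pytest.raises(ValueError, match="too short"):
            preprocess.segment_epochs(raw, cfg)


class TestRejection:
    def test_clean_data_mostly_retained(self):
        """On artifact-free synthetic data, >= 95% of epochs survive
        rejection at z=5, pooled over 10 seeds."""
        cfg = AnalysisConfig()
        kept = total = 0
        for s in range(10):
            sim = reduced_config(seed=800 + s, n_channels=8,
                                 condition_len=12.0, rest_len=12.0)
            rec, _ = simulate_recording(sim)
            sb, _ = preprocess.segment_epochs(rec, cfg)
            out, _ = preprocess.reject_artifact_epochs(sb, 5.0)
            kept += out.n_epochs
            total += sb.n_epochs
        assert kept / total >= 0.95

    def test_injected_step_rejected(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        data = sb.data.copy()
        sd = data.std()
        data[5, 0, 100:] += 50 * sd
        bad = type(sb)(data, sb.sfreq, sb.condition, sb.block, sb.order_index,
                       sb.sensors, sb.start_sample)
        out, log = preprocess.reject_artifact_epochs(bad, 5.0)
        assert bool(log.loc[5, "rejected"])
        assert out.n_epochs == sb.n_epochs - int(log["rejected"].sum())

    def test_infinite_threshold_is_identity(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        out, _ = preprocess.reject_artifact_epochs(sb, np.inf)
        assert out.n_epochs == sb.n_epochs

    def test_rejection_idempotent(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        once, _ = preprocess.reject_artifact_epochs(sb, 5.0)
        twice, log = preprocess.reject_artifact_epochs(once, np.inf)
        assert twice.n_epochs == once.n_epochs


class TestDownsample:
    def test_acquisition_rate_sample_count(self, rng):
        """1017.25 -> 300 Hz turns 2-s (2034-sample) epochs into 600."""
        from boundless.io import EpochSet

        sensors = fibonacci_cap_array(2, 0.1)
        ep = EpochSet(rng.standard_normal((3, 2, 2034)), 1017.25,
                      np.array(["SB1"] * 3), np.zeros(3, int),
                      np.arange(3), sensors)
        out = preprocess.downsample(ep, 300.0)
        assert out.data.shape[2] == 600
        assert out.sfreq == 300.0

    def test_tone_survives_and_high_band_attenuated(self):
        from boundless.io import EpochSet

        sfreq = 1017.25
        t = np.arange(2034) / sfreq
        tone27 = np.sin(2 * np.pi * 27 * t)
        tone160 = np.sin(2 * np.pi * 160 * t)
        sensors = fibonacci_cap_array(2, 0.1)
        ep = EpochSet(np.stack([np.stack([tone27, tone160])] * 2), sfreq,
                      np.array(["SB1"] * 2), np.zeros(2, int),
                      np.arange(2), sensors)
        out = preprocess.downsample(ep, 300.0)
        spec = np.abs(np.fft.rfft(out.data[0], axis=-1))
        freqs = np.fft.rfftfreq(out.data.shape[2], 1 / 300.0)
        amp27 = 2 * spec[0, np.argmin(np.abs(freqs - 27))] / out.data.shape[2]
        assert abs(amp27 - 1.0) < 0.01
        # 160 Hz sits above the new Nyquist (150): attenuated >= 20 dB
        in_rms = np.sqrt((tone160**2).mean())
        out_rms = np.sqrt((out.data[0, 1] ** 2).mean())
        assert out_rms < in_rms / 10

    def test_upsampling_rejected(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        with pytest.raises(ValueError):
            preprocess.downsample(sb, 2 * sb.sfreq)


class TestICA:
    def test_toy_unmixing_recovers_sources(self, rng):
        """3 super-Gaussian sources mixed into 5 channels: recovered
        components match the sources at |r| >= 0.99 after matching."""
        from boundless.io import EpochSet

        n = 6000
        src = rng.laplace(size=(3, n))
        mix = rng.standard_normal((5, 3))
        data = (mix @ src).reshape(5, 10, n // 10).transpose(1, 0, 2)
        sensors = fibonacci_cap_array(5, 0.1)
        ep = EpochSet(data, 100.0, np.array(["SB1"] * 10),
                      np.zeros(10, int), np.arange(10), sensors)
        out, log = preprocess.ica_clean(ep, list(src), downsample_to=200.0,
                                        corr_thresh=0.99, seed=0)
        # rank-3 data: three components, each matching one source
        assert len(log) == 3
        assert (log["max_abs_template_corr"] >= 0.99).all()

    def test_component_count_equals_good_channels(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        rec.sensors.bad_channels = [rec.sensors.channel_names[0]]
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        _, log = preprocess.ica_clean(sb, [], seed=0)
        assert len(log) == rec.sensors.n_channels - 1

    def test_no_templates_identity_reconstruction(self, tiny_sim, analysis_cfg):
        _, rec, _ = tiny_sim
        sb, _ = preprocess.segment_epochs(rec, analysis_cfg)
        out, log = preprocess.ica_clean(sb, [], seed=0)
        assert not log["flagged"].any()
        rel = np.abs(out.data - sb.data).max() / np.abs(sb.data).max()
        assert rel < 1e-6

    def test_cardiac_component_flagged_and_correlated(self):
        """Injected cardiac artifact is flagged by template correlation and
        the flagged component tracks the true trace at |r| > 0.8 in >= 8/10
        seeds."""
        cfg = AnalysisConfig()
        hits = 0
        for s in range(10):
            sim = reduced_config(seed=s, n_channels=24, condition_len=12.0,
                                 rest_len=12.0, cardiac_amplitude=3e-7)
            rec, truth = simulate_recording(sim)
            sb, _ = preprocess.segment_epochs(rec, cfg)
            tpl = preprocess.slice_to_epochs(truth.cardiac_series, sb)
            _, log = preprocess.ica_clean(sb, [tpl], corr_thresh=0.5, seed=s)
            hits += (log["flagged"].any()
                     and log["max_abs_template_corr"].max() > 0.8)
        assert hits >= 8
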