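import numpy as np
import pytest

from vcsd.errors import DegenerateInputError
from vcsd.preprocessing import (
    SNIPPET_POST,
    SNIPPET_PRE,
    Recording,
    SpikeTrain,
    bandpass,
    detect_spikes,
    epoch_average,
    spike_triggered_average,
)

FS = 25_000.0


def make_recording(x, events=(), fs=FS, band="raw"):
    return Recording(samples=x, sampling_rate=fs,
                     event_times=np.asarray(events, float), band=band)


def tone(freq, dur=2.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_amplitude_preserved(self):
        rec = make_recording(tone(100.0))
        out = bandpass(rec, "lfp")
        mid = slice(10_000, 40_000)  # avoid filter edges
        ratio = out.samples[0, mid].std() / rec.samples[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_out_of_band_tone_attenuated(self):
        rec = make_recording(tone(4000.0))
        out = bandpass(rec, "lfp")
        mid = slice(10_000, 40_000)
        # project onto the quadrature pair at the tone frequency so the
        # low-frequency edge transients of the 1 Hz corner do not mask the
        # stop-band attenuation
        t = np.arange(rec.n_samples)[mid] / FS
        basis = np.c_[np.sin(2 * np.pi * 4000 * t), np.cos(2 * np.pi * 4000 * t)]

        def amp(x):
            return np.linalg.norm(basis.T @ x) / len(t) * 2

        atten_db = 20 * np.log10(amp(out.samples[0, mid])
                                 / amp(rec.samples[0, mid]))
        assert atten_db < -20.0

    def test_dc_offset_removed(self):
        rec = make_recording(np.full(50_000, 0.5) + tone(100.0, amp=0.1))
        for band in ("lfp", "unit"):
            out = bandpass(rec, band)
            # 0.5 V offset suppressed by >= two orders of magnitude
            assert abs(out.samples[0, 10_000:40_000].mean()) < 5e-3

    def test_band_separation_at_shared_corner(self):
        rec = make_recording(tone(500.0))
        mid = slice(10_000, 40_000)
        for band in ("lfp", "unit"):
            out = bandpass(rec, band)
            atten_db = 20 * np.log10(out.samples[0, mid].std()
                                     / rec.samples[0, mid].std())
            assert atten_db <= -3.0  # corner of a zero-phase Butterworth

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(tone(100.0, fs=10_000.0), fs=10_000.0)
        with pytest.raises(ValueError):
            bandpass(rec, "unit")  # 8 kHz corner vs 5 kHz Nyquist


class TestEpochAverage:
    def test_identical_epochs_average_to_one_epoch(self):
        fs = 1000.0
        template = np.sin(2 * np.pi * 10 * np.arange(150) / fs)
        x = np.zeros(5000)
        events = [1.0, 2.0, 3.0]
        for e in events:
            i = int(e * fs)
            x[i - 50: i + 100] += template
        rec = make_recording(x, events, fs=fs)
        erp = epoch_average(rec, window=(-0.05, 0.1))
        np.testing.assert_allclose(erp[0], template, atol=1e-12)

    def test_single_event_returns_that_epoch(self):
        fs = 1000.0
        x = np.arange(3000, dtype=float)
        rec = make_recording(x, [1.5], fs=fs)
        erp = epoch_average(rec, window=(-0.05, 0.1))
        np.testing.assert_array_equal(erp[0], x[1450:1600])

    def test_noise_variance_shrinks_with_trial_count(self, rng):
        fs = 1000.0
        n_trials = 100
        x = rng.normal(size=int(fs * (n_trials + 2)))
        events = 1.0 + np.arange(n_trials)
        rec = make_recording(x, events, fs=fs)
        erp = epoch_average(rec, window=(-0.05, 0.1))
        assert erp.var() == pytest.approx(1.0 / n_trials, rel=0.5)

    def test_linearity(self, rng):
        fs = 1000.0
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        events = [1.0, 2.0, 3.0]
        erp_a = epoch_average(make_recording(a, events, fs=fs))
        erp_b = epoch_average(make_recording(b, events, fs=fs))
        erp_ab = epoch_average(make_recording(a + 2 * b, events, fs=fs))
        np.testing.assert_allclose(erp_ab, erp_a + 2 * erp_b, atol=1e-12)

    def test_window_overflow_lists_events(self):
        rec = make_recording(np.zeros(1000), [0.01, 0.5], fs=1000.0)
        with pytest.raises(ValueError, match=r"\[0\]"):
            epoch_average(rec, window=(-0.05, 0.1))


def spike_template():
    """Biphasic template with its trough at sample 8."""
    w = np.zeros(20)
    w[6:11] = [-0.3, -0.7, -1.0, -0.6, -0.2]
    w[11:15] = [0.2, 0.3, 0.2, 0.1]
    return w


class TestDetectSpikes:
    def test_injected_spikes_recovered_at_troughs(self):
        rng = np.random.default_rng(7)
        x = 0.05 * rng.normal(size=100_000)
        spike_samples = [10_000, 30_000, 60_000, 90_000]
        w = spike_template()
        for s in spike_samples:
            x[s - 8: s + 12] += w  # trough lands at s
        rec = make_recording(x, band="unit")
        train = detect_spikes(rec)[0]
        got = np.round(train.times * FS).astype(int)
        # every injected spike recovered within one sample; a handful of
        # noise crossings at the 4-sigma level is expected on 1e5 samples
        for s in spike_samples:
            assert np.min(np.abs(got - s)) <= 1
        assert train.n_spikes <= len(spike_samples) + 8
        assert train.waveforms.shape[1] == SNIPPET_PRE + SNIPPET_POST

    def test_dead_time_suppresses_second_spike(self):
        rng = np.random.default_rng(13)
        x = 0.02 * rng.normal(size=50_000)
        w = spike_template()
        gap = int(1.0e-3 * FS)  # 1.0 ms < 1.5 ms dead time
        x[10_000 - 8: 10_000 + 12] += w
        x[10_000 + gap - 8: 10_000 + gap + 12] += w
        rec = make_recording(x, band="unit")
        train = detect_spikes(rec)[0]
        near = np.abs(train.times * FS - 10_000) < 2 * gap
        assert np.sum(near) == 1

    def test_amplitude_scale_invariance(self, rng):
        x = 0.05 * rng.normal(size=60_000)
        w = spike_template()
        for s in (15_000, 45_000):
            x[s - 8: s + 12] += w
        t1 = detect_spikes(make_recording(x))[0].times
        t2 = detect_spikes(make_recording(7.5 * x))[0].times
        np.testing.assert_array_equal(t1, t2)

    def test_crossing_rate_on_pure_noise(self, rng):
        """Detections on Gaussian noise agree with the 4-sigma upcrossing
        rate within a factor of two."""
        n = 2_000_000
        x = rng.normal(size=n)
        rec = make_recording(x, band="unit")
        train = detect_spikes(rec)[0]
        # discrete-time downward crossing probability of a -4 sd level
        from scipy.stats import norm

        p = norm.cdf(-4.0)
        expected = n * p  # crossings approx. Bernoulli entries below level
        assert expected / 2 < train.n_spikes < expected * 2

    def test_short_channel_skipped_with_warning(self):
        rec = make_recording(np.zeros(10))
        with pytest.warns(UserWarning):
            trains = detect_spikes(rec)
        assert trains[0].n_spikes == 0


class TestSTAP:
    def test_single_spike_equals_epoch(self):
        fs = 1000.0
        x = np.arange(2000, dtype=float)
        rec = make_recording(x, fs=fs)
        tr = SpikeTrain(0, [1.0], np.zeros((1, 20)))
        stap = spike_triggered_average(rec, tr, window=(-0.01, 0.02))
        np.testing.assert_array_equal(stap[0], x[990:1020])

    def test_periodic_artifact_reproduced(self):
        fs = 1000.0
        period = 100
        template = np.sin(2 * np.pi * np.arange(30) / 30)
        x = np.zeros(20_000)
        starts = np.arange(1000, 19_000, period)
        for s in starts:
            x[s: s + 30] += template
        rec = make_recording(x, fs=fs)
        tr = SpikeTrain(0, starts / fs, np.zeros((len(starts), 20)))
        stap = spike_triggered_average(rec, tr, window=(0.0, 0.03))
        np.testing.assert_allclose(stap[0], template, atol=1e-12)

    def test_shuffled_triggers_shrink_as_sqrt_count(self):
        rng = np.random.default_rng(11)
        fs = 1000.0
        x = rng.normal(size=400_000)
        rec = make_recording(x, fs=fs)
        amps = []
        for n_spikes in (50, 5000):
            times = rng.uniform(1.0, 390.0, size=n_spikes)
            tr = SpikeTrain(0, np.sort(times), np.zeros((n_spikes, 20)))
            stap = spike_triggered_average(rec, tr, window=(-0.01, 0.01))
            amps.append(stap.std())
        # 100x more triggers -> roughly 10x smaller residual amplitude
        assert 0.02 < amps[1] / amps[0] < 0.3

    def test_no_usable_spikes_raises(self):
        rec = make_recording(np.zeros(100), fs=1000.0)
        tr = SpikeTrain(0, [0.001], np.zeros((1, 20)))
        with pytest.raises(DegenerateInputError):
            spike_triggered_average(rec, tr, window=(-0.05, 0.05))
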