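"""Filtering, re-referencing, blink regression, epoching and rejection."""

import numpy as np
import pytest

from conftest import make_gaussian_epochs
from erdvoice.preprocess import (epoch, highpass, reject_epochs,
                                 remove_blinks, reref_mastoids)
from erdvoice.recording import Event, RawRecording

SF = 512.0


def sine_raw(freq, dur=20.0, amp=50.0, ch=("C3",)):
    t = np.arange(int(dur * SF)) / SF
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (len(ch), 1))
    return RawRecording(data, list(ch), SF)


class TestHighpass:
    def test_dc_rejected(self):
        raw = RawRecording(np.full((1, 10240), 50.0), ["C3"], SF)
        out = highpass(raw)
        assert np.abs(out.data[0, 2048:-2048]).mean() < 0.5

    def test_passband_10hz_preserved(self):
        out = highpass(sine_raw(10.0))
        mid = out.data[0, 2560:-2560]
        assert np.abs(mid).max() == pytest.approx(50.0, rel=0.05)

    def test_slow_drift_strongly_attenuated(self):
        out = highpass(sine_raw(0.05, dur=60.0))
        mid = out.data[0, int(20 * SF):int(40 * SF)]
        assert np.abs(mid).max() < 0.1 * 50.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(sine_raw(10.0), cutoff_hz=300.0)


class TestReref:
    def _raw(self, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 10, (4, 1024))
        return RawRecording(data, ["C3", "C4", "M1", "M2"], SF)

    def test_zero_mastoids_is_identity(self):
        raw = self._raw()
        raw.data[2:] = 0.0
        out = reref_mastoids(raw)
        assert np.allclose(out.data, raw.data[:2])
        assert out.ch_names == ["C3", "C4"]

    def test_common_signal_removed_exactly(self):
        raw = self._raw()
        common = np.sin(np.arange(1024) * 0.1) * 30
        raw.data += common
        base = self._raw()
        out = reref_mastoids(raw)
        ref = 0.5 * (base.data[2] + base.data[3])
        assert np.allclose(out.data, base.data[:2] - ref, atol=1e-9)

    def test_elementwise_subtraction_oracle(self):
        raw = self._raw(3)
        out = reref_mastoids(raw)
        expected = raw.data[:2] - 0.5 * (raw.data[2] + raw.data[3])
        assert np.allclose(out.data, expected)

    def test_missing_mastoid_rejected(self):
        raw = RawRecording(np.zeros((2, 100)), ["C3", "M1"], SF)
        with pytest.raises(ValueError):
            reref_mastoids(raw)


class TestRemoveBlinks:
    def _blink_train(self, n=int(30 * SF), seed=0):
        rng = np.random.default_rng(seed)
        sig = np.zeros(n)
        tpl = np.hanning(int(0.35 * SF)) ** 2
        for t0 in rng.uniform(0, n - len(tpl), 12).astype(int):
            sig[t0:t0 + len(tpl)] += 100 * tpl
        return sig

    def test_zero_reference_is_identity(self):
        rng = np.random.default_rng(1)
        data = np.vstack([rng.normal(0, 10, 4096), np.zeros(4096)])
        raw = RawRecording(data, ["C3", "EOG"], SF)
        out = remove_blinks(raw, "EOG")
        assert np.allclose(out.data[0], data[0], atol=1e-6)

    def test_scaled_blink_copies_cancelled(self):
        blink = self._blink_train()
        data = np.vstack([0.6 * blink, blink])
        raw = RawRecording(data, ["Fp1", "EOG"], SF)
        out = remove_blinks(raw, "EOG")
        assert np.mean(out.data[0] ** 2) < 0.01 * np.mean(data[0] ** 2)

    def test_oscillatory_content_preserved(self):
        t = np.arange(int(30 * SF)) / SF
        sine = 20 * np.sin(2 * np.pi * 10 * t)
        blink = self._blink_train()
        data = np.vstack([sine + 0.5 * blink, blink])
        raw = RawRecording(data, ["C3", "EOG"], SF)
        out = remove_blinks(raw, "EOG")
        # power of the 10 Hz content within 5%
        from erdvoice.spectral import band_power, welch_psd

        f, p = welch_psd(out.data[0], SF)
        f0, p0 = welch_psd(sine, SF)
        assert band_power(p, f, (9, 11)) == pytest.approx(
            band_power(p0, f0, (9, 11)), rel=0.05
        )

    def test_missing_channel_rejected(self):
        raw = RawRecording(np.zeros((1, 100)), ["C3"], SF)
        with pytest.raises(ValueError):
            remove_blinks(raw, "EOG")


class TestEpoch:
    def _raw_with_events(self, n_events=120, spacing=7.0):
        n = int((n_events * spacing + 10) * SF)
        rng = np.random.default_rng(0)
        data = rng.normal(0, 10, (3, n))
        events = [
            Event(2.0 + i * spacing, "stim_vocal" if i % 2 else "stim_nonvocal", i)
            for i in range(n_events)
        ]
        return RawRecording(data, ["C3", "C4", "Cz"], SF, events)

    def test_stimulus_epochs_have_exact_shape(self):
        ep = epoch(self._raw_with_events(), "stim", (1.0, 5.0))
        assert ep.data.shape == (120, 3, 3072)  # 6 s x 512 Hz
        assert ep.times[0] == -1.0
        assert set(ep.conditions) == {"vocal", "nonvocal"}

    def test_seven_second_window_sample_count(self):
        ep = epoch(self._raw_with_events(n_events=4, spacing=10.0), "stim", (1.0, 6.0))
        assert ep.data.shape[-1] == 3584

    def test_no_matching_events_warns(self):
        with pytest.warns(UserWarning):
            ep = epoch(self._raw_with_events(4), "go", (1.0, 5.0))
        assert ep.n_trials == 0

    def test_edge_trial_flagged_not_dropped(self):
        raw = self._raw_with_events(4, spacing=7.0)
        raw.events[0] = Event(0.5, "stim_vocal", 0)  # too close to start
        ep = epoch(raw, "stim", (1.0, 5.0))
        assert ep.n_trials == 4
        assert not ep.kept[0] and ep.reasons[0] == "edge"
        assert ep.kept[1:].all()


class TestRejectEpochs:
    def test_homogeneous_data_all_kept(self):
        ep = make_gaussian_epochs()
        out = reject_epochs(ep)
        assert out.kept.all()

    def test_injected_spike_rejected_with_amplitude_reason(self):
        ep = make_gaussian_epochs()
        ep.data[7, 2, 100:110] += 150.0
        out = reject_epochs(ep)
        assert not out.kept[7] and out.reasons[7] == "amplitude"
        assert out.kept.sum() == ep.n_trials - 1

    def test_heavy_tailed_epoch_rejected(self):
        # a z-score across n epochs cannot exceed (n-1)/sqrt(n), so the
        # 5-SD rule needs a realistic epoch count to see one outlier
        rng = np.random.default_rng(5)
        ep = make_gaussian_epochs(n_trials=40, seed=1)
        # heavy tails at matched SD so the amplitude rule stays quiet
        heavy = rng.standard_t(2, ep.data.shape[2])
        heavy = np.clip(heavy / heavy.std() * 10.0, -95, 95)
        ep.data[4, :, :] = heavy
        out = reject_epochs(ep)
        assert not out.kept[4]
        assert out.reasons[4] in ("improbability", "kurtosis")
        assert out.kept.sum() == ep.n_trials - 1

    def test_rejection_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        ep = make_gaussian_epochs(seed=2)
        ep.data[3] *= 3.0
        ep.data[11, 0, 50] += 120
        base = int((~reject_epochs(ep, 100, 5, 5).kept).sum())
        for amp, prob, kurt in [(120, 5, 5), (100, 6, 5), (100, 5, 6), (150, 8, 8)]:
            n = int((~reject_epochs(ep, amp, prob, kurt).kept).sum())
            assert n <= base

    def test_too_few_epochs_rejected(self):
        ep = make_gaussian_epochs(n_trials=5)
        with pytest.raises(ValueError):
            reject_epochs(ep)
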