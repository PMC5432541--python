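"""EEG conditioning and saccade-locked epoching."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from srpsearch import (
    EpochSet,
    bandpass_eeg,
    detect_bad_channels,
    extract_epochs,
    interpolate_bad_channels,
    reject_outlier_epochs,
    rereference_average,
    resample_recording,
)
from srpsearch.signal_synthesis import DEFAULT_P300_WEIGHTS, EEG_CHANNELS, PARIETO_CENTRAL


class TestResample:
    def test_sinusoid_amplitude_preserved(self, quiet_session):
        _, _, rec = quiet_session
        n = rec.eeg.shape[1]
        t = np.arange(n) / rec.eeg_fs
        probe = dataclasses.replace(
            rec,
            eeg=np.tile(np.sin(2 * np.pi * 10 * t), (rec.eeg.shape[0], 1)),
            events=rec.events.copy(),
        )
        out = resample_recording(probe, 256.0)
        mid = out.eeg[0, 1000:-1000]
        assert abs(mid.max() - 1.0) < 0.01
        assert out.eeg_fs == 256.0

    def test_identity_at_native_rate(self, quiet_session):
        _, _, rec = quiet_session
        out = resample_recording(rec, rec.eeg_fs)
        np.testing.assert_array_equal(out.eeg, rec.eeg)

    def test_length_contract(self, quiet_session):
        _, _, rec = quiet_session
        out = resample_recording(rec, 256.0)
        expected = int(np.ceil(rec.eeg.shape[1] * 256.0 / rec.eeg_fs))
        assert out.eeg.shape[1] == expected

    def test_upsampling_rejected(self, quiet_session):
        _, _, rec = quiet_session
        with pytest.raises(ValueError):
            resample_recording(rec, 2 * rec.eeg_fs)

    def test_event_times_unchanged(self, quiet_session):
        _, _, rec = quiet_session
        out = resample_recording(rec, 256.0)
        pd.testing.assert_series_equal(out.events["onset_s"], rec.events["onset_s"])


class TestBadChannels:
    def test_identical_channels_none_flagged(self, rng):
        x = np.tile(rng.normal(0, 1, 5000), (8, 1))
        assert detect_bad_channels(x, 256.0, EEG_CHANNELS[:8]) == []

    def test_scaled_channel_flagged_exactly(self, rng):
        x = rng.normal(0, 1, (8, 5000))
        x[3] *= 10
        assert detect_bad_channels(x, 256.0, EEG_CHANNELS[:8]) == [EEG_CHANNELS[3]]

    def test_injected_bad_channel_found_across_seeds(self, small_config):
        from srpsearch import (
            BehaviorParams,
            SignalParams,
            generate_schedule,
            simulate_behavior,
            synthesize_recording,
        )
        from srpsearch.task_model import ExperimentConfig

        config = ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=2)
        for seed in range(3):
            schedule = generate_schedule(config, "high", seed)
            outcomes = simulate_behavior(schedule, BehaviorParams(), seed)
            rec = synthesize_recording(
                schedule, outcomes, SignalParams(bad_channel="T7"), seed=seed
            )
            bads = detect_bad_channels(rec.eeg, rec.eeg_fs, rec.channel_names)
            assert bads == ["T7"]

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_bad_channels(rng.normal(0, 1, (2, 100)), 256.0, EEG_CHANNELS[:2])


class TestInterpolation:
    def test_identical_neighbours_reproduced(self, rng):
        sig = rng.normal(0, 1, 1000)
        x = np.tile(sig, (32, 1))
        x[5] = 99.0
        out = interpolate_bad_channels(x, EEG_CHANNELS, [EEG_CHANNELS[5]])
        np.testing.assert_allclose(out[5], sig, atol=1e-12)
        np.testing.assert_array_equal(out[6], x[6])

    def test_interpolated_channel_inside_neighbour_range(self, rng):
        x = rng.normal(0, 1, (32, 500))
        bad = "Pz"
        out = interpolate_bad_channels(x, EEG_CHANNELS, [bad])
        bi = EEG_CHANNELS.index(bad)
        good = np.delete(np.arange(32), bi)
        assert np.all(out[bi] <= x[good].max(axis=0) + 1e-12)
        assert np.all(out[bi] >= x[good].min(axis=0) - 1e-12)

    def test_weights_sum_to_one_via_constant_signal(self):
        x = np.full((32, 100), 7.5)
        x[10] = -3.0
        out = interpolate_bad_channels(x, EEG_CHANNELS, [EEG_CHANNELS[10]])
        np.testing.assert_allclose(out[10], 7.5, atol=1e-12)

    def test_all_bad_rejected(self, rng):
        x = rng.normal(0, 1, (4, 100))
        with pytest.raises(ValueError):
            interpolate_bad_channels(x, EEG_CHANNELS[:4], list(EEG_CHANNELS[:4]))


class TestRereference:
    def test_good_channel_mean_zero(self, rng):
        x = rng.normal(0, 1, (8, 1000))
        out = rereference_average(x, EEG_CHANNELS[:8], ["T7"])
        good = [i for i, c in enumerate(EEG_CHANNELS[:8]) if c != "T7"]
        np.testing.assert_allclose(out[good].mean(axis=0), 0.0, atol=1e-12)

    def test_two_equal_channels_become_zero(self):
        x = np.tile(np.arange(10.0), (2, 1))
        out = rereference_average(x, EEG_CHANNELS[:2])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_matrix(self):
        x = np.array([[1.0, 4.0], [2.0, 5.0], [6.0, 9.0]])
        out = rereference_average(x, EEG_CHANNELS[:3])
        np.testing.assert_allclose(out, x - x.mean(axis=0, keepdims=True))


class TestBandpass:
    def _tone(self, freq, fs=256.0, n=25600):
        return np.sin(2 * np.pi * freq * np.arange(n) / fs)

    def test_60hz_attenuated(self):
        out = bandpass_eeg(self._tone(60), 256.0)
        assert out[5000:-5000].max() < 10 ** (-20 / 20)

    def test_10hz_preserved(self):
        out = bandpass_eeg(self._tone(10), 256.0)
        assert abs(out[5000:-5000].max() - 1.0) < 0.05

    def test_dc_removed(self, rng):
        x = rng.normal(0, 1, 25600) + 50.0
        out = bandpass_eeg(x, 256.0)
        assert abs(out.mean()) < 0.5

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_eeg(np.zeros(1000), 256.0, 32.0, 0.5)


def _saccade_table(peak_times):
    return pd.DataFrame(
        {
            "event_id": np.arange(len(peak_times)),
            "matched": True,
            "peak_time_s": peak_times,
            "latency_ms": 200.0,
            "channel": "H",
            "sign": 1,
        }
    )


def _event_table(n):
    return pd.DataFrame(
        {
            "trial": 0,
            "serial_pos": np.arange(1, n + 1),
            "row": 0,
            "col": 0,
            "onset_s": np.arange(n, dtype=float),
            "is_target": False,
            "is_hit": False,
            "condition": "nontarget",
        }
    )


class TestEpochs:
    def test_constant_channel_zero_after_baseline(self):
        eeg = np.full((2, 256 * 10), 42.0)
        es = extract_epochs(
            eeg, 256.0, EEG_CHANNELS[:2], _saccade_table([2.0, 5.0]),
            _event_table(2), "high",
        )
        assert es.data.shape == (2, 2, 256)
        np.testing.assert_allclose(es.data, 0.0, atol=1e-12)

    def test_ramp_minus_mean_of_first_25(self):
        fs = 256.0
        ramp = np.arange(256 * 10, dtype=float)
        es = extract_epochs(
            ramp[None, :], fs, ("Cz",), _saccade_table([3.0]), _event_table(1), "low",
        )
        i0 = int(round(3.0 * fs))
        seg = ramp[i0:i0 + 256]
        np.testing.assert_allclose(es.data[0, 0], seg - seg[:25].mean())

    def test_baseline_mean_exactly_zero(self, default_analysis):
        es = default_analysis.epochs
        base = es.data[:, :, :25].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)

    def test_epoch_sample_count_is_one_second(self, default_analysis):
        assert default_analysis.epochs.data.shape[2] == 256

    def test_near_end_saccade_skipped_with_count(self):
        eeg = np.zeros((1, 256 * 4))
        with pytest.warns(UserWarning, match="skipped"):
            es = extract_epochs(
                eeg, 256.0, ("Cz",), _saccade_table([1.0, 3.5]),
                _event_table(2), "high",
            )
        assert es.n_skipped == 1
        assert es.data.shape[0] == 1


class TestOutlierRejection:
    def _epochs(self, data):
        n = data.shape[0]
        return EpochSet(
            data=data,
            channel_names=tuple(EEG_CHANNELS[: data.shape[1]]),
            fs=256.0,
            labels=pd.DataFrame({"event_id": np.arange(n), "condition": "nontarget",
                                 "is_target": False}),
            load="high",
        )

    def test_identical_epochs_none_rejected(self, rng):
        base = rng.normal(0, 1, (1, 3, 256))
        es = self._epochs(np.repeat(base, 8, axis=0))
        out = reject_outlier_epochs(es, 50.0)
        assert out.rejected_epoch_ids == []
        assert out.data.shape[0] == 8

    def test_scaled_epoch_rejected(self, rng):
        data = rng.normal(0, 1, (10, 3, 256))
        data[4] *= 100
        out = reject_outlier_epochs(self._epochs(data), 50.0)
        assert out.rejected_epoch_ids == [4]
        assert out.data.shape[0] == 9

    def test_invariant_to_channel_permutation(self, rng):
        data = rng.normal(0, 1, (10, 4, 256))
        data[7] *= 200
        a = reject_outlier_epochs(self._epochs(data), 50.0)
        b = reject_outlier_epochs(self._epochs(data[:, ::-1, :]), 50.0)
        assert a.rejected_epoch_ids == b.rejected_epoch_ids


class TestEffectRecovery:
    def test_injected_p300_difference_recovered(self, default_analysis, default_session):
        """Grand-average target minus non-target difference at parieto-central
        channels recovers the injected amplitude after accounting for the
        average-reference attenuation (weight minus mean weight)."""
        _, _, rec = default_session
        es = default_analysis.epochs
        pc = es.pick(PARIETO_CENTRAL)
        diff = (
            pc[es.condition_mask("target")].mean(axis=0).mean(axis=0)
            - pc[es.condition_mask("nontarget")].mean(axis=0).mean(axis=0)
        )
        w = np.array([DEFAULT_P300_WEIGHTS[c] for c in EEG_CHANNELS])
        w_pc = np.mean([DEFAULT_P300_WEIGHTS[c] for c in PARIETO_CENTRAL])
        # average the difference over +/-40 ms around the bump centre and
        # compare with the injected half-cosine averaged over that window
        times = es.times
        window = np.abs(times - 0.5) <= 0.04
        shape = np.mean(np.cos(np.pi * (times[window] - 0.5) / 0.3) ** 2)
        expected = (5.0 - 1.0) * (w_pc - w.mean()) * shape
        observed = diff[window].mean()
        # residual-noise SE of the condition difference is ~0.6 uV here
        assert observed == pytest.approx(expected, abs=1.2)
        assert np.argmax(diff) * (1 / 256.0) == pytest.approx(0.5, abs=0.08)
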