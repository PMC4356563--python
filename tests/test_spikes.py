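"""Filtering, template detection, SNR statistic and subaverage bookkeeping."""

import numpy as np
import pytest

from emegscan.errors import ConfigurationError, InputError
from emegscan.phantom import ContinuousRecording
from emegscan.spikes import (
    DEFAULT_GROUP_SIZES,
    Epoch,
    SubaverageSpec,
    bandpass,
    compute_snr,
    detect_spikes,
    make_subaverages,
    make_template,
    snr_gate,
)

SFREQ = 250.0


def recording_from(data, kinds=None, ground_truth=()):
    n = data.shape[0]
    return ContinuousRecording(
        data=np.asarray(data, float),
        sfreq=SFREQ,
        channel_names=[f"ch{i}" for i in range(n)],
        channel_kinds=list(kinds) if kinds is not None else ["eeg"] * n,
        ground_truth=list(ground_truth),
    )


def epoch_from(data, kinds=None):
    d = np.asarray(data, float)
    return Epoch(data=d, sfreq=SFREQ, channel_kinds=list(kinds) if kinds else ["eeg"] * d.shape[0])


class TestBandpass:
    def _sine(self, freq, seconds=20.0):
        t = np.arange(int(seconds * SFREQ)) / SFREQ
        return np.sin(2 * np.pi * freq * t)[None, :]

    def test_passband_tone_retained(self):
        rec = recording_from(self._sine(50.0))
        out = bandpass(rec, 1.0, 100.0)
        mid = slice(1000, 4000)  # avoid filter edges
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated(self):
        rec = recording_from(self._sine(0.1, seconds=60.0))
        out = bandpass(rec, 1.0, 100.0)
        mid = slice(3000, 12000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio < 0.1  # >= 20 dB

    def test_zero_in_zero_out(self):
        rec = recording_from(np.zeros((3, 1000)))
        np.testing.assert_array_equal(bandpass(rec, 1.0, 100.0).data, 0)

    def test_invalid_band_rejected(self):
        rec = recording_from(np.zeros((1, 1000)))
        with pytest.raises(ConfigurationError):
            bandpass(rec, 1.0, 200.0)


class TestDetectSpikes:
    def _template(self):
        rng = np.random.default_rng(0)
        return rng.standard_normal((4, 25))

    def test_exact_recovery_in_zero_noise(self):
        tpl = self._template()
        data = np.zeros((4, 10_000))
        truth = [500, 1500, 2500, 3500, 4500, 5500, 6500, 7500, 8500, 9500]
        for t in truth:
            data[:, t - 12 : t + 13] += tpl
        rec = recording_from(data)
        events = detect_spikes(rec, tpl, 0.9)
        assert len(events) == 10
        assert np.all(np.abs(np.sort(events) - np.array(truth)) <= 1)

    def test_scale_invariance(self):
        tpl = self._template()
        data = np.zeros((4, 8_000))
        truth = [500, 2000, 3500, 5000, 6500]
        scales = [0.5, 0.8, 1.0, 1.5, 2.0]
        for t, s in zip(truth, scales):
            data[:, t - 12 : t + 13] += s * tpl
        rec = recording_from(data)
        events = detect_spikes(rec, tpl, 0.8)
        assert len(events) == 5

    def test_white_noise_yields_no_detections(self):
        rng = np.random.default_rng(1)
        rec = recording_from(rng.standard_normal((80, 10_000)))
        tpl = rng.standard_normal((80, 25))
        assert len(detect_spikes(rec, tpl, 0.99)) == 0

    def test_empty_template_rejected(self):
        rec = recording_from(np.zeros((2, 100)))
        with pytest.raises(ConfigurationError):
            detect_spikes(rec, np.empty((2, 0)), 0.5)


class TestMakeTemplate:
    def test_identical_embedded_spikes_average_to_one(self):
        rng = np.random.default_rng(2)
        spike = rng.standard_normal((3, 50))
        data = np.zeros((3, 6_000))
        marks = [500 + 500 * i for i in range(10)]
        for t in marks:
            data[:, t - 25 : t + 25] += spike
        rec = recording_from(data)
        tpl = make_template(rec, marks, n_seed=10, half_width_ms=100.0)
        np.testing.assert_allclose(tpl, spike, atol=1e-12)

    def test_single_seed_returns_that_epoch(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 2_000))
        rec = recording_from(data)
        tpl = make_template(rec, [1000], n_seed=1, half_width_ms=100.0)
        np.testing.assert_array_equal(tpl, data[:, 975:1025])

    def test_noise_shrinks_as_sqrt_of_seed_count(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((40, 20_000))
        rec = recording_from(data)
        marks = [500 + 1000 * i for i in range(10)]
        tpl = make_template(rec, marks, n_seed=10, half_width_ms=100.0)
        # pure-noise average over 10 windows: SD should be ~1/sqrt(10)
        assert abs(tpl.std() - 1 / np.sqrt(10)) < 0.15 / np.sqrt(10)

    def test_too_few_marks_rejected(self):
        rec = recording_from(np.zeros((2, 1000)))
        with pytest.raises(InputError):
            make_template(rec, [500], n_seed=10)


class TestComputeSNR:
    def _epoch(self, signal_value, baseline_sd, seed=0):
        rng = np.random.default_rng(seed)
        data = np.zeros((5, 101))
        data[:, :33] = baseline_sd * rng.standard_normal((5, 33))  # -200..-70 ms
        data[:, 50] = signal_value
        return epoch_from(data)

    def test_unit_snr_when_signal_equals_baseline_sd(self):
        data = np.zeros((4, 101))
        # deterministic baseline of exactly unit variance: +-1 alternation
        data[:, :34] = np.tile([1.0, -1.0], 17)[:34]
        data[:, 50] = 1.0
        rec = compute_snr(epoch_from(data), 0.0, np.arange(4))
        assert rec.value == pytest.approx(1.0)

    def test_zero_signal_gives_zero(self):
        rec = compute_snr(self._epoch(0.0, 1.0), 0.0, np.arange(5))
        assert rec.value == 0.0

    def test_quadratic_in_amplitude(self):
        a = compute_snr(self._epoch(2.0, 1.0, seed=5), 0.0, np.arange(5))
        b = compute_snr(self._epoch(4.0, 1.0, seed=5), 0.0, np.arange(5))
        assert b.value == pytest.approx(4 * a.value)

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_snr(self._epoch(1.0, 1.0), 0.0, np.array([], int))


class TestSubaverages:
    def _epochs(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return [epoch_from(rng.standard_normal((3, 101))) for _ in range(n)]

    def test_av1_is_identity_list(self):
        eps = self._epochs(20)
        groups = make_subaverages(eps, SubaverageSpec(group_sizes=(1,), seed=1))
        assert len(groups[1]) == 20
        members = sorted(int(r.member_indices[0]) for r in groups[1])
        assert members == list(range(20))
        for i, real in enumerate(groups[1]):
            np.testing.assert_array_equal(real.epoch.data, eps[i].data)

    def test_draws_are_distinct_within_realization(self):
        eps = self._epochs(30)
        groups = make_subaverages(
            eps, SubaverageSpec(group_sizes=(10,), realizations_per_group=50, seed=2)
        )
        for real in groups[10]:
            assert len(set(real.member_indices.tolist())) == 10

    def test_average_is_arithmetic_mean(self):
        eps = self._epochs(15)
        groups = make_subaverages(
            eps, SubaverageSpec(group_sizes=(5,), realizations_per_group=8, seed=3)
        )
        real = groups[5][0]
        want = np.mean([eps[i].data for i in real.member_indices], axis=0)
        np.testing.assert_allclose(real.epoch.data, want, rtol=1e-15)

    def test_identical_epochs_average_to_common_value(self):
        base = epoch_from(np.ones((2, 101)) * 3.5)
        eps = [base] * 12
        groups = make_subaverages(
            eps, SubaverageSpec(group_sizes=(10,), realizations_per_group=5, seed=4)
        )
        for real in groups[10]:
            np.testing.assert_array_equal(real.epoch.data, base.data)

    def test_deterministic_for_fixed_seed(self):
        eps = self._epochs(25)
        spec = SubaverageSpec(group_sizes=(5, 10), realizations_per_group=6, seed=5)
        a = make_subaverages(eps, spec)
        b = make_subaverages(eps, spec)
        for k in (5, 10):
            for ra, rb in zip(a[k], b[k]):
                np.testing.assert_array_equal(ra.member_indices, rb.member_indices)

    def test_oversized_group_rejected(self):
        with pytest.raises(ConfigurationError):
            make_subaverages(self._epochs(5), SubaverageSpec(group_sizes=(10,), seed=0))

    def test_default_group_sizes_match_protocol(self):
        assert DEFAULT_GROUP_SIZES == (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


class TestSNRGate:
    def _realization_with_snr(self, snr_target, seed):
        """Epoch engineered to have a given power SNR at time 0."""
        rng = np.random.default_rng(seed)
        data = np.zeros((4, 101))
        data[:, :34] = np.tile([1.0, -1.0], 17)[:34]  # unit baseline variance
        data[:, 50] = np.sqrt(snr_target)
        from emegscan.spikes import SubaverageRealization

        return SubaverageRealization(1, np.array([seed]), epoch_from(data))

    def test_known_snrs_filtered(self):
        reals = [self._realization_with_snr(s, i) for i, s in enumerate([1, 2, 4, 8])]
        out = snr_gate(reals, np.arange(4), 0.0, threshold=3.0)
        assert len(out) == 2
        assert sorted(round(rec.value) for _, rec in out) == [4, 8]

    def test_strict_inequality_at_threshold(self):
        reals = [self._realization_with_snr(3.0, i) for i in range(4)]
        assert snr_gate(reals, np.arange(4), 0.0, threshold=3.0) == []

    def test_all_above_threshold_is_identity(self):
        reals = [self._realization_with_snr(9.0, i) for i in range(5)]
        out = snr_gate(reals, np.arange(4), 0.0, threshold=3.0)
        assert [r for r, _ in out] == reals

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            snr_gate([], np.arange(4), 0.0, threshold=0.0)


class TestAveragingLaw:
    def test_snr_of_k_average_scales_with_k_for_fixed_amplitude(self):
        """For k copies of one fixed signal plus iid noise the power SNR of
        the k-average is ~k times the single-epoch SNR (within 15%)."""
        rng = np.random.default_rng(6)
        k, n_draws = 10, 1000
        # strong single-epoch SNR so the additive noise-power term at the
        # measurement instant stays small relative to k-fold scaling
        signal = np.zeros((1, 101))
        signal[:, 50] = 4.0
        singles, averages = [], []
        for _ in range(n_draws):
            noise = rng.standard_normal((k, 1, 101))
            eps = signal[None] + noise
            singles.append(eps[0, 0, 50] ** 2 / eps[0, 0, :34].var())
            avg = eps.mean(axis=0)
            averages.append(avg[0, 50] ** 2 / avg[0, :34].var())
        ratio = np.mean(averages) / np.mean(singles)
        assert abs(ratio - k) / k < 0.15

    def test_varying_amplitudes_break_the_scaling(self):
        """When single-spike amplitudes vary, averaging no longer multiplies
        the SNR by k — the k-average SNR reflects the mean amplitude."""
        rng = np.random.default_rng(7)
        k, n_draws = 10, 600
        singles, averages = [], []
        for _ in range(n_draws):
            amps = 2.0 * np.exp(0.8 * rng.standard_normal(k))
            noise = rng.standard_normal((k, 101))
            eps = noise.copy()
            eps[:, 50] += amps
            singles.append(np.mean(eps[:, 50] ** 2 / eps[:, :34].var(axis=1)))
            avg = eps.mean(axis=0)
            averages.append(avg[50] ** 2 / avg[:34].var())
        ratio = np.mean(averages) / np.mean(singles)
        assert ratio < 0.85 * k
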