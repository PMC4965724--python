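import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semgrip as sg
from semgrip import io as sio
from semgrip import preprocess as pre


def brute_force_mav(x, step, half):
    """Independent oracle: explicit per-window mean of absolute values."""
    x = np.asarray(x, dtype=float)
    out = []
    for k in range(1, x.size // step + 1):
        lo, hi = max(0, k * step - half), min(x.size, k * step + half)
        out.append(np.abs(x[lo:hi]).mean())
    return np.asarray(out)


class TestMav:
    def test_worked_example(self):
        """N=2, T1=1, T=2: first window averages |f(1)|..|f(4)|."""
        x = np.asarray([1, -2, 3, -4, 5, 6], dtype=float)
        got = pre.mav_from_samples(x, step=2, half_width=2)
        assert got[0] == pytest.approx((1 + 2 + 3 + 4) / 4)
        np.testing.assert_allclose(got, brute_force_mav(x, 2, 2))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 1200))
        x = rng.normal(size=n)
        np.testing.assert_allclose(
            pre.mav_from_samples(x, 100, 100), brute_force_mav(x, 100, 100), atol=1e-12
        )

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(
            pre.mav_from_samples(x, 100, 100), pre.mav_from_samples(-x, 100, 100)
        )

    def test_constant_magnitude_recovers_constant(self):
        x = 3.5 * np.where(np.arange(2000) % 2 == 0, 1, -1)
        np.testing.assert_allclose(pre.mav_from_samples(x, 100, 100), 3.5)

    def test_full_run_yields_2400_instances(self, quiet_hammer_features):
        _, mav, _ = quiet_hammer_features
        assert len(mav) == 2400
        assert mav.times[0] == pytest.approx(0.05)
        assert mav.times[-1] == pytest.approx(120.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pre.mav_from_samples(np.ones(150), 100, 100)


class TestBandpass:
    @staticmethod
    def _series(values):
        return sio.ChannelSeries("1:ED", "EMG", 2000.0, values)

    def test_dc_attenuated_and_passband_preserved(self):
        t = np.arange(8000) / 2000.0
        dc = self._series(np.ones(8000))
        assert np.abs(pre.bandpass(dc).values[2000:6000]).max() < 0.05
        tone = self._series(np.sin(2 * np.pi * 100 * t))
        out = pre.bandpass(tone).values[2000:6000]
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.05)

    def test_disabled_is_identity(self):
        s = self._series(np.random.default_rng(0).normal(size=4000))
        assert pre.bandpass(s, enabled=False) is s

    def test_low_rate_rejected(self):
        s = sio.ChannelSeries("9:Thumb:x", "ACC", 148.1, np.zeros(1000))
        with pytest.raises(ValueError, match="rate"):
            pre.bandpass(s)


class TestZscore:
    def test_training_data_standardised(self):
        rng = np.random.default_rng(2)
        stream = pre.MavStream(times=0.05 * np.arange(1, 101), values=rng.uniform(1, 5, (100, 8)))
        stats = pre.fit_channel_stats(stream)
        z = pre.apply_zscore(stream, stats)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=0), 1, atol=1e-12)

    def test_two_point_channel_population_convention(self):
        values = np.zeros((2, 8))
        values[1] = 2.0
        stream = pre.MavStream(times=np.asarray([0.05, 0.1]), values=values)
        stats = pre.fit_channel_stats(stream)
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(stats.std, 1.0)  # population (divide-by-n)
        z = pre.apply_zscore(stream, stats)
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 1.0])

    def test_held_out_uses_training_stats(self):
        rng = np.random.default_rng(3)
        train = pre.MavStream(times=0.05 * np.arange(1, 51), values=rng.uniform(0, 1, (50, 8)))
        test = pre.MavStream(times=0.05 * np.arange(1, 51), values=rng.uniform(5, 6, (50, 8)))
        stats = pre.fit_channel_stats(train)
        z = pre.apply_zscore(test, stats)
        expected = (test.values - stats.mean) / stats.std
        np.testing.assert_array_equal(z.values, expected)
        assert z.values.mean() > 3  # clearly not re-centred on itself

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        stream = pre.MavStream(times=0.05 * np.arange(1, 31), values=rng.uniform(0, 2, (30, 8)))
        stats = pre.fit_channel_stats(stream)
        back = pre.invert_zscore(pre.apply_zscore(stream, stats), stats)
        np.testing.assert_allclose(back.values, stream.values, atol=1e-9)

    def test_degenerate_channel_rejected(self):
        stream = pre.MavStream(times=np.asarray([0.05, 0.1]), values=np.ones((2, 8)))
        with pytest.raises(ValueError, match="degenerate|constant"):
            pre.fit_channel_stats(stream)


class TestAccSummary:
    @staticmethod
    def _bundle(acc_values):
        emg = [sio.ChannelSeries(f"{i}:E", "EMG", 2000.0, np.ones(400)) for i in range(8)]
        acc = [
            sio.ChannelSeries(f"9:T:{k}", "ACC", 148.1, v) for k, v in enumerate(acc_values)
        ]
        return sio.RunBundle(emg=emg, acc=acc)

    def test_constant_acc_gives_zero_statistic(self):
        bundle = self._bundle([np.full(300, 0.7)] * 6)
        summary = pre.summarize_acc(bundle)
        assert np.all(summary.stat == 0)
        assert summary.median == 0

    def test_single_step_gives_single_nonzero(self):
        values = [np.zeros(300) for _ in range(6)]
        values[2][150:] = 1.0  # one unit step on one channel
        summary = pre.summarize_acc(self._bundle(values))
        nz = np.flatnonzero(summary.stat)
        assert nz.size == 1
        assert summary.stat[nz[0]] == pytest.approx(1.0)

    def test_rate_of_summary_grid(self, quiet_hammer_features):
        _, _, summary = quiet_hammer_features
        rate = summary.stat.size / 120.0
        assert rate == pytest.approx(21.1, abs=0.1)

    def test_too_few_samples_rejected(self):
        bundle = self._bundle([np.zeros(6)] * 6)  # one decimated sample only
        with pytest.raises(ValueError, match="few"):
            pre.summarize_acc(bundle)
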