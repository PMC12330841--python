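"""Binning, brick-layer detrending and readability rules."""

import numpy as np
import pytest

from scalpsd.edf import Recording
from scalpsd.layouts import scalp29_layout
from scalpsd.preprocess import (
    BinnedRecording,
    assess_readability,
    bin_8s,
    brick_layer_epochs,
    scale_range,
)


def _rec(data, rate=256.0, labels=None):
    data = np.atleast_2d(data)
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(labels=labels, data=data, rate=rate)


class TestBin8s:
    def test_constant_signal_bins_to_constant(self):
        b = bin_8s(_rec(np.full((1, 2048 * 3), 100.0)))
        assert b.n_bins == 3
        assert np.allclose(b.bin_means, 100.0)

    def test_ramp_first_bin_is_mean_of_arithmetic_series(self):
        b = bin_8s(_rec(np.arange(2048.0)[None]))
        assert b.bin_means[0, 0] == pytest.approx(1023.5)

    def test_output_rate_is_eighth_hz(self):
        b = bin_8s(_rec(np.zeros((2, 2048 * 5))))
        assert b.rate == 0.125
        assert b.bin_width == 8.0

    def test_partial_trailing_bin_dropped(self):
        b = bin_8s(_rec(np.zeros((1, 2048 + 100))))
        assert b.n_bins == 1

    def test_masked_samples_excluded_and_all_masked_bin_missing(self):
        data = np.ones((1, 2048 * 2))
        data[0, :2048] = 7.0
        mask = np.zeros_like(data, dtype=bool)
        mask[0, :1024] = True  # half of first bin
        mask[0, 2048:] = True  # entire second bin
        rec = Recording(labels=["x"], data=data, rate=256.0, mask=mask)
        b = bin_8s(rec)
        assert b.bin_means[0, 0] == pytest.approx(7.0)
        assert np.isnan(b.bin_means[0, 1])

    def test_binning_is_mean_preserving(self, rng):
        data = rng.normal(0, 50, (3, 2048 * 4))
        b = bin_8s(_rec(data))
        assert np.allclose(b.bin_means.mean(axis=1), data.mean(axis=1))

    def test_incommensurate_rate_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            bin_8s(_rec(np.zeros((1, 100)), rate=0.3))


def _binned(data, labels=None, layout=None):
    return BinnedRecording(
        labels=labels or [f"ch{i}" for i in range(np.atleast_2d(data).shape[0])],
        bin_means=np.atleast_2d(np.asarray(data, dtype=float)),
        layout=layout,
    )


class TestBrickLayer:
    def test_three_hour_record_gives_two_staggered_epochs(self):
        n = int(3 * 3600 / 8)
        eps = brick_layer_epochs(_binned(np.zeros((1, n))))
        assert [e.start for e in eps] == [0.0, 3600.0]
        assert all(e.length == 7200.0 for e in eps)

    def test_pure_linear_drift_detrends_to_zero(self):
        t = (np.arange(900) + 0.5) * 8.0
        eps = brick_layer_epochs(_binned(3.0 + 0.05 * t))
        assert np.abs(eps[0].detrended).max() < 1e-9

    def test_detrending_is_idempotent(self, rng):
        from scalpsd.preprocess import detrend_linear

        x = rng.normal(0, 20, (2, 900))
        t = (np.arange(900) + 0.5) * 8.0
        once, _ = detrend_linear(t, x)
        twice, coeffs = detrend_linear(t, once)
        assert np.abs(twice - once).max() < 1e-9
        assert np.abs(coeffs).max() < 1e-9

    def test_pulse_on_drift_leaves_pulse_minus_own_projection(self):
        t = (np.arange(900) + 0.5) * 8.0
        pulse = -400.0 * np.exp(-((t - 3600) ** 2) / (2 * 30.0**2))
        drift = 10.0 + 0.02 * t
        eps = brick_layer_epochs(_binned(pulse + drift))
        # independent closed-form oracle: residual of the pulse against
        # its own least-squares line
        slope, intercept = np.polyfit(t, pulse, 1)
        expected = pulse - (intercept + slope * t)
        assert np.allclose(eps[0].detrended[0], expected, atol=1e-8)

    def test_short_record_yields_truncated_epoch_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than epoch"):
            eps = brick_layer_epochs(_binned(np.zeros((1, 100))))
        assert len(eps) == 1
        assert eps[0].length == pytest.approx(800.0)

    def test_raw_reconstruction_from_trend(self, rng):
        x = rng.normal(0, 30, (2, 900)) + 0.03 * np.arange(900)
        eps = brick_layer_epochs(_binned(x))
        assert np.allclose(eps[0].raw(), x, atol=1e-8)


class TestScaleRange:
    def test_constant_channel_collapses(self):
        eps = brick_layer_epochs(_binned(np.full((2, 900), 5.0)))
        lo, hi = scale_range(eps[0])
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_uniform_values_give_middle_99_percent(self, rng):
        vals = rng.uniform(0, 1000, (1, 10000))
        e = brick_layer_epochs(_binned(vals))[0]
        e.detrended = vals  # bypass detrending to test the percentiles
        lo, hi = scale_range(e)
        assert lo == pytest.approx(5.0, abs=2.0)
        assert hi == pytest.approx(995.0, abs=2.0)

    def test_single_spike_excluded_from_range(self):
        vals = np.zeros((1, 10000))
        vals[0, 5000] = 5000.0
        e = brick_layer_epochs(_binned(vals))[0]
        e.detrended = vals
        lo, hi = scale_range(e)
        assert hi < 1.0


def _quiet_epoch(rng, n_ch=8, n_bins=900, sigma=10.0, spread=100.0):
    """Epoch of white noise plus distinct channel offsets (span ~ spread)."""
    x = rng.normal(0, sigma, (n_ch, n_bins))
    x += np.linspace(-spread, spread, n_ch)[:, None]
    eps = brick_layer_epochs(_binned(x))
    return eps[0]


class TestReadability:
    def test_quiet_epoch_is_readable(self, rng):
        e = assess_readability(_quiet_epoch(rng))
        assert e.readability == "readable"
        assert e.reasons == ()

    def test_large_excursions_flag_high_range(self, rng):
        e = _quiet_epoch(rng)
        e.detrended[0, 100:160] += 1500.0
        e.detrended[1, 100:160] -= 1500.0
        e = assess_readability(e)
        assert "high_range" in e.reasons

    def test_flat_epoch_flags_no_recording(self, rng):
        x = rng.normal(0, 1.0, (8, 900))  # span ~ 10 µV
        e = brick_layer_epochs(_binned(x))[0]
        e = assess_readability(e)
        assert "no_recording" in e.reasons

    def test_synchronous_same_sign_step_flags_all_channel_deflection(self, rng):
        e = _quiet_epoch(rng)
        e.detrended[:, 400:410] += 200.0  # all channels, same sign
        e = assess_readability(e)
        assert "all_channel_deflection" in e.reasons

    def test_noisy_channel_flags_burst(self, rng):
        e = _quiet_epoch(rng)
        idx = rng.choice(900, 150, replace=False)  # >10% of bins
        e.detrended[2, idx] += 200.0 * rng.choice([-1, 1], 150)
        e = assess_readability(e)
        assert "burst" in e.reasons

    @pytest.mark.parametrize("gain", [1.0, 2.0, 5.0, 20.0])
    def test_readability_monotone_in_artifact_amplitude(self, rng, gain):
        """Scaling an unreadable epoch's artifact up never makes it readable."""
        base = _quiet_epoch(np.random.default_rng(5))
        base.detrended[:, 400:410] += gain * 200.0
        e = assess_readability(base)
        assert e.readability != "readable"

    def test_too_few_live_channels_rejected(self, rng):
        x = rng.normal(0, 10, (1, 900))
        e = brick_layer_epochs(_binned(x))[0]
        with pytest.raises(ValueError, match="live channels"):
            assess_readability(e)

    def test_dead_channels_excluded_from_rules(self, rng):
        lay = scalp29_layout()
        x = rng.normal(0, 10, (29, 900))
        x += np.linspace(-80, 80, 29)[:, None]
        dead_idx = [lay.labels.index(l) for l in lay.dead_labels]
        x[dead_idx] = 0.0
        b = _binned(x, labels=lay.labels, layout=lay)
        e = assess_readability(brick_layer_epochs(b)[0])
        assert e.readability == "readable"
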