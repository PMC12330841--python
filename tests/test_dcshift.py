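"""Gaussian-plus-quadratic fitting and scalp/ECoG similarity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalpsd.dcshift import (
    DCShiftFit,
    compare_event,
    derive_metrics,
    fit_gaussian_quadratic,
    scale_and_cod,
    select_peak_channel,
)

BIN_T = np.arange(30) * 8.0 + 4.0  # 240-s window of 8-s bin centres


def _series(A, t0, sigma, c0=0.0, c1=0.0, c2=0.0, t=BIN_T):
    return A * np.exp(-((t - t0) ** 2) / (2 * sigma**2)) + c0 + c1 * t + c2 * t * t


class TestFit:
    def test_noiseless_recovery_at_study_scale(self):
        v = _series(-3771.0, 120.0, 26.8, 50.0, 0.1, -1e-4)
        f = fit_gaussian_quadratic(BIN_T, v)
        truth = np.array([-3771.0, 120.0, 26.8, 50.0, 0.1, -1e-4])
        assert f.converged
        assert np.all(np.abs((f.params - truth) / truth) < 1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        A=st.floats(-5000, -100),
        t0=st.floats(80, 160),
        sigma=st.floats(10, 45),
        c0=st.floats(-200, 200),
        c1=st.floats(-0.5, 0.5),
        c2=st.floats(-1e-3, 1e-3),
    )
    def test_noiseless_recovery_is_exact_for_admissible_parameters(
        self, A, t0, sigma, c0, c1, c2
    ):
        v = _series(A, t0, sigma, c0, c1, c2)
        f = fit_gaussian_quadratic(BIN_T, v)
        assert f.converged
        assert f.A == pytest.approx(A, rel=1e-6)
        assert f.t0 == pytest.approx(t0, abs=1e-4)
        assert f.sigma == pytest.approx(sigma, rel=1e-6)

    def test_pure_quadratic_flagged_no_shift(self, rng):
        v = _series(0.0, 120.0, 30.0, 20.0, 0.3, -5e-4) + rng.normal(0, 1, 30)
        f = fit_gaussian_quadratic(BIN_T, v)
        assert f.converged
        assert "no shift" in f.flags

    def test_two_percent_noise_keeps_pulse_errors_under_11_percent(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            v = _series(-3771.0, 120.0, 26.8, 50.0, 0.1, -1e-4)
            v = v + rng.normal(0, 0.02 * 3771.0, v.size)
            f = fit_gaussian_quadratic(BIN_T, v)
            assert f.converged
            # pulse parameters: amplitude, peak time, width
            assert np.all(f.rel_param_err[[0, 2]] < 0.11)
            assert f.rel_param_err[1] < 0.11

    def test_mask_excludes_artifact_bins(self):
        v = _series(-500.0, 120.0, 25.0)
        v_bad = v.copy()
        v_bad[[3, 4]] = 4000.0  # gross artifact
        mask = np.zeros(30, dtype=bool)
        mask[[3, 4]] = True
        f = fit_gaussian_quadratic(BIN_T, v_bad, mask=mask)
        assert f.A == pytest.approx(-500.0, rel=1e-6)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="unmasked bins"):
            fit_gaussian_quadratic(BIN_T[:10], _series(-500, 40, 10, t=BIN_T[:10]))

    def test_window_far_from_origin_is_well_conditioned(self):
        t = BIN_T + 9.5 * 3600.0
        v = _series(-457.0, 9.5 * 3600 + 120.0, 30.1, 40.0, 0.01, -1e-5, t=t)
        f = fit_gaussian_quadratic(t, v)
        assert f.A == pytest.approx(-457.0, rel=1e-6)
        assert f.t0 == pytest.approx(9.5 * 3600 + 120.0, abs=1e-3)


class TestDerivedMetrics:
    def test_fwhm_is_2_355_sigma(self):
        f = DCShiftFit(A=-1, t0=0, sigma=1.0, c0=0, c1=0, c2=0,
                       rel_param_err=np.zeros(6), converged=True)
        fwhm, freq = derive_metrics(f)
        assert fwhm == pytest.approx(2.355)
        assert freq == pytest.approx(1 / 2.355)

    def test_sigma_26_84_gives_study_duration(self):
        f = DCShiftFit(A=-1, t0=0, sigma=63.2 / 2.355, c0=0, c1=0, c2=0,
                       rel_param_err=np.zeros(6), converged=True)
        assert derive_metrics(f)[0] == pytest.approx(63.2)

    def test_frequency_inverse_of_fwhm(self):
        f = DCShiftFit(A=-1, t0=0, sigma=70.9 / 2.355, c0=0, c1=0, c2=0,
                       rel_param_err=np.zeros(6), converged=True)
        assert derive_metrics(f)[1] == pytest.approx(1 / 70.9)
        assert derive_metrics(f)[1] == pytest.approx(0.0141, abs=1e-4)

    def test_fwhm_sigma_ratio_exact_for_any_fit(self):
        for sigma in (0.5, 12.0, 26.8, 301.0):
            f = DCShiftFit(A=-1, t0=0, sigma=sigma, c0=0, c1=0, c2=0,
                           rel_param_err=np.zeros(6), converged=True)
            assert f.fwhm / f.sigma == 2.355


def _fit(A, rel_a=0.01, channel=None):
    err = np.full(6, rel_a)
    return DCShiftFit(A=A, t0=120.0, sigma=25.0, c0=0, c1=0, c2=0,
                      rel_param_err=err, converged=True, channel=channel)


class TestPeakChannel:
    def test_maximum_absolute_amplitude_wins(self):
        fits = {"B3": _fit(-400), "B4": _fit(-457), "C4": _fit(-300)}
        assert select_peak_channel(fits) == "B4"

    def test_single_channel(self):
        assert select_peak_channel({"C1": _fit(-100)}) == "C1"

    def test_tie_broken_by_lower_relative_error(self):
        fits = {"A1": _fit(-457, rel_a=0.05), "B1": _fit(-457, rel_a=0.02)}
        assert select_peak_channel(fits) == "B1"

    def test_no_converged_fits_raises(self):
        f = _fit(-100)
        f.converged = False
        with pytest.raises(ValueError, match="no converged"):
            select_peak_channel({"A1": f})


class TestCod:
    def test_exact_proportionality_gives_unity(self):
        scalp = _series(-457.0, 120.0, 30.0)
        ecog = 8.26 * scalp
        ratio, cod = scale_and_cod(scalp, ecog, ratio=1 / 8.26)
        assert cod == pytest.approx(1.0)

    def test_independent_noise_pairs_have_low_cod(self):
        rng = np.random.default_rng(0)
        cods = []
        for _ in range(100):
            _, cod = scale_and_cod(rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                                   ratio=1.0)
            cods.append(cod)
        assert np.mean(np.array(cods) < 0.2) >= 0.95

    @pytest.mark.parametrize("a,b", [(3.0, 1.0), (-2.0, 5.0), (0.121, -7.0)])
    def test_cod_invariant_to_affine_rescaling(self, rng, a, b):
        x = _series(-457.0, 120.0, 30.0) + rng.normal(0, 10, 30)
        y = _series(-3771.0, 117.0, 27.0) + rng.normal(0, 80, 30)
        _, cod0 = scale_and_cod(x, y, ratio=0.121)
        _, cod1 = scale_and_cod(a * x + b, y, ratio=0.121)
        assert cod1 == pytest.approx(cod0, abs=1e-12)
        assert 0.0 <= cod1 <= 1.0

    def test_zero_variance_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            scale_and_cod(np.zeros(30), np.ones(30), ratio=1.0)


class TestCompareEvent:
    def test_identical_series_unity(self):
        v = _series(-457.0, 120.0, 30.0, 10.0, 0.05, 1e-5)
        rec = compare_event(BIN_T, v, BIN_T, v)
        assert rec.ratio == pytest.approx(1.0)
        assert rec.peak_dt == pytest.approx(0.0, abs=1e-6)
        assert rec.cod == pytest.approx(1.0)
        assert rec.similar

    def test_study_geometry_pair_is_similar(self, rng):
        ecog = _series(-3771.0, 120.0, 63.2 / 2.355, 30.0, -0.1, 1e-4)
        scalp = _series(-456.3, 122.89, 70.9 / 2.355, -20.0, 0.05, -2e-4)
        ecog = ecog + rng.normal(0, 75.0, 30)
        scalp = scalp + rng.normal(0, 9.0, 30)
        rec = compare_event(BIN_T, scalp, BIN_T, ecog)
        assert rec.similar
        assert rec.ratio == pytest.approx(0.121, abs=0.01)
        assert rec.peak_dt == pytest.approx(2.89, abs=3.0)

    def test_decorrelated_pair_is_not_similar(self):
        ecog = _series(-3771.0, 120.0, 26.8)
        # time-reversed and shifted scalp pulse
        scalp = _series(-456.3, 240.0 - 120.0 + 40.0, 30.1, t=BIN_T)
        rec = compare_event(BIN_T, scalp, BIN_T, ecog)
        assert rec.usable
        assert rec.cod < 0.80
        assert not rec.similar

    def test_dict_input_selects_peak_channels(self):
        scalp = {
            "C4": _series(-457.0, 120.0, 30.0),
            "C5": _series(-200.0, 120.0, 30.0),
        }
        ecog = {"3": _series(-3771.0, 118.0, 26.8), "2": _series(-700.0, 118.0, 26.8)}
        rec = compare_event(BIN_T, scalp, BIN_T, ecog)
        assert rec.scalp_fit.channel == "C4"
        assert rec.ecog_fit.channel == "3"
        assert rec.ratio == pytest.approx(457.0 / 3771.0, rel=1e-4)
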