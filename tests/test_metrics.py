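"""Shielding factors, Welch spectra, noise covariance and dipole fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megshield import (
    Recording,
    estimate_noise_covariance,
    fit_dipole,
    shielding_factor_fft,
    shielding_factor_norm,
    source_errors,
    welch_spectrum,
)
from megshield.metrics import FitResult
from megshield.simulate import (
    DipoleSource,
    dipole_forward_sphere,
    random_tangential_dipole,
)


def _tone_rec(freqs_amps, sfreq=1000.0, duration=20.0, n_chan=3):
    t = np.arange(int(duration * sfreq)) / sfreq
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return Recording(
        np.tile(sig, (n_chan, 1)), sfreq, [f"MAG-{i:03d}" for i in range(n_chan)]
    )


class TestShieldingFactorNorm:
    def test_identity_is_one(self, rng):
        rec = _tone_rec([(2.0, 1e-12)])
        assert shielding_factor_norm(rec, rec) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_attenuation(self):
        rec = _tone_rec([(2.0, 1e-12)])
        proc = rec.with_data(rec.data / 10.0)
        assert shielding_factor_norm(rec, proc) == pytest.approx(10.0, rel=1e-10)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_common_rescale(self, scale):
        rng = np.random.default_rng(77)
        raw = Recording(
            rng.standard_normal((4, 5000)), 1000.0,
            [f"MAG-{i}" for i in range(4)],
        )
        proc = raw.with_data(raw.data * 0.2 + rng.standard_normal((4, 5000)) * 0.01)
        a = shielding_factor_norm(raw, proc)
        b = shielding_factor_norm(
            raw.with_data(raw.data * scale), proc.with_data(proc.data * scale)
        )
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_processed_flagged_infinite(self):
        rec = _tone_rec([(2.0, 1e-12)])
        proc = rec.with_data(np.zeros_like(rec.data))
        assert shielding_factor_norm(rec, proc) == np.inf


class TestShieldingFactorFFT:
    def test_identity_is_one(self):
        rec = _tone_rec([(20.0, 1e-12)])
        assert shielding_factor_fft(rec, rec, 20.0) == pytest.approx(1.0, rel=1e-12)

    def test_selective_attenuation(self):
        raw = _tone_rec([(20.0, 1e-12), (40.0, 1e-12)])
        proc = _tone_rec([(20.0, 1e-14), (40.0, 1e-12)])
        assert shielding_factor_fft(raw, proc, 20.0) == pytest.approx(100.0, rel=0.02)
        assert shielding_factor_fft(raw, proc, 40.0) == pytest.approx(1.0, rel=0.02)

    def test_agrees_with_norm_sf_on_single_tone(self):
        raw = _tone_rec([(5.0, 1e-12)])
        proc = raw.with_data(raw.data / 30.0)
        a = shielding_factor_fft(raw, proc, 5.0)
        b = shielding_factor_norm(raw, proc)
        assert 0.5 < a / b < 2.0


class TestWelchSpectrum:
    def test_sine_peak_closed_form(self):
        # Hann window, exact-bin sine: ASD peak = A / sqrt(3 df)
        sfreq, A = 1000.0, 1e-12
        f0 = 250 * sfreq / 4096
        rec = _tone_rec([(f0, A)], sfreq=sfreq, n_chan=1)
        freqs, asd = welch_spectrum(rec)
        df = freqs[1] - freqs[0]
        assert asd[0].max() == pytest.approx(A / np.sqrt(3.0 * df), rel=0.05)

    def test_white_noise_level(self, rng):
        level = 3e-15
        sfreq = 1000.0
        data = rng.standard_normal((1, 60000)) * level * np.sqrt(sfreq / 2.0)
        rec = Recording(data, sfreq, ["MAG-000"])
        freqs, asd = welch_spectrum(rec)
        band = (freqs > 10) & (freqs < 400)
        assert np.mean(asd[0][band]) == pytest.approx(level, rel=0.1)

    def test_parseval(self, rng):
        data = rng.standard_normal((1, 40960)) * 1e-13
        rec = Recording(data, 1000.0, ["MAG-000"])
        freqs, asd = welch_spectrum(rec)
        df = freqs[1] - freqs[0]
        power_spectral = np.sum(asd[0] ** 2) * df
        power_time = np.var(data)
        assert power_spectral == pytest.approx(power_time, rel=0.02)


class TestNoiseCovariance:
    def test_iid_noise_recovers_identity(self, rng):
        data = rng.standard_normal((20, 20000))
        rec = Recording(data, 1000.0, [f"CH{i}" for i in range(20)])
        nc = estimate_noise_covariance(rec)
        off = nc.cov - np.diag(np.diag(nc.cov))
        assert np.abs(off).max() < 0.05
        white = nc.whitener @ data
        c = np.cov(white)
        assert np.abs(c - np.eye(20)).max() < 0.1

    def test_rank_deficient_baseline_still_positive_definite(self, rng):
        data = rng.standard_normal((30, 10))  # fewer samples than channels
        rec = Recording(data, 1000.0, [f"CH{i}" for i in range(30)])
        nc = estimate_noise_covariance(rec)
        assert np.linalg.eigvalsh(nc.cov).min() > 0
        assert nc.rank < 30

    def test_whitener_ignores_empty_directions(self, rng):
        # data confined to a subspace: the whitener must not amplify the
        # orthogonal complement
        basis = np.linalg.qr(rng.standard_normal((30, 5)))[0]
        data = basis @ rng.standard_normal((5, 5000))
        rec = Recording(data, 1000.0, [f"CH{i}" for i in range(30)])
        nc = estimate_noise_covariance(rec)
        v = rng.standard_normal(30)
        v -= basis @ (basis.T @ v)
        assert np.linalg.norm(nc.whitener @ v) < 1e-6 * np.linalg.norm(
            nc.whitener @ (basis @ np.ones(5))
        )


class TestFitDipole:
    def test_noiseless_self_consistency(self, helmet, rng):
        dip = random_tangential_dipole(0.05, rng)
        pat = dipole_forward_sphere(dip, helmet)
        fit = fit_dipole(pat, helmet)
        assert np.linalg.norm(fit.position - dip.position) < 1e-4  # < 0.1 mm
        assert abs(fit.amplitude - dip.peak_amplitude) < 1e-3 * dip.peak_amplitude
        assert fit.goodness_of_fit == pytest.approx(1.0, abs=1e-9)

    def test_moment_orientation_recovered(self, helmet, rng):
        dip = random_tangential_dipole(0.06, rng)
        pat = dipole_forward_sphere(dip, helmet)
        fit = fit_dipole(pat, helmet)
        cosine = abs(fit.moment @ dip.orientation) / fit.amplitude
        assert cosine > 0.9999


class TestSourceErrors:
    def test_exact_fits_give_zero(self, rng):
        truths = [random_tangential_dipole(0.05, rng) for _ in range(3)]
        fits = [
            FitResult(t.position, t.peak_amplitude * t.orientation, 1.0)
            for t in truths
        ]
        s = source_errors(fits, truths)
        assert s.localization_error == 0.0
        assert s.amplitude_error == 0.0
        assert s.n == 3

    def test_known_displacement(self, rng):
        t = random_tangential_dipole(0.05, rng)
        shifted = t.position + np.array([0.0, 0.003, 0.0])
        fits = [FitResult(shifted, t.peak_amplitude * t.orientation, 1.0)]
        s = source_errors(fits, [t])
        assert s.localization_error == pytest.approx(0.003, rel=1e-12)

    def test_per_depth_breakdown(self, rng):
        truths = [random_tangential_dipole(r, rng) for r in (0.02, 0.02, 0.05)]
        fits = [
            FitResult(t.position, t.peak_amplitude * t.orientation, 1.0)
            for t in truths
        ]
        s = source_errors(fits, truths)
        assert set(s.per_depth) == {0.02, 0.05}
        assert s.per_depth[0.02]["n"] == 2
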