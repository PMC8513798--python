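"""Extended-basis construction and the eSSS processing pipeline."""

from types import SimpleNamespace

import numpy as np
import pytest

from megshield import (
    Recording,
    apply_esss,
    apply_sss,
    condition_report,
    estimate_interference_subspace,
    extend_external_basis,
    extend_with_band_components,
)
from megshield.simulate import (
    add_sensor_noise,
    random_tangential_dipole,
    simulate_dipole_trials,
)


@pytest.fixture(scope="module")
def joint_subspace(helmet, empty_room):
    return estimate_interference_subspace(
        empty_room, k=8, mode="joint", mag_scale=100.0, array=helmet
    )


class TestExtendExternalBasis:
    def test_no_pcs_reduces_to_sss_span(self, helmet, basis, rng):
        ext = extend_external_basis(basis, None)
        assert ext.D_e == basis.D_out
        phi = rng.standard_normal((306, 3)) * 1e-12
        rec = Recording(phi, 1000.0, helmet.channel_names)
        from megshield import decompose, reconstruct_internal

        a = reconstruct_internal(basis, decompose(basis, rec)).data
        b = reconstruct_internal(ext, decompose(ext, rec)).data
        assert np.abs(a - b).max() < 1e-10 * np.abs(a).max()

    def test_pcs_inside_external_span_add_nothing(self, helmet, basis, rng):
        # fabricate a "measured" subspace lying exactly in span(S_out)
        U, _, _ = np.linalg.svd(
            basis.S_out @ rng.standard_normal((15, 4)), full_matrices=False
        )
        fake = SimpleNamespace(
            U=U[:, :4],
            k=4,
            scaling=basis.row_scale.copy(),
            channel_names=list(basis.channel_names),
            source_meta={},
        )
        with pytest.warns(UserWarning, match="dropped"):
            ext = extend_external_basis(basis, fake)
        assert ext.D_e == 15

    def test_default_pipeline_gives_103_vectors(self, basis, joint_subspace):
        ext = extend_external_basis(basis, joint_subspace)
        assert ext.D_in + ext.D_e == 103

    def test_external_block_orthonormal_and_contains_sout(
        self, basis, joint_subspace
    ):
        ext = extend_external_basis(basis, joint_subspace)
        G = ext.S_out_e.T @ ext.S_out_e
        assert np.abs(G - np.eye(ext.D_e)).max() < 1e-10
        resid = basis.S_out - ext.S_out_e @ (ext.S_out_e.T @ basis.S_out)
        assert np.abs(resid).max() < 1e-8


class TestBandExtension:
    def test_zero_band_components_equal_plain_extension(
        self, basis, joint_subspace, empty_room
    ):
        a = extend_external_basis(basis, joint_subspace)
        b = extend_with_band_components(
            basis, joint_subspace, empty_room, band=(16.8, 18.8), n_components=0
        )
        assert a.D_e == b.D_e
        assert np.allclose(a.S_out_e, b.S_out_e)

    def test_narrowband_artifact_removed_only_by_band_pcs(
        self, helmet, basis, empty_room, rng
    ):
        # artifact pattern orthogonal to span(S_out): plain eSSS leaves a
        # large residual at 17.8 Hz, the band-extended basis removes it
        from megshield.metrics import _fft_peak_amplitudes

        v = rng.standard_normal(306)
        Uout, _, _ = np.linalg.svd(basis.S_out, full_matrices=False)
        v -= Uout @ (Uout.T @ v)
        pat = v / basis.row_scale
        pat *= 2e-9 / np.abs(pat[helmet.mag_mask]).max()
        t = np.arange(20000) / 1000.0
        rec = Recording(
            pat[:, None] * np.sin(2 * np.pi * 17.8 * t)[None, :],
            1000.0,
            helmet.channel_names,
        )
        rec = add_sensor_noise(rec, seed=3, array=helmet)
        plain = apply_esss(rec, helmet, empty_room, basis=basis)
        prime = apply_esss(
            rec, helmet, empty_room, basis=basis,
            band=(16.8, 18.8), band_pcs=3, band_recording=rec,
        )
        mag = helmet.mag_mask
        a_raw = np.linalg.norm(_fft_peak_amplitudes(rec.data[mag], 1000.0, 17.8))
        a_plain = np.linalg.norm(_fft_peak_amplitudes(plain.data[mag], 1000.0, 17.8))
        a_prime = np.linalg.norm(_fft_peak_amplitudes(prime.data[mag], 1000.0, 17.8))
        assert a_plain > 0.2 * a_raw
        assert a_prime < 0.01 * a_raw

    def test_band_outside_nyquist_rejected(self, basis, joint_subspace, empty_room):
        with pytest.raises(ValueError):
            extend_with_band_components(
                basis, joint_subspace, empty_room, band=(400.0, 600.0)
            )


class TestApplyESSS:
    def test_zero_in_zero_out(self, helmet, empty_room, basis):
        rec = Recording(np.zeros((306, 4)), 1000.0, helmet.channel_names)
        out = apply_esss(rec, helmet, empty_room, basis=basis)
        assert not out.data.any()

    def test_internal_dipole_preserved(self, helmet, empty_room, basis, rng):
        dip = random_tangential_dipole(0.05, rng)
        trials = simulate_dipole_trials(dip, helmet, n_trials=3)
        out = apply_esss(trials, helmet, empty_room, basis=basis)
        rel = np.linalg.norm(out.data - trials.data) / np.linalg.norm(trials.data)
        assert rel < 0.02

    def test_idempotent(self, helmet, empty_room, basis, rng):
        rec = Recording(
            rng.standard_normal((306, 3)) * 1e-12, 1000.0, helmet.channel_names
        )
        once = apply_esss(rec, helmet, empty_room, basis=basis)
        twice = apply_esss(once, helmet, empty_room, basis=basis)
        assert np.abs(twice.data - once.data).max() < 1e-10 * np.abs(once.data).max()

    def test_channel_mismatch_refused(self, helmet, empty_room, basis):
        rec = Recording(
            np.zeros((306, 3)),
            1000.0,
            ["X-000"] + helmet.channel_names[1:],
        )
        with pytest.raises(ValueError, match="channel"):
            apply_esss(rec, helmet, empty_room, basis=basis)


class TestConditionReport:
    def test_orthonormal_matrix_has_unit_condition(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((40, 40)))
        rep = condition_report(SimpleNamespace(S=Q))
        assert rep["n_vectors"] == 40
        assert rep["condition_number"] == pytest.approx(1.0, abs=1e-12)

    def test_extension_leaves_conditioning_similar(self, basis, joint_subspace):
        ext = extend_external_basis(basis, joint_subspace)
        c_sss = condition_report(basis)["condition_number"]
        c_esss = condition_report(ext)["condition_number"]
        assert c_esss / c_sss < 1.5

    def test_near_parallel_vector_explodes_condition(self, basis, rng):
        # guard: merging without a rank cut would be numerically singular
        v = basis.S_out[:, 0].copy()
        w = rng.standard_normal(306)
        w -= (w @ v) * v
        w /= np.linalg.norm(w)
        bad = np.column_stack([basis.S_out, v + 1e-6 * w])
        rep = condition_report(SimpleNamespace(S=bad))
        assert rep["condition_number"] > 1e5
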