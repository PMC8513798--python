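"""Generators: spherical-conductor dipole forward model, interference,
sensor noise and the empty-room fixture."""

import numpy as np
import pytest
import sympy as sp

from megshield import (
    DipoleSource,
    Recording,
    add_sensor_noise,
    decompose,
    dipole_forward_sphere,
    simulate_dipole_trials,
    simulate_empty_room,
    simulate_interference,
)
from megshield.simulate import (
    empty_room_specs,
    random_tangential_dipole,
    sarvas_field,
)
from megshield.simulate import test_interference_specs as interference_specs


class TestDipoleForward:
    def test_radial_dipole_is_silent(self, helmet):
        pos = np.array([0.02, 0.01, 0.04])
        radial = pos / np.linalg.norm(pos)
        tang = np.cross(pos, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        # construct the radial source directly (DipoleSource enforces
        # tangentiality, which is exactly what this checks)
        sig_radial = sarvas_field(pos, 1e-6 * radial, np.array([[0.0, 0.05, 0.11]]))
        sig_tang = sarvas_field(pos, 1e-6 * tang, np.array([[0.0, 0.05, 0.11]]))
        assert np.abs(sig_radial).max() < 1e-15 * np.abs(sig_tang).max()

    def test_linearity_in_moment(self, helmet, rng):
        dip1 = random_tangential_dipole(0.04, rng, peak_amplitude=1e-6)
        dip2 = DipoleSource(dip1.position, dip1.orientation, 2e-6)
        a = dipole_forward_sphere(dip1, helmet)
        b = dipole_forward_sphere(dip2, helmet)
        assert np.array_equal(b, 2.0 * a)

    def test_against_symbolic_oracle(self):
        # independent evaluation: the scalar F is written symbolically and
        # grad F obtained by symbolic differentiation, not the hand-coded
        # closed form
        x, y, z = sp.symbols("x y z", real=True)
        r0v = sp.Matrix([0.012, -0.021, 0.033])
        qv = sp.Matrix([3.1e-7, 1.7e-7, (-3.1e-7 * 0.012 - 1.7e-7 * -0.021) / 0.033])
        qv = qv - (qv.dot(r0v) / r0v.dot(r0v)) * r0v  # exactly tangential
        rv = sp.Matrix([x, y, z])
        d = rv - r0v
        a = sp.sqrt(d.dot(d))
        rn = sp.sqrt(rv.dot(rv))
        F = a * (rn * a + rn**2 - r0v.dot(rv))
        gradF = sp.Matrix([sp.diff(F, s) for s in (x, y, z)])
        qxr0 = qv.cross(r0v)
        Bsym = (1e-7 / F**2) * (F * qxr0 - (qxr0.dot(rv)) * gradF)
        fB = sp.lambdify((x, y, z), Bsym, "numpy")
        pts = np.array(
            [
                [0.00, 0.02, 0.12],
                [0.08, -0.05, 0.07],
                [-0.11, 0.01, 0.04],
                [0.03, 0.10, -0.01],
                [-0.05, -0.06, 0.09],
            ]
        )
        q = np.array(qv.T.tolist()[0], dtype=float)
        r0 = np.array(r0v.T.tolist()[0], dtype=float)
        B = sarvas_field(r0, q, pts)
        for p, b in zip(pts, B):
            expected = np.array(fB(*p), dtype=float).ravel()
            assert np.linalg.norm(b - expected) < 1e-10 * np.linalg.norm(expected)

    def test_source_outside_region_rejected(self, helmet, rng):
        dip = random_tangential_dipole(0.11, rng)
        with pytest.raises(ValueError, match="outside"):
            dipole_forward_sphere(dip, helmet)

    def test_tangentiality_enforced(self):
        with pytest.raises(ValueError, match="tangential"):
            DipoleSource(np.array([0.0, 0.0, 0.05]), np.array([0.0, 0.0, 1.0]), 1e-6)


class TestDipoleTrials:
    def test_default_duration_20s(self, helmet, rng):
        dip = random_tangential_dipole(0.05, rng)
        rec = simulate_dipole_trials(dip, helmet)
        assert rec.n_samples == 20000
        assert rec.sfreq == 1000.0

    def test_trial_structure(self, helmet, rng):
        dip = random_tangential_dipole(0.05, rng)
        rec = simulate_dipole_trials(dip, helmet, n_trials=5)
        trial = rec.data.reshape(306, 5, 200)
        assert not trial[:, :, 100:].any()  # silent second half
        assert np.array_equal(trial[:, 0], trial[:, 4])  # no jitter


class TestInterference:
    def test_preset_peak_matches_magnetometer_dynamic_range(self, perturbed_helmet):
        rec = simulate_interference(
            perturbed_helmet, empty_room_specs(), duration=30.0, seed=4
        )
        peak_nT = np.abs(rec.data[perturbed_helmet.mag_mask]).max() * 1e9
        assert 15.0 <= peak_nT <= 25.0

    def test_lies_in_external_span(self, helmet, basis):
        rec = simulate_interference(
            helmet, interference_specs(), duration=1.0, seed=5
        )
        m = decompose(basis, rec)
        assert np.linalg.norm(m.x_in) < 1e-10 * np.linalg.norm(m.x_out)

    def test_seeded_determinism(self, helmet):
        a = simulate_interference(helmet, empty_room_specs(), duration=1.0, seed=6)
        b = simulate_interference(helmet, empty_room_specs(), duration=1.0, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_nyquist_guard(self, helmet):
        from megshield.simulate import InterferenceSpec

        with pytest.raises(ValueError, match="Nyquist"):
            simulate_interference(
                helmet, [InterferenceSpec(1, 0, 300.0, 1e-9)], duration=1.0,
                sfreq=500.0,
            )


class TestSensorNoise:
    def test_white_noise_level(self, helmet):
        zero = Recording(np.zeros((306, 20000)), 1000.0, helmet.channel_names)
        out = add_sensor_noise(zero, correlated_fraction=0.0, seed=7, array=helmet)
        sd = out.data.std(axis=1, ddof=1)
        target = np.where(helmet.mag_mask, 3e-15, 3e-13) * np.sqrt(500.0)
        assert np.all(np.abs(sd / target - 1.0) < 0.05)

    def test_zero_levels_identity(self, helmet):
        rec = Recording(np.ones((306, 10)), 1000.0, helmet.channel_names)
        out = add_sensor_noise(rec, mag_level=0.0, grad_level=0.0, seed=1)
        assert np.array_equal(out.data, rec.data)

    def test_correlated_part_rank_five(self, helmet):
        zero = Recording(np.zeros((306, 4000)), 1000.0, helmet.channel_names)
        out = add_sensor_noise(zero, correlated_fraction=0.9, seed=8, array=helmet)
        sd = np.where(helmet.mag_mask, 3e-15, 3e-13) * np.sqrt(500.0)
        ev = np.linalg.eigvalsh(np.cov(out.data / sd[:, None]))[::-1]
        assert ev[:5].sum() / ev.sum() > 0.85  # 5 patterns carry ~90% power
        assert ev[5] < 0.01 * ev[0]


class TestEmptyRoom:
    def test_one_minute_default(self, helmet):
        rec = simulate_empty_room(helmet, seed=0)
        assert rec.n_samples == 60000

    def test_spatial_subspace_stable_across_seeds(self, perturbed_helmet):
        from scipy.linalg import subspace_angles

        from megshield import estimate_interference_subspace

        subs = [
            estimate_interference_subspace(
                simulate_empty_room(perturbed_helmet, duration=10.0, seed=s),
                k=8, mode="joint", array=perturbed_helmet,
            )
            for s in (21, 22)
        ]
        angles = subspace_angles(subs[0].U, subs[1].U)
        assert angles.max() < 1e-3
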