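"""Synthetic-data generators: dipole trials, external interference,
sensor noise and empty-room fixtures.

The generators emulate the simulation conditions of the study design
this package reproduces: tangential current dipoles in a spherically
symmetric conductor (closed-form field of a primary current dipole plus
its volume currents), homogeneous (degree-1) external fields below 2 Hz
at roughly the magnetometer dynamic range (+-20 nT), first-order
gradient (degree-2) fields near 20 Hz at 10% relative amplitude, and
sensor noise with uncorrelated and rank-5 correlated parts.  All
generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SensorArray
from .harmonics import HarmonicIndex, multipole_field
from .recording import Recording

__all__ = [
    "DipoleSource",
    "InterferenceSpec",
    "dipole_forward_sphere",
    "simulate_dipole_trials",
    "simulate_interference",
    "add_sensor_noise",
    "simulate_empty_room",
    "empty_room_specs",
    "test_interference_specs",
    "random_tangential_dipole",
]

MU0_OVER_4PI = 1e-7  # T*m/A

#: Peak amplitude of each homogeneous interference component (T), chosen so
#: the combined degree-1 field peaks near the +-20 nT magnetometer dynamic
#: range when the three Cartesian components align on a diagonally oriented
#: sensor (20 nT / sqrt(3) each).
L1_COMPONENT_AMPLITUDE = 20e-9 / np.sqrt(3.0)
#: First-order-gradient components at ~10% of the homogeneous amplitude.
L2_RELATIVE_AMPLITUDE = 0.1

#: Component frequencies (Hz). Homogeneous fields sit below 2 Hz and the
#: gradient fields near 20 Hz; each (l, m) component gets its own frequency
#: so the eight interference degrees of freedom are temporally resolvable.
EMPTY_ROOM_L1_FREQS = {-1: 0.9, 0: 1.1, 1: 1.3}
EMPTY_ROOM_L2_FREQS = {-2: 19.2, -1: 19.6, 0: 20.0, 1: 20.4, 2: 20.8}
#: The test (subject-measurement analog) interference reuses the same
#: spatial components at shifted frequencies.
TEST_L1_FREQS = {-1: 0.5, 0: 0.7, 1: 0.85}
TEST_L2_FREQS = {-2: 22.2, -1: 22.6, 0: 23.0, 1: 23.4, 2: 23.8}

DEFAULT_MAG_NOISE = 3e-15  # T/sqrt(Hz)
DEFAULT_GRAD_NOISE = 3e-13  # (T/m)/sqrt(Hz)  (= 3 fT/cm/sqrt(Hz))


@dataclass(frozen=True)
class DipoleSource:
    """Tangential current dipole inside the conductor sphere."""

    position: np.ndarray  # (3,) m from the conductor origin
    orientation: np.ndarray  # (3,) unit, tangential
    peak_amplitude: float  # A*m (1000 nAm = 1e-6)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-10:
            raise ValueError("dipole orientation must be a unit vector")
        if abs(float(self.orientation @ self.position)) > 1e-10 * max(
            np.linalg.norm(self.position), 1e-30
        ):
            raise ValueError("dipole orientation must be tangential to the sphere")


@dataclass(frozen=True)
class InterferenceSpec:
    """One external multipole component with its tone frequency."""

    l: int  # 1 (homogeneous) or 2 (first-order gradient)
    m: int
    frequency: float  # Hz
    amplitude: float  # T, peak reading of the most-coupled magnetometer

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("interference degree l must be >= 1")
        if abs(self.m) > self.l:
            raise ValueError("|m| must not exceed l")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def empty_room_specs(
    include_l1_orders=(-1, 0, 1), include_l2_orders=(-2, -1, 0, 1, 2)
) -> list[InterferenceSpec]:
    """Interference preset of the empty-room fixture.

    Restricting the included orders creates the setting where a *new*
    interference source later contributes field components (in both
    degrees) that the empty-room data never contained.
    """
    specs = [
        InterferenceSpec(1, m, EMPTY_ROOM_L1_FREQS[m], L1_COMPONENT_AMPLITUDE)
        for m in include_l1_orders
    ]
    specs += [
        InterferenceSpec(2, m, EMPTY_ROOM_L2_FREQS[m],
                         L2_RELATIVE_AMPLITUDE * L1_COMPONENT_AMPLITUDE)
        for m in include_l2_orders
    ]
    return specs


def test_interference_specs(
    include_l1_orders=(-1, 0, 1), include_l2_orders=(-2, -1, 0, 1, 2)
) -> list[InterferenceSpec]:
    """Same spatial components as the empty-room preset, shifted frequencies."""
    specs = [
        InterferenceSpec(1, m, TEST_L1_FREQS[m], L1_COMPONENT_AMPLITUDE)
        for m in include_l1_orders
    ]
    specs += [
        InterferenceSpec(2, m, TEST_L2_FREQS[m],
                         L2_RELATIVE_AMPLITUDE * L1_COMPONENT_AMPLITUDE)
        for m in include_l2_orders
    ]
    return specs


# ---------------------------------------------------------------------------
# Dipole forward model (spherically symmetric conductor)
# ---------------------------------------------------------------------------

def sarvas_field(r0: np.ndarray, q: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a spherical conductor.

    ``r0``: dipole position, ``q``: dipole moment (A*m), both relative to
    the conductor center; ``points``: (n, 3) field points outside the
    conductor.  Closed form including volume currents; radial dipoles
    (q parallel to r0) produce exactly zero field.
    """
    r = np.atleast_2d(points)
    d = r - r0
    a = np.linalg.norm(d, axis=1)
    rn = np.linalg.norm(r, axis=1)
    dr = np.einsum("ij,ij->i", d, r)
    F = a * (rn * a + rn**2 - r0 @ r.T)
    gradF = (
        (a**2 / rn + dr / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + dr / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI * (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF) / (F**2)[:, None]
    return B


def dipole_forward_sphere(
    dipole: DipoleSource,
    array: SensorArray,
    conductor_origin: np.ndarray | None = None,
) -> np.ndarray:
    """Channel signal vector (length N) of a unit-waveform dipole.

    The returned vector corresponds to the dipole at its peak amplitude;
    it is linear in the dipole moment.
    """
    origin = (
        np.zeros(3) if conductor_origin is None
        else np.asarray(conductor_origin, dtype=float)
    )
    pos = dipole.position - origin
    depth = np.linalg.norm(pos)
    if depth == 0:
        raise ValueError("dipole at the conductor origin produces no field")
    if depth >= array.inner_radius:
        raise ValueError(
            f"dipole at radius {depth:.3f} m is outside the source region "
            f"(inner_radius {array.inner_radius:.3f} m)"
        )
    pts, normals, weights, owner = array.stacked_integration()
    B = sarvas_field(pos, dipole.peak_amplitude * dipole.orientation, pts - origin)
    contrib = weights * np.einsum("ij,ij->i", B, normals)
    return np.bincount(owner, weights=contrib, minlength=array.n_channels)


def dipole_gain_matrix(
    position: np.ndarray,
    array: SensorArray,
    conductor_origin: np.ndarray | None = None,
) -> np.ndarray:
    """(N, 3) forward matrix: channel responses to unit dipoles along x,y,z."""
    origin = (
        np.zeros(3) if conductor_origin is None
        else np.asarray(conductor_origin, dtype=float)
    )
    pos = np.asarray(position, dtype=float) - origin
    pts, normals, weights, owner = array.stacked_integration()
    G = np.empty((array.n_channels, 3))
    for k in range(3):
        q = np.zeros(3)
        q[k] = 1.0
        B = sarvas_field(pos, q, pts - origin)
        contrib = weights * np.einsum("ij,ij->i", B, normals)
        G[:, k] = np.bincount(owner, weights=contrib, minlength=array.n_channels)
    return G


def one_cycle_waveform(
    sfreq: float, f0: float = 10.0, silence_s: float = 0.1
) -> np.ndarray:
    """One sinusoid cycle followed by silence: the per-trial source time course."""
    n_active = int(round(sfreq / f0))
    n_silent = int(round(silence_s * sfreq))
    t = np.arange(n_active) / sfreq
    return np.concatenate([np.sin(2.0 * np.pi * f0 * t), np.zeros(n_silent)])


def simulate_dipole_trials(
    dipole: DipoleSource,
    array: SensorArray,
    n_trials: int = 100,
    sfreq: float = 1000.0,
    conductor_origin: np.ndarray | None = None,
) -> Recording:
    """Trial series: one 10-Hz cycle (100 ms) then 100 ms of silence,
    repeated ``n_trials`` times (defaults give 20 s of data)."""
    pattern = dipole_forward_sphere(dipole, array, conductor_origin)
    wave = np.tile(one_cycle_waveform(sfreq), n_trials)
    return Recording(
        data=pattern[:, None] * wave[None, :],
        sfreq=sfreq,
        channel_names=array.channel_names,
        provenance={
            "generator": "dipole_trials",
            "n_trials": n_trials,
            "depth_m": float(np.linalg.norm(dipole.position)),
            "peak_amplitude_Am": dipole.peak_amplitude,
        },
    )


def interference_pattern(array: SensorArray, l: int, m: int) -> np.ndarray:
    """Native-unit channel pattern of one exterior multipole, scaled to a
    unit peak reading on the most strongly coupled magnetometer."""
    pts, normals, weights, owner = array.stacked_integration()
    B = multipole_field(HarmonicIndex(l, m, "out"), pts - array.expansion_origin)
    contrib = weights * np.einsum("ij,ij->i", B, normals)
    pat = np.bincount(owner, weights=contrib, minlength=array.n_channels)
    peak = np.abs(pat[array.mag_mask]).max()
    if peak == 0:
        raise ValueError("interference pattern does not couple to magnetometers")
    return pat / peak


def simulate_interference(
    array: SensorArray,
    specs: list[InterferenceSpec],
    duration: float = 20.0,
    sfreq: float = 1000.0,
    seed: int = 0,
) -> Recording:
    """Sum of sinusoidal external multipole components with seeded phases."""
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    rng = np.random.default_rng(seed)
    data = np.zeros((array.n_channels, n))
    for spec in specs:
        if spec.frequency >= sfreq / 2.0:
            raise ValueError(
                f"component at {spec.frequency} Hz exceeds Nyquist ({sfreq / 2} Hz)"
            )
        pat = interference_pattern(array, spec.l, spec.m) * spec.amplitude
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data += pat[:, None] * np.sin(2.0 * np.pi * spec.frequency * t + phase)[None, :]
    return Recording(
        data=data,
        sfreq=sfreq,
        channel_names=array.channel_names,
        provenance={
            "generator": "interference",
            "components": [
                {"l": s.l, "m": s.m, "f_hz": s.frequency, "amp_T": s.amplitude}
                for s in specs
            ],
            "seed": seed,
        },
    )


def add_sensor_noise(
    recording: Recording,
    mag_level: float = DEFAULT_MAG_NOISE,
    grad_level: float = DEFAULT_GRAD_NOISE,
    correlated_fraction: float = 0.1,
    seed: int = 0,
    array: SensorArray | None = None,
) -> Recording:
    """Add white sensor noise plus a rank-5 spatially correlated component.

    Per-channel noise SD is ``level * sqrt(sfreq / 2)`` (white noise over
    the full Nyquist band); ``correlated_fraction`` of the total noise
    power is moved into 5 random fixed spatial patterns with independent
    white time courses.
    """
    if not (0.0 <= correlated_fraction < 1.0):
        raise ValueError("correlated_fraction must be in [0, 1)")
    if mag_level == 0 and grad_level == 0:
        return recording.copy()
    rng = np.random.default_rng(seed)
    mag = (
        array.mag_mask if array is not None
        else np.array([n.startswith("MAG") for n in recording.channel_names])
    )
    sd = np.where(mag, mag_level, grad_level) * np.sqrt(recording.sfreq / 2.0)
    N, T = recording.data.shape
    noise = rng.standard_normal((N, T)) * (sd * np.sqrt(1.0 - correlated_fraction))[:, None]
    if correlated_fraction > 0:
        # 5 fixed random patterns shaped by the per-channel noise SD so the
        # correlated part respects channel units; white unit time courses.
        # E[sum_k shaped_jk^2] = 5 sd_j^2, so sqrt(f/5) yields per-channel
        # correlated variance f * sd_j^2 in expectation.
        shaped = rng.standard_normal((N, 5)) * sd[:, None]
        courses = rng.standard_normal((5, T))
        noise += np.sqrt(correlated_fraction / 5.0) * (shaped @ courses)
    return recording.with_data(
        recording.data + noise,
        note={
            "generator": "sensor_noise",
            "mag_level": mag_level,
            "grad_level": grad_level,
            "correlated_fraction": correlated_fraction,
            "seed": seed,
        },
    )


def simulate_empty_room(
    array: SensorArray,
    duration: float = 60.0,
    sfreq: float = 1000.0,
    seed: int = 0,
    specs: list[InterferenceSpec] | None = None,
) -> Recording:
    """Empty-room fixture: the interference preset plus sensor noise."""
    specs = empty_room_specs() if specs is None else specs
    rec = simulate_interference(array, specs, duration=duration, sfreq=sfreq, seed=seed)
    rec = add_sensor_noise(rec, seed=seed + 1, array=array)
    rec.provenance["generator"] = "empty_room"
    return rec


def random_tangential_dipole(
    radius: float,
    rng: np.random.Generator,
    peak_amplitude: float = 1e-6,
) -> DipoleSource:
    """Random upper-hemisphere dipole at the given radius, tangential."""
    while True:
        v = rng.standard_normal(3)
        if v[2] < 0:
            v[2] = -v[2]
        n = np.linalg.norm(v)
        if n > 1e-6 and v[2] / n > 0.05:  # stay clearly in the upper hemisphere
            break
    pos = radius * v / n
    t = np.cross(pos, rng.standard_normal(3))
    t /= np.linalg.norm(t)
    return DipoleSource(position=pos, orientation=t, peak_amplitude=peak_amplitude)
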