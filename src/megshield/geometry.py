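"""Sensor-array geometry and calibration.

A :class:`SensorArray` describes a multichannel MEG helmet: for every
channel the pick-up coil is discretized into integration points ``r_i``
with weights ``w_i`` so that the channel output for a field ``B`` is

    phi_j = gain_j * sum_i w_ij * B(r_ij) . n_j

For magnetometers the weights sum to 1 (area-averaged normal field,
units tesla); for planar gradiometers they sum to 0 and carry 1/length
units so the output is a finite-difference field gradient in T/m.

The channel ordering of the array is the single source of truth for the
row order of every matrix (bases, recordings, projectors) in this
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SensorChannel",
    "SensorArray",
    "build_synthetic_helmet",
    "perturb_calibration",
    "save_array",
    "load_array",
    "ArrayFormatError",
    "MAGNETOMETER",
    "PLANAR_GRADIOMETER",
]

MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

#: Distance between the two loops of a generated planar gradiometer (m).
DEFAULT_BASELINE = 0.0168
#: Side of the square magnetometer pick-up coil (m).
MAG_COIL_SIDE = 0.021
#: Side of each square gradiometer loop (m).
GRAD_LOOP_SIDE = 0.010


class ArrayFormatError(ValueError):
    """Raised when a serialized array file is malformed."""


@dataclass(frozen=True)
class SensorChannel:
    """One pick-up coil: geometry, discretization and calibration."""

    name: str
    kind: str  # MAGNETOMETER or PLANAR_GRADIOMETER
    position: np.ndarray  # (3,) m, device coordinates
    orientation: np.ndarray  # (3,) unit coil normal
    integration_points: np.ndarray  # (n, 3) m
    weights: np.ndarray  # (n,) 1 for mags, 1/m for gradiometers
    gain: float = 1.0
    baseline_dir: np.ndarray | None = None  # (3,) unit, gradiometers only

    def __post_init__(self) -> None:
        for attr in ("position", "orientation", "integration_points", "weights"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if self.baseline_dir is not None:
            object.__setattr__(self, "baseline_dir", np.asarray(self.baseline_dir, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.kind not in (MAGNETOMETER, PLANAR_GRADIOMETER):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-12:
            raise ValueError(f"channel {self.name}: orientation is not a unit vector")
        if self.integration_points.ndim != 2 or self.integration_points.shape[1] != 3:
            raise ValueError(f"channel {self.name}: integration_points must be (n, 3)")
        if len(self.weights) != len(self.integration_points) or len(self.weights) < 1:
            raise ValueError(f"channel {self.name}: need >=1 integration point with weights")
        wsum = float(np.sum(self.weights))
        if self.kind == MAGNETOMETER and abs(wsum - 1.0) > 1e-12:
            raise ValueError(f"channel {self.name}: magnetometer weights must sum to 1")
        if self.kind == PLANAR_GRADIOMETER:
            # balanced up to a possible injected loop imbalance (<= 10%)
            if abs(wsum) > 0.1 * np.sum(np.abs(self.weights)):
                raise ValueError(f"channel {self.name}: gradiometer weights must sum to ~0")
            if self.baseline_dir is None:
                raise ValueError(f"channel {self.name}: gradiometer needs baseline_dir")


@dataclass(frozen=True)
class SensorArray:
    """Ordered collection of channels plus the harmonic expansion origin."""

    channels: tuple[SensorChannel, ...]
    expansion_origin: np.ndarray  # (3,) m
    inner_radius: float  # m; sources must stay inside, coils outside

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(
            self, "expansion_origin", np.asarray(self.expansion_origin, dtype=float)
        )
        names = [ch.name for ch in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names are not unique")
        for ch in self.channels:
            d = np.linalg.norm(ch.integration_points - self.expansion_origin, axis=1)
            if np.any(d <= self.inner_radius):
                raise ValueError(
                    f"channel {ch.name}: integration point inside inner_radius"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    @property
    def kinds(self) -> np.ndarray:
        return np.array([ch.kind for ch in self.channels])

    @property
    def mag_mask(self) -> np.ndarray:
        return self.kinds == MAGNETOMETER

    def stacked_integration(self):
        """Flattened integration geometry for vectorized field evaluation.

        Returns ``(points (P,3), normals (P,3), weights (P,), owner (P,))``
        where ``weights`` already include the channel gain and ``owner``
        maps each point to its channel row.
        """
        pts, nrm, wts, own = [], [], [], []
        for j, ch in enumerate(self.channels):
            n = len(ch.weights)
            pts.append(ch.integration_points)
            nrm.append(np.tile(ch.orientation, (n, 1)))
            wts.append(ch.weights * ch.gain)
            own.append(np.full(n, j))
        return (
            np.concatenate(pts),
            np.concatenate(nrm),
            np.concatenate(wts),
            np.concatenate(own),
        )


def _square_offsets(e1: np.ndarray, e2: np.ndarray, side: float) -> np.ndarray:
    """Corner offsets of a square of given side in the (e1, e2) plane."""
    h = side / 2.0
    return np.array(
        [h * e1 + h * e2, h * e1 - h * e2, -h * e1 + h * e2, -h * e1 - h * e2]
    )


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangential directions for a unit normal."""
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(z, normal)
    if np.linalg.norm(e1) < 1e-8:  # normal along z: pick x
        e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def build_synthetic_helmet(
    n_sites: int = 102,
    helmet_radius: float = 0.12,
    origin: np.ndarray | None = None,
    baseline: float = DEFAULT_BASELINE,
    inner_radius_fraction: float = 0.8,
) -> SensorArray:
    """Deterministic helmet-like array: one magnetometer plus two orthogonal
    planar gradiometers at each of ``n_sites`` quasi-uniform sites.

    Sites follow a golden-angle (Fibonacci) lattice restricted to the
    spherical cap ``z > -0.1 * helmet_radius``; the default 102 sites give
    a 306-channel array. Gradiometers use two square loops separated by
    ``baseline`` with weights ``+-1/(4*baseline)``, producing T/m outputs.
    """
    if n_sites < 30:
        raise ValueError("n_sites must be >= 30")
    # the default L_in=8, L_out=3 basis has 95 columns; demand oversampling
    min_sites = 32
    if 3 * n_sites <= 95:
        raise ValueError(
            f"n_sites={n_sites} yields {3 * n_sites} channels, too few to span "
            f"the default 95-dimensional basis; need n_sites >= {min_sites}"
        )
    if helmet_radius <= 0:
        raise ValueError("helmet_radius must be positive")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    z_lo, z_hi = -0.1, 1.0  # cap in units of helmet_radius
    golden = np.pi * (3.0 - np.sqrt(5.0))
    channels: list[SensorChannel] = []
    for i in range(n_sites):
        z = z_hi - (i + 0.5) * (z_hi - z_lo) / n_sites
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        phi = i * golden
        normal = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
        pos = origin + helmet_radius * normal
        e1, e2 = _tangent_frame(normal)

        mag_pts = pos + _square_offsets(e1, e2, MAG_COIL_SIDE)
        channels.append(
            SensorChannel(
                name=f"MAG-{i:03d}",
                kind=MAGNETOMETER,
                position=pos,
                orientation=normal,
                integration_points=mag_pts,
                weights=np.full(4, 0.25),
            )
        )
        for axis, bdir in (("A", e1), ("B", e2)):
            loop_w = 1.0 / (4.0 * baseline)
            pts = np.concatenate(
                [
                    pos + (baseline / 2.0) * bdir + _square_offsets(e1, e2, GRAD_LOOP_SIDE),
                    pos - (baseline / 2.0) * bdir + _square_offsets(e1, e2, GRAD_LOOP_SIDE),
                ]
            )
            wts = np.concatenate([np.full(4, loop_w), np.full(4, -loop_w)])
            channels.append(
                SensorChannel(
                    name=f"GRAD-{i:03d}{axis}",
                    kind=PLANAR_GRADIOMETER,
                    position=pos,
                    orientation=normal,
                    integration_points=pts,
                    weights=wts,
                    baseline_dir=bdir,
                )
            )
    return SensorArray(
        channels=tuple(channels),
        expansion_origin=origin,
        inner_radius=inner_radius_fraction * helmet_radius,
    )


def _small_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (unit) by ``angle`` (rad), Rodrigues."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb_calibration(
    array: SensorArray,
    gain_sd: float,
    orient_sd: float = 0.0,
    seed: int = 0,
    loop_sd: float | None = None,
) -> SensorArray:
    """Copy of ``array`` with random calibration errors.

    Gains are multiplied by ``1 + eps`` with ``eps ~ N(0, gain_sd^2)``
    i.i.d. per channel.  Planar-gradiometer pick-up loops additionally get
    independent per-loop gain factors at sd ``loop_sd`` (default: equal to
    ``gain_sd``), modeling the loop-area imbalance that lets gradiometers
    pick up a fraction of the homogeneous field — the dominant way
    calibration uncertainty limits SSS shielding.  With ``orient_sd > 0``
    each channel is additionally rotated rigidly about its position by an
    angle ``|N(0, orient_sd^2)|`` around a random axis.  Reproducible via
    ``seed``; the input is untouched.
    """
    if gain_sd < 0 or orient_sd < 0:
        raise ValueError("gain_sd and orient_sd must be >= 0")
    loop_sd = gain_sd if loop_sd is None else loop_sd
    rng = np.random.default_rng(seed)
    new_channels = []
    for ch in array.channels:
        gain = ch.gain * (1.0 + (rng.normal(0.0, gain_sd) if gain_sd > 0 else 0.0))
        weights = ch.weights
        if ch.kind == PLANAR_GRADIOMETER and loop_sd > 0:
            weights = weights.copy()
            pos_loop = weights > 0
            weights[pos_loop] *= 1.0 + rng.normal(0.0, loop_sd)
            weights[~pos_loop] *= 1.0 + rng.normal(0.0, loop_sd)
            ch = replace(ch, weights=weights)
        if orient_sd > 0:
            angle = abs(rng.normal(0.0, orient_sd))
            axis = rng.normal(size=3)
            R = _small_rotation(axis, angle)
            orientation = R @ ch.orientation
            pts = ch.position + (ch.integration_points - ch.position) @ R.T
            bdir = None if ch.baseline_dir is None else R @ ch.baseline_dir
            new_channels.append(
                replace(
                    ch,
                    gain=gain,
                    orientation=orientation,
                    integration_points=pts,
                    baseline_dir=bdir,
                )
            )
        else:
            new_channels.append(replace(ch, gain=gain))
    return SensorArray(
        channels=tuple(new_channels),
        expansion_origin=array.expansion_origin.copy(),
        inner_radius=array.inner_radius,
    )


# ---------------------------------------------------------------------------
# JSON serialization (schema version 1, SI units stated in the file)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_array(array: SensorArray, path: str | Path) -> None:
    """Write the array to a versioned JSON file (lossless, SI units)."""
    doc = {
        "version": _SCHEMA_VERSION,
        "units": {"position": "m", "magnetometer": "T", "gradiometer": "T/m"},
        "origin_m": array.expansion_origin.tolist(),
        "inner_radius_m": array.inner_radius,
        "channels": [
            {
                "name": ch.name,
                "kind": ch.kind,
                "position_m": ch.position.tolist(),
                "orientation": ch.orientation.tolist(),
                **(
                    {"baseline_dir": ch.baseline_dir.tolist()}
                    if ch.baseline_dir is not None
                    else {}
                ),
                "integration_points": [
                    {"r_m": p.tolist(), "w": float(w)}
                    for p, w in zip(ch.integration_points, ch.weights)
                ],
                "gain": ch.gain,
            }
            for ch in array.channels
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_array(path: str | Path) -> SensorArray:
    """Read an array written by :func:`save_array`, validating all invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ArrayFormatError(f"not valid JSON: {err}") from err
    if doc.get("version") != _SCHEMA_VERSION:
        raise ArrayFormatError(f"unsupported schema version {doc.get('version')!r}")
    channels = []
    for i, chdoc in enumerate(doc.get("channels", [])):
        try:
            pts = np.array([p["r_m"] for p in chdoc["integration_points"]])
            wts = np.array([p["w"] for p in chdoc["integration_points"]])
            channels.append(
                SensorChannel(
                    name=chdoc["name"],
                    kind=chdoc["kind"],
                    position=np.array(chdoc["position_m"]),
                    orientation=np.array(chdoc["orientation"]),
                    integration_points=pts,
                    weights=wts,
                    gain=float(chdoc["gain"]),
                    baseline_dir=(
                        np.array(chdoc["baseline_dir"])
                        if "baseline_dir" in chdoc
                        else None
                    ),
                )
            )
        except KeyError as err:
            raise ArrayFormatError(
                f"channel entry {i}: missing field {err.args[0]!r}"
            ) from err
        except ValueError as err:
            raise ArrayFormatError(f"channel entry {i}: {err}") from err
    try:
        return SensorArray(
            channels=tuple(channels),
            expansion_origin=np.array(doc["origin_m"]),
            inner_radius=float(doc["inner_radius_m"]),
        )
    except KeyError as err:
        raise ArrayFormatError(f"missing field {err.args[0]!r}") from err
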