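"""Signal-space projection: PCA interference subspace and projector.

The interference subspace ``U`` is estimated from an empty-room
recording by PCA (SVD of the demeaned data).  Data are then projected
onto the orthogonal complement with ``P = I - U U^T``.  Two estimation
modes mirror common practice with mixed magnetometer / planar
gradiometer arrays:

``per_type``
    the top-k directions per channel type, estimated separately and
    stacked with zero padding (classic SSP; default k = 5 per type);
``joint``
    one SVD of all channels after multiplying magnetometer rows by
    ``mag_scale`` (default 100) so both types carry commensurate
    numerical range (the input used by eSSS; default k = 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MAGNETOMETER, SensorArray
from .recording import Recording

__all__ = [
    "InterferenceSubspace",
    "Projector",
    "estimate_interference_subspace",
    "make_projector",
    "apply_projector",
    "project_forward",
]


def _mag_mask_from_names(names) -> np.ndarray:
    """Channel-kind inference for recordings generated by this package."""
    return np.array([n.startswith("MAG") for n in names])


@dataclass
class InterferenceSubspace:
    """Orthonormal PC patterns spanning the measured interference."""

    U: np.ndarray  # (N, k), orthonormal columns (in scaled units)
    singular_values: np.ndarray  # (k,)
    scaling: np.ndarray  # (N,) channel scale applied before the SVD
    channel_names: list[str]
    source_meta: dict

    @property
    def k(self) -> int:
        return self.U.shape[1]


@dataclass
class Projector:
    """Orthogonal projector ``I - U U^T`` in the subspace's scaled units."""

    U: np.ndarray  # (N, k)
    scaling: np.ndarray  # (N,)
    channel_names: list[str]

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def P(self) -> np.ndarray:
        n = self.U.shape[0]
        return np.eye(n) - self.U @ self.U.T


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|.| element of each column made positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def estimate_interference_subspace(
    empty_room: Recording,
    k: int = 5,
    mode: str = "per_type",
    mag_scale: float = 100.0,
    array: SensorArray | None = None,
) -> InterferenceSubspace:
    """Top-k interference field patterns from an empty-room recording.

    The per-channel temporal mean is removed, rows are scaled (joint mode
    only), and the left singular vectors of the demeaned matrix are the
    PC patterns.  In ``per_type`` mode, k components are estimated for
    magnetometers and k for gradiometers separately and stacked with
    zero padding (2k columns in total).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    N, T = empty_room.data.shape
    if k >= N:
        raise ValueError(f"k = {k} must be smaller than the channel count {N}")
    if T < k:
        raise ValueError("empty-room recording shorter than k samples")
    X = empty_room.data - empty_room.data.mean(axis=1, keepdims=True)
    if np.linalg.norm(X) == 0:
        raise ValueError("degenerate empty-room recording (constant data)")
    mag = (
        array.mag_mask if array is not None
        else _mag_mask_from_names(empty_room.channel_names)
    )

    if mode == "joint":
        scaling = np.where(mag, mag_scale, 1.0)
        Uf, sv, _ = np.linalg.svd(X * scaling[:, None], full_matrices=False)
        U, sv = Uf[:, :k], sv[:k]
    elif mode == "per_type":
        scaling = np.ones(N)
        cols, svs = [], []
        for mask in (mag, ~mag):
            Ut, st, _ = np.linalg.svd(X[mask], full_matrices=False)
            block = np.zeros((N, k))
            block[mask] = Ut[:, :k]
            cols.append(block)
            svs.append(st[:k])
        U = np.concatenate(cols, axis=1)
        sv = np.concatenate(svs)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return InterferenceSubspace(
        U=_fix_signs(U),
        singular_values=sv,
        scaling=scaling,
        channel_names=list(empty_room.channel_names),
        source_meta={
            "mode": mode,
            "k": int(U.shape[1]),
            "mag_scale": float(mag_scale) if mode == "joint" else 1.0,
            "duration_s": empty_room.duration,
            "source": empty_room.provenance,
        },
    )


def make_projector(subspace: InterferenceSubspace) -> Projector:
    return Projector(
        U=subspace.U.copy(),
        scaling=subspace.scaling.copy(),
        channel_names=list(subspace.channel_names),
    )


def apply_projector(projector: Projector, recording: Recording) -> Recording:
    """Project every sample onto the complement of the interference span.

    The projection acts in the scaled channel units the subspace was
    estimated in; scaling is inverted afterwards so output stays in
    native sensor units.
    """
    if list(projector.channel_names) != list(recording.channel_names):
        raise ValueError("channel order mismatch between projector and recording")
    c = projector.scaling
    X = recording.data * c[:, None]
    X = X - projector.U @ (projector.U.T @ X)
    return recording.with_data(
        X / c[:, None], note={"method": "ssp", "k": projector.k}
    )


def project_forward(projector: Projector, leadfield: np.ndarray) -> np.ndarray:
    """Apply the projector to forward-model columns (N x n_sources).

    Source fitting on SSP-processed data must use this compensated
    forward model; otherwise the projection's suppression of signal
    components inside the interference span biases the fitted amplitude.
    """
    L = np.atleast_2d(np.asarray(leadfield, dtype=float))
    c = projector.scaling[:, None]
    Ls = L * c
    return (Ls - projector.U @ (projector.U.T @ Ls)) / c
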