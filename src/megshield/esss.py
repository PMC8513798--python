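"""Extended signal-space separation (eSSS).

eSSS augments the computational external SSS basis with empirically
measured interference patterns — the dominant principal components of an
unprocessed empty-room recording — and orthogonalizes the union:

    S_out_e = orth([S_out  PC_out])        (SVD orthogonalization)
    S_e     = [S_in  S_out_e]

Decomposition and internal reconstruction then proceed exactly as in
SSS.  Because the merged PCs carry the *measured* (hence miscalibrated)
interference patterns, the extended basis absorbs the part of the
interference that calibration errors push outside span(S_out), which is
what limits plain SSS.  An optional band-limited extension (eSSS')
additionally merges PCs of band-pass-filtered artifact data.

Orthogonalization happens in the basis's scaled channel units; PC
patterns estimated under a different scaling (e.g. the joint-PCA
mag_scale = 100) are rescaled before merging, which maps their span
exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .geometry import SensorArray
from .harmonics import SSSBasis, build_sss_basis
from .recording import Recording
from .sss import decompose, reconstruct_internal
from .ssp import InterferenceSubspace, estimate_interference_subspace

__all__ = [
    "ExtendedBasis",
    "extend_external_basis",
    "extend_with_band_components",
    "apply_esss",
    "condition_report",
]

logger = logging.getLogger(__name__)

DEFAULT_RANK_TOL = 1e-8


@dataclass(frozen=True)
class ExtendedBasis:
    """eSSS basis ``[S_in S_out_e]`` with orthonormal external block."""

    S_in: np.ndarray  # (N, D_in), scaled + normalized (from SSSBasis)
    S_out_e: np.ndarray  # (N, D_e), orthonormal columns in scaled units
    L_in: int
    origin: np.ndarray
    row_scale: np.ndarray
    channel_names: tuple[str, ...]
    provenance: dict

    @property
    def S(self) -> np.ndarray:
        return np.concatenate([self.S_in, self.S_out_e], axis=1)

    @property
    def D_in(self) -> int:
        return self.S_in.shape[1]

    @property
    def D_e(self) -> int:
        return self.S_out_e.shape[1]


def _subspace_in_basis_units(
    basis: SSSBasis, subspace: InterferenceSubspace
) -> np.ndarray:
    """Re-express PC patterns in the basis's scaled channel units."""
    if list(subspace.channel_names) != list(basis.channel_names):
        raise ValueError("channel order mismatch between basis and subspace")
    U = basis.row_scale[:, None] * (subspace.U / subspace.scaling[:, None])
    norms = np.linalg.norm(U, axis=0)
    return U / norms


def _orth(M: np.ndarray, rank_tol: float) -> tuple[np.ndarray, int]:
    """SVD orthonormalization keeping directions above the rank tolerance."""
    U, sv, _ = np.linalg.svd(M, full_matrices=False)
    keep = sv > rank_tol * sv[0]
    return U[:, keep], int(np.sum(~keep))


def extend_external_basis(
    basis: SSSBasis,
    subspace: InterferenceSubspace | None,
    rank_tol: float = DEFAULT_RANK_TOL,
) -> ExtendedBasis:
    """Merge empty-room PCs into the external basis (SVD orthogonalized).

    Directions of the concatenation ``[S_out U]`` whose singular value
    falls below ``rank_tol`` times the largest are dropped (with a
    warning), preventing a singular extended basis when measured and
    computational patterns nearly coincide.
    """
    blocks = [basis.S_out]
    prov: dict = {"rank_tol": rank_tol, "n_pcs": 0}
    if subspace is not None and subspace.k > 0:
        blocks.append(_subspace_in_basis_units(basis, subspace))
        prov["n_pcs"] = subspace.k
        prov["pc_source"] = subspace.source_meta
    S_out_e, n_dropped = _orth(np.concatenate(blocks, axis=1), rank_tol)
    if n_dropped:
        warnings.warn(
            f"orthogonalization dropped {n_dropped} nearly dependent "
            f"direction(s) from the extended external basis"
        )
    prov["n_dropped"] = n_dropped
    N = basis.S_in.shape[0]
    if basis.D_in + S_out_e.shape[1] >= N:
        raise ValueError(
            f"extended basis ({basis.D_in + S_out_e.shape[1]} vectors) exceeds "
            f"the oversampling margin of the {N}-channel array"
        )
    return ExtendedBasis(
        S_in=basis.S_in,
        S_out_e=S_out_e,
        L_in=basis.L_in,
        origin=basis.origin,
        row_scale=basis.row_scale,
        channel_names=basis.channel_names,
        provenance=prov,
    )


def extend_with_band_components(
    basis: SSSBasis,
    subspace: InterferenceSubspace | None,
    artifact_recording: Recording,
    band: tuple[float, float],
    n_components: int = 3,
    rank_tol: float = DEFAULT_RANK_TOL,
    filter_order: int = 4,
) -> ExtendedBasis:
    """eSSS' basis: also merge PCs of band-pass-filtered artifact data.

    The artifact recording is zero-phase band-pass filtered (forward-
    backward 4th-order Butterworth sections), its top ``n_components``
    joint PCs are extracted in the same scaled units as ``subspace``,
    and the union ``[S_out PC_out PC_out_f]`` is orthogonalized.
    """
    f_lo, f_hi = band
    nyq = artifact_recording.sfreq / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    if n_components == 0:
        return extend_external_basis(basis, subspace, rank_tol)

    sos = butter(filter_order, [f_lo, f_hi], btype="bandpass", fs=artifact_recording.sfreq, output="sos")
    filtered = sosfiltfilt(sos, artifact_recording.data, axis=1)
    band_rms = np.sqrt(np.mean(filtered**2))
    raw_rms = np.sqrt(np.mean(artifact_recording.data**2))
    if band_rms < 1e-6 * raw_rms:
        warnings.warn(f"band {band} Hz contains almost no energy; proceeding")
    band_rec = artifact_recording.with_data(filtered)
    scaling_meta = subspace.source_meta if subspace is not None else {}
    band_sub = estimate_interference_subspace(
        band_rec,
        k=n_components,
        mode="joint",
        mag_scale=float(scaling_meta.get("mag_scale", 100.0)),
    )

    blocks = [basis.S_out]
    prov: dict = {"rank_tol": rank_tol, "n_pcs": 0, "band": list(band),
                  "n_band_pcs": n_components}
    if subspace is not None and subspace.k > 0:
        blocks.append(_subspace_in_basis_units(basis, subspace))
        prov["n_pcs"] = subspace.k
    blocks.append(_subspace_in_basis_units(basis, band_sub))
    S_out_e, n_dropped = _orth(np.concatenate(blocks, axis=1), rank_tol)
    if n_dropped:
        warnings.warn(
            f"orthogonalization dropped {n_dropped} nearly dependent "
            f"direction(s) from the extended external basis"
        )
    prov["n_dropped"] = n_dropped
    N = basis.S_in.shape[0]
    if basis.D_in + S_out_e.shape[1] >= N:
        raise ValueError("extended basis exceeds the oversampling margin")
    return ExtendedBasis(
        S_in=basis.S_in,
        S_out_e=S_out_e,
        L_in=basis.L_in,
        origin=basis.origin,
        row_scale=basis.row_scale,
        channel_names=basis.channel_names,
        provenance=prov,
    )


def apply_esss(
    recording: Recording,
    array: SensorArray,
    empty_room: Recording,
    n_pcs: int = 8,
    L_in: int = 8,
    L_out: int = 3,
    mag_scale: float = 100.0,
    band: tuple[float, float] | None = None,
    band_pcs: int = 0,
    band_recording: Recording | None = None,
    basis: SSSBasis | None = None,
) -> Recording:
    """Full eSSS pipeline on one recording.

    Builds the SSS basis, estimates ``n_pcs`` joint PCs from the
    unprocessed empty-room data (magnetometers scaled by ``mag_scale``),
    merges and orthogonalizes, then decomposes the recording and keeps
    the interior reconstruction.  Pass ``band``/``band_pcs`` (and
    optionally a dedicated ``band_recording``) for the eSSS' variant.
    """
    if list(recording.channel_names) != list(empty_room.channel_names):
        raise ValueError(
            "recording and empty-room data have different channel ordering"
        )
    if basis is None:
        basis = build_sss_basis(array, L_in=L_in, L_out=L_out)
    subspace = (
        estimate_interference_subspace(
            empty_room, k=n_pcs, mode="joint", mag_scale=mag_scale, array=array
        )
        if n_pcs > 0
        else None
    )
    if band is not None and band_pcs > 0:
        ext = extend_with_band_components(
            basis, subspace,
            band_recording if band_recording is not None else empty_room,
            band=band, n_components=band_pcs,
        )
        method = "esss_prime"
    else:
        ext = extend_external_basis(basis, subspace)
        method = "esss"
    report = condition_report(ext)
    logger.info(
        "eSSS basis: %d vectors, condition number %.1f",
        report["n_vectors"], report["condition_number"],
    )
    moments = decompose(ext, recording)
    out = reconstruct_internal(ext, moments)
    return recording.with_data(
        out.data,
        note={"method": method, "n_pcs": n_pcs, "L_in": basis.L_in,
              "L_out": basis.L_out, **report},
    )


def condition_report(basis_or_extended) -> dict:
    """Size and conditioning of a (possibly extended) basis.

    The condition number is the ratio of the largest to the smallest
    singular value of the scaled full basis; a large jump versus the
    plain SSS basis signals nearly dependent added vectors that would
    amplify reconstruction noise.
    """
    S = basis_or_extended.S
    sv = np.linalg.svd(S, compute_uv=False)
    return {
        "n_vectors": int(S.shape[1]),
        "condition_number": float(sv[0] / sv[-1]),
    }
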