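"""SSS decomposition and internal reconstruction.

Given a basis ``S = [S_in S_out]`` the multipole moments of a signal
vector are the least-squares solution ``x = S^+ phi``; discarding the
external moments and mapping back, ``phi_in = S_in x_in``, removes
external interference.  The same code path serves the extended (eSSS)
basis, which exposes the identical ``S`` / ``D_in`` / ``row_scale``
surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray
from .harmonics import SSSBasis, build_sss_basis
from .recording import Recording

__all__ = ["MultipoleMoments", "decompose", "reconstruct_internal", "apply_sss"]

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff of the basis pseudoinverse.
PINV_RCOND = 1e-10


@dataclass
class MultipoleMoments:
    """Interior/exterior expansion coefficients, one column per sample."""

    x_in: np.ndarray  # (D_in, T)
    x_out: np.ndarray  # (D_out_or_De, T)
    sfreq: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.x_in = np.atleast_2d(np.asarray(self.x_in, dtype=float))
        self.x_out = np.atleast_2d(np.asarray(self.x_out, dtype=float))
        if not (np.all(np.isfinite(self.x_in)) and np.all(np.isfinite(self.x_out))):
            raise ValueError("non-finite multipole moments")


def _check_channels(basis, recording: Recording) -> None:
    if list(basis.channel_names) != list(recording.channel_names):
        for b, r in zip(basis.channel_names, recording.channel_names):
            if b != r:
                raise ValueError(
                    f"channel order mismatch between basis and recording: "
                    f"first differing name {b!r} vs {r!r}"
                )
        raise ValueError(
            "channel count mismatch between basis and recording: "
            f"{len(basis.channel_names)} vs {len(recording.channel_names)}"
        )


def decompose(basis, recording: Recording) -> MultipoleMoments:
    """Least-squares multipole moments of every sample of ``recording``.

    The pseudoinverse is computed by SVD with a relative cutoff of
    ``1e-10``; channel-type scaling is applied consistently with the
    basis construction.  Works for both :class:`~megshield.harmonics.SSSBasis`
    and :class:`~megshield.esss.ExtendedBasis`.
    """
    _check_channels(basis, recording)
    S = basis.S
    phi = recording.data * basis.row_scale[:, None]
    x = np.linalg.pinv(S, rcond=PINV_RCOND) @ phi
    return MultipoleMoments(
        x_in=x[: basis.D_in],
        x_out=x[basis.D_in:],
        sfreq=recording.sfreq,
        channel_names=list(recording.channel_names),
    )


def reconstruct_internal(basis, moments: MultipoleMoments) -> Recording:
    """Map the interior moments back to sensor units: ``phi_in = S_in x_in``.

    The exterior expansion is discarded (this is the interference
    suppression step); channel scaling is inverted so the output is in
    native sensor units.
    """
    if moments.x_in.shape[0] != basis.D_in:
        raise ValueError(
            f"moments have {moments.x_in.shape[0]} interior coefficients, "
            f"basis expects {basis.D_in}"
        )
    data = (basis.S[:, : basis.D_in] @ moments.x_in) / basis.row_scale[:, None]
    return Recording(
        data=data,
        sfreq=moments.sfreq,
        channel_names=list(moments.channel_names),
    )


def apply_sss(
    recording: Recording,
    array: SensorArray,
    L_in: int = 8,
    L_out: int = 3,
    basis: SSSBasis | None = None,
) -> Recording:
    """SSS-process a recording: decompose and keep the interior part.

    A prebuilt ``basis`` may be passed to amortize basis construction
    across recordings; it must match the array's channel ordering.
    """
    if basis is None:
        basis = build_sss_basis(array, L_in=L_in, L_out=L_out)
    sv = np.linalg.svd(basis.S, compute_uv=False)
    cond = sv[0] / sv[-1]
    logger.info(
        "SSS basis: %d vectors, condition number %.1f", basis.S.shape[1], cond
    )
    moments = decompose(basis, recording)
    out = reconstruct_internal(basis, moments)
    return recording.with_data(
        out.data,
        note={"method": "sss", "L_in": basis.L_in, "L_out": basis.L_out,
              "n_vectors": int(basis.S.shape[1]), "condition_number": float(cond)},
    )
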