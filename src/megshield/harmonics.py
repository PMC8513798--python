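"""Real spherical harmonics, multipole magnetic fields and the SSS basis.

The signal-space separation (SSS) model expands the measured field as a
sum of interior and exterior multipole terms.  Both families derive from
scalar potentials built on real, orthonormal spherical harmonics
``Y_lm`` (no Condon-Shortley phase):

    psi_in(l, m)  = Y_lm(theta, phi) / r**(l + 1)   (sources inside)
    psi_out(l, m) = r**l * Y_lm(theta, phi)         (sources outside)

with ``B = -grad(psi)`` up to a fixed constant (set to 1 here; absolute
multipole scaling is absorbed by column normalization and is irrelevant
to the spans and shielding factors this package computes).  The degree
``l = 0`` term vanishes for magnetic fields and is omitted, so a
truncation degree ``L`` yields ``L*(L+2)`` basis functions per domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln, lpmv

from .geometry import SensorArray

__all__ = [
    "HarmonicIndex",
    "SSSBasis",
    "real_spherical_harmonic",
    "multipole_field",
    "build_sss_basis",
    "harmonic_indices",
    "n_harmonics",
    "MAG_LENGTH_SCALE",
]

#: Length scale (m) dividing magnetometer rows before decomposition, so
#: magnetometer (T) and planar gradiometer (T/m) rows are commensurate.
#: Equals the generated gradiometer baseline.
MAG_LENGTH_SCALE = 0.0168

_SIN_FLOOR = 1e-12  # pole guard for 1/sin(theta) terms


class HarmonicIndex(NamedTuple):
    """Degree/order/domain label of one basis column."""

    l: int
    m: int
    domain: str  # "in" or "out"


def n_harmonics(L: int) -> int:
    """Number of (l, m) pairs with 1 <= l <= L: L*(L+2)."""
    return L * (L + 2)


def harmonic_indices(L: int, domain: str) -> list[HarmonicIndex]:
    return [
        HarmonicIndex(l, m, domain) for l in range(1, L + 1) for m in range(-l, l + 1)
    ]


def _norm_const(l: int, m: int) -> float:
    """sqrt((2l+1)/(4 pi) * (l-|m|)!/(l+|m|)!)."""
    m = abs(m)
    return np.sqrt(
        (2 * l + 1) / (4 * np.pi) * np.exp(gammaln(l - m + 1) - gammaln(l + m + 1))
    )


def _legendre_nocs(m: int, l: int, x: np.ndarray) -> np.ndarray:
    """Associated Legendre P_l^m without the Condon-Shortley phase."""
    if m > l:
        return np.zeros_like(np.asarray(x, dtype=float))
    return (-1.0) ** m * lpmv(m, l, x)


def real_spherical_harmonic(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic Y_lm(theta, phi).

    Convention: no Condon-Shortley phase; ``m > 0`` pairs with
    ``cos(m phi)``, ``m < 0`` with ``sin(|m| phi)``; orthonormal over the
    unit sphere.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    P = _legendre_nocs(am, l, np.cos(theta))
    N = _norm_const(l, am)
    if m == 0:
        return N * P * np.ones_like(phi)
    if m > 0:
        return np.sqrt(2.0) * N * P * np.cos(m * phi)
    return np.sqrt(2.0) * N * P * np.sin(am * phi)


def _dlegendre_dtheta(m: int, l: int, ct: np.ndarray, st: np.ndarray) -> np.ndarray:
    """d/dtheta of P_l^m(cos theta) (no CS phase), via the degree recurrence.

    Uses (1-x^2) dP/dx = (l+m) P_{l-1}^m - l x P_l^m; valid away from the
    poles, where ``st`` has been floored.
    """
    P_l = _legendre_nocs(m, l, ct)
    P_lm1 = _legendre_nocs(m, l - 1, ct) if l - 1 >= m else np.zeros_like(ct)
    return (l * ct * P_l - (l + m) * P_lm1) / st


def _angular_parts(l: int, m: int, theta: np.ndarray, phi: np.ndarray):
    """Return Y, dY/dtheta, (1/sin theta) dY/dphi for the real harmonic."""
    am = abs(m)
    ct = np.cos(theta)
    st = np.maximum(np.sin(theta), _SIN_FLOOR)
    P = _legendre_nocs(am, l, ct)
    dP = _dlegendre_dtheta(am, l, ct, st)
    N = _norm_const(l, am)
    if m == 0:
        trig, dtrig = np.ones_like(phi), np.zeros_like(phi)
        scale = N
    elif m > 0:
        trig, dtrig = np.cos(m * phi), -m * np.sin(m * phi)
        scale = np.sqrt(2.0) * N
    else:
        trig, dtrig = np.sin(am * phi), am * np.cos(am * phi)
        scale = np.sqrt(2.0) * N
    Y = scale * P * trig
    dY_dtheta = scale * dP * trig
    dY_dphi_over_sin = scale * P * dtrig / st
    return Y, dY_dtheta, dY_dphi_over_sin


def multipole_field(index: HarmonicIndex, points: np.ndarray) -> np.ndarray:
    """Magnetic field (up to a fixed constant) of one multipole term.

    ``points`` are Cartesian coordinates relative to the expansion origin,
    shape ``(3,)`` or ``(n, 3)``.  ``domain='in'`` evaluates the interior
    (r**-(l+2) decaying) field, valid outside the sources; ``domain='out'``
    the exterior (r**(l-1) growing) field, valid inside the helmet.
    """
    l, m, domain = index
    if l < 1:
        raise ValueError("degree l must be >= 1 (l = 0 vanishes)")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    if domain == "in" and np.any(r <= 0):
        raise ValueError("interior multipole field is singular at the origin")
    theta = np.arccos(np.clip(pts[:, 2] / np.maximum(r, 1e-300), -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    Y, dY_dt, dY_dp_os = _angular_parts(l, m, theta, phi)

    if domain == "out":
        # psi = r^l Y ; -grad(psi)
        B_r = -l * r ** (l - 1) * Y
        B_t = -(r ** (l - 1)) * dY_dt
        B_p = -(r ** (l - 1)) * dY_dp_os
    elif domain == "in":
        # psi = Y / r^(l+1)
        B_r = (l + 1) * r ** (-(l + 2)) * Y
        B_t = -(r ** (-(l + 2))) * dY_dt
        B_p = -(r ** (-(l + 2))) * dY_dp_os
    else:
        raise ValueError(f"unknown domain {domain!r}")

    st = np.sin(theta)
    ct = np.cos(theta)
    sp = np.sin(phi)
    cp = np.cos(phi)
    r_hat = np.stack([st * cp, st * sp, ct], axis=1)
    t_hat = np.stack([ct * cp, ct * sp, -st], axis=1)
    p_hat = np.stack([-sp, cp, np.zeros_like(sp)], axis=1)
    B = B_r[:, None] * r_hat + B_t[:, None] * t_hat + B_p[:, None] * p_hat
    return B[0] if np.asarray(points).ndim == 1 else B


@dataclass(frozen=True)
class SSSBasis:
    """SSS basis matrices coupled to a sensor array.

    ``S_in``/``S_out`` hold unit-norm columns in *scaled* channel units
    (magnetometer rows divided by :data:`MAG_LENGTH_SCALE`); the applied
    row scales and column norms are retained so reconstructions can be
    mapped back to native sensor units.
    """

    S_in: np.ndarray  # (N, D_in), scaled + column-normalized
    S_out: np.ndarray  # (N, D_out)
    L_in: int
    L_out: int
    origin: np.ndarray  # (3,)
    row_scale: np.ndarray  # (N,), multiply native data by this before decomposing
    column_norms: np.ndarray  # (D_in + D_out,) norms divided out
    index_map: tuple[HarmonicIndex, ...]  # column -> harmonic
    channel_names: tuple[str, ...]

    @property
    def S(self) -> np.ndarray:
        return np.concatenate([self.S_in, self.S_out], axis=1)

    @property
    def D_in(self) -> int:
        return self.S_in.shape[1]

    @property
    def D_out(self) -> int:
        return self.S_out.shape[1]

    @property
    def n_channels(self) -> int:
        return self.S_in.shape[0]


def channel_row_scale(array: SensorArray, mag_length_scale: float = MAG_LENGTH_SCALE):
    """Per-row scale making magnetometer and gradiometer rows commensurate."""
    scale = np.ones(array.n_channels)
    scale[array.mag_mask] = 1.0 / mag_length_scale
    return scale


def _couple_to_array(array: SensorArray, indices) -> np.ndarray:
    """Raw (native-unit) basis matrix: channel responses to each multipole."""
    pts, normals, weights, owner = array.stacked_integration()
    rel = pts - array.expansion_origin
    N = array.n_channels
    S = np.empty((N, len(indices)))
    for c, idx in enumerate(indices):
        B = multipole_field(idx, rel)
        contrib = weights * np.einsum("ij,ij->i", B, normals)
        S[:, c] = np.bincount(owner, weights=contrib, minlength=N)
    return S


def build_sss_basis(
    array: SensorArray,
    L_in: int = 8,
    L_out: int = 3,
    mag_length_scale: float = MAG_LENGTH_SCALE,
    rank_rtol: float = 1e-8,
) -> SSSBasis:
    """Assemble the SSS basis ``[S_in S_out]`` for an array.

    Element ``(j, c)`` is the output of channel ``j`` (through its
    integration points and gain) for multipole ``c``.  Magnetometer rows
    are then divided by ``mag_length_scale`` and every column normalized
    to unit Euclidean norm (norms retained).
    """
    D_in, D_out = n_harmonics(L_in), n_harmonics(L_out)
    N = array.n_channels
    if D_in + D_out >= N:
        raise ValueError(
            f"basis dimension {D_in + D_out} must be < channel count {N}"
        )
    idx = tuple(harmonic_indices(L_in, "in") + harmonic_indices(L_out, "out"))
    S = _couple_to_array(array, idx)
    scale = channel_row_scale(array, mag_length_scale)
    S = S * scale[:, None]
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        raise ValueError("basis has an identically zero column")
    S = S / norms

    sv = np.linalg.svd(S, compute_uv=False)
    rank = int(np.sum(sv > rank_rtol * sv[0]))
    if rank < D_in + D_out:
        raise ValueError(
            f"[S_in S_out] is rank deficient: numerical rank {rank} < "
            f"{D_in + D_out} columns (sigma_min/sigma_max = {sv[-1] / sv[0]:.2e})"
        )
    return SSSBasis(
        S_in=S[:, :D_in],
        S_out=S[:, D_in:],
        L_in=L_in,
        L_out=L_out,
        origin=array.expansion_origin.copy(),
        row_scale=scale,
        column_norms=norms,
        index_map=idx,
        channel_names=tuple(array.channel_names),
    )
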