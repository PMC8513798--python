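"""Shielding factors, spectra, whitened dipole fitting and error summaries.

The shielding factor (SF) quantifies interference suppression as the
ratio of raw to processed signal amplitude, either as the ratio of
time-averaged magnetometer signal-vector norms over the 2-s window with
the largest raw swing (norm-based SF), or as the ratio of FFT amplitude
peaks at a known interference frequency (frequency-resolved SF, immune
to internal signals at other frequencies).

Dipole fitting follows the classic least-squares approach: the dipole
moment is solved linearly in whitened channel space at each candidate
position, and the position is refined by a derivative-free simplex
search seeded from the best point of a coarse grid inside the conductor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import welch

from .geometry import SensorArray
from .recording import Recording
from .simulate import DipoleSource, dipole_gain_matrix
from .ssp import Projector, project_forward

__all__ = [
    "FitResult",
    "ErrorSummary",
    "NoiseCovariance",
    "shielding_factor_norm",
    "shielding_factor_fft",
    "welch_spectrum",
    "estimate_noise_covariance",
    "fit_dipole",
    "source_errors",
]


def _subset_mask(recording: Recording, channels) -> np.ndarray:
    if channels == "magnetometers":
        return np.array([n.startswith("MAG") for n in recording.channel_names])
    if channels == "gradiometers":
        return np.array([not n.startswith("MAG") for n in recording.channel_names])
    if channels == "all":
        return np.ones(recording.n_channels, dtype=bool)
    mask = np.asarray(channels)
    if mask.dtype == bool:
        return mask
    raise ValueError(f"unknown channel subset {channels!r}")


def shielding_factor_norm(
    raw: Recording,
    processed: Recording,
    window_s: float = 2.0,
    channels="magnetometers",
) -> float:
    """Norm-based shielding factor over the largest-swing window.

    Locates the ``window_s`` stretch maximizing the summed raw
    signal-vector norm, then returns the ratio of the time-averaged raw
    and processed norms over that window.  A numerically zero processed
    norm yields ``inf`` (flagged suppression floor), not an exception.
    """
    if raw.data.shape != processed.data.shape:
        raise ValueError("raw and processed recordings have different shapes")
    mask = _subset_mask(raw, channels)
    w = int(round(window_s * raw.sfreq))
    w = min(max(w, 1), raw.n_samples)
    nr = np.linalg.norm(raw.data[mask], axis=0)
    npr = np.linalg.norm(processed.data[mask], axis=0)
    csum = np.concatenate([[0.0], np.cumsum(nr)])
    windows = csum[w:] - csum[:-w]
    start = int(np.argmax(windows))
    raw_mean = nr[start:start + w].mean()
    proc_mean = npr[start:start + w].mean()
    if proc_mean <= 1e-30 * raw_mean:
        return float("inf")
    return float(raw_mean / proc_mean)


def _fft_peak_amplitudes(data: np.ndarray, sfreq: float, freq: float) -> np.ndarray:
    """Per-channel FFT amplitude at ``freq`` (max over +-1 bin)."""
    T = data.shape[1]
    spec = np.abs(np.fft.rfft(data, axis=1)) * 2.0 / T
    freqs = np.fft.rfftfreq(T, 1.0 / sfreq)
    b = int(np.argmin(np.abs(freqs - freq)))
    lo, hi = max(b - 1, 0), min(b + 2, spec.shape[1])
    return spec[:, lo:hi].max(axis=1)


def shielding_factor_fft(
    raw: Recording,
    processed: Recording,
    freq: float,
    channels="magnetometers",
) -> float:
    """Frequency-resolved shielding factor at one interference tone.

    Per-channel FFT amplitudes (peak within +-1 bin of ``freq``) are
    combined across the channel subset by Euclidean norm and the
    raw/processed ratio returned.
    """
    if raw.data.shape != processed.data.shape:
        raise ValueError("raw and processed recordings have different shapes")
    mask = _subset_mask(raw, channels)
    a_raw = np.linalg.norm(_fft_peak_amplitudes(raw.data[mask], raw.sfreq, freq))
    a_proc = np.linalg.norm(
        _fft_peak_amplitudes(processed.data[mask], processed.sfreq, freq)
    )
    if a_proc <= 1e-30 * a_raw:
        return float("inf")
    return float(a_raw / a_proc)


def welch_spectrum(
    recording: Recording, nperseg: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel amplitude spectral density, Welch / Hann / 50% overlap.

    Returns ``(freqs, asd)`` with ``asd`` in native channel units per
    sqrt(Hz) (T/sqrt(Hz) for magnetometers).
    """
    nperseg = min(nperseg, recording.n_samples)
    freqs, psd = welch(
        recording.data,
        fs=recording.sfreq,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=1,
    )
    return freqs, np.sqrt(psd)


@dataclass
class NoiseCovariance:
    cov: np.ndarray  # (N, N), after diagonal loading
    whitener: np.ndarray  # (N, N), rank-restricted inverse square root
    loading: float
    rank: int

    @property
    def n_channels(self) -> int:
        return self.cov.shape[0]


def estimate_noise_covariance(
    recording: Recording,
    baseline_segments: list[tuple[int, int]] | None = None,
    loading: float = 1e-3,
    rank_rtol: float = 1e-10,
) -> NoiseCovariance:
    """Sample covariance over concatenated baseline periods, regularized.

    ``baseline_segments`` are (start, stop) sample index pairs; ``None``
    uses the whole recording.  Diagonal loading (relative to the mean
    diagonal) guarantees positive definiteness.  The whitener is *rank
    restricted*: subspace-projected data (SSS/eSSS reconstructions, SSP
    output) have rank-deficient noise covariance, and directions with
    eigenvalues below ``rank_rtol`` times the largest carry no data —
    they receive zero whitener weight instead of a huge ``1/sqrt(lam)``
    amplification that would blow up forward-model components outside
    the processed subspace.
    """
    if baseline_segments is None:
        X = recording.data
    else:
        X = np.concatenate(
            [recording.data[:, a:b] for a, b in baseline_segments], axis=1
        )
    X = X - X.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / max(X.shape[1] - 1, 1)
    lam = loading * np.mean(np.diag(cov))
    if lam <= 0:  # degenerate all-zero baseline
        lam = loading
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > rank_rtol * max(evals.max(), 0.0)
    if not np.any(keep):
        keep = evals == evals.max()
    Vr = evecs[:, keep]
    whitener = (Vr / np.sqrt(evals[keep] + lam)) @ Vr.T
    return NoiseCovariance(
        cov=cov + lam * np.eye(cov.shape[0]),
        whitener=whitener,
        loading=loading,
        rank=int(np.sum(keep)),
    )


@dataclass
class FitResult:
    position: np.ndarray  # (3,) m
    moment: np.ndarray  # (3,) A*m
    goodness_of_fit: float
    latency: float | None = None
    converged: bool = True

    @property
    def amplitude(self) -> float:
        return float(np.linalg.norm(self.moment))


def _default_grid(max_radius: float) -> np.ndarray:
    """27-point coarse grid of seed positions in the upper source region."""
    g = max_radius * np.array([-0.45, 0.0, 0.45])
    z = max_radius * np.array([0.15, 0.45, 0.75])
    pts = np.array([[x, y, zz] for x in g for y in g for zz in z])
    keep = np.linalg.norm(pts, axis=1) < 0.95 * max_radius
    return pts[keep]


def fit_dipole(
    evoked: np.ndarray,
    array: SensorArray,
    conductor_origin: np.ndarray | None = None,
    noise_cov: NoiseCovariance | None = None,
    projector: Projector | None = None,
    grid: np.ndarray | None = None,
    latency: float | None = None,
) -> FitResult:
    """Single-dipole least-squares fit to one evoked field vector.

    The moment is solved linearly in whitened space at each candidate
    position; the position is refined with Nelder-Mead from the best
    seed of a coarse grid (positions constrained inside the conductor).
    With ``projector`` given (SSP-processed data), both the data and the
    forward model are projected, compensating the projection's signal
    distortion.
    """
    evoked = np.asarray(evoked, dtype=float).ravel()
    origin = (
        np.zeros(3) if conductor_origin is None
        else np.asarray(conductor_origin, dtype=float)
    )
    W = noise_cov.whitener if noise_cov is not None else np.eye(evoked.size)
    if projector is not None:
        evoked = (projector.scaling**-1) * (
            (np.eye(evoked.size) - projector.U @ projector.U.T)
            @ (projector.scaling * evoked)
        )
    y = W @ evoked
    yn2 = float(y @ y)
    max_r = array.inner_radius

    def whitened_forward(pos_rel: np.ndarray) -> np.ndarray:
        G = dipole_gain_matrix(origin + pos_rel, array, origin)
        if projector is not None:
            G = project_forward(projector, G)
        return W @ G

    def cost(pos_rel: np.ndarray) -> float:
        r = np.linalg.norm(pos_rel)
        if r >= 0.98 * max_r:
            return yn2 * (1.0 + 10.0 * (r / max_r))  # push back inside
        Gw = whitened_forward(pos_rel)
        q, *_ = np.linalg.lstsq(Gw, y, rcond=None)
        resid = y - Gw @ q
        return float(resid @ resid)

    grid = _default_grid(max_r) if grid is None else np.asarray(grid, dtype=float)
    best = min(grid, key=cost)
    res = minimize(
        cost,
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": yn2 * 1e-12, "maxiter": 600},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn("dipole fit did not converge; returning best candidate")
    pos_rel = res.x
    Gw = whitened_forward(pos_rel)
    q, *_ = np.linalg.lstsq(Gw, y, rcond=None)
    rss = float(np.sum((y - Gw @ q) ** 2))
    gof = 1.0 - rss / yn2 if yn2 > 0 else 0.0
    return FitResult(
        position=origin + pos_rel,
        moment=q,
        goodness_of_fit=gof,
        latency=latency,
        converged=converged,
    )


@dataclass
class ErrorSummary:
    """Localization / amplitude errors of a batch of dipole fits."""

    localization_error: float  # m, mean Euclidean distance
    amplitude_error: float  # dimensionless fraction
    n: int
    per_depth: dict = dataclass_field(default_factory=dict)  # radius_m -> dict


def source_errors(
    fits: list[FitResult], truths: list[DipoleSource]
) -> ErrorSummary:
    """Mean Euclidean localization error and mean relative absolute
    amplitude error versus ground truth, with a per-depth breakdown."""
    if len(fits) != len(truths):
        raise ValueError("fits and truths differ in length")
    loc = np.array(
        [np.linalg.norm(f.position - t.position) for f, t in zip(fits, truths)]
    )
    amp = np.array(
        [
            abs(f.amplitude - t.peak_amplitude) / t.peak_amplitude
            for f, t in zip(fits, truths)
        ]
    )
    radii = np.array([round(float(np.linalg.norm(t.position)), 4) for t in truths])
    per_depth = {}
    for r in np.unique(radii):
        m = radii == r
        per_depth[float(r)] = {
            "localization_error_m": float(loc[m].mean()),
            "amplitude_error": float(amp[m].mean()),
            "n": int(m.sum()),
        }
    return ErrorSummary(
        localization_error=float(loc.mean()),
        amplitude_error=float(amp.mean()),
        n=len(fits),
        per_depth=per_depth,
    )
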