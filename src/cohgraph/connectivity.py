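"""Magnitude-squared coherence, band averaging, dynamic threshold + normalization.

MSC between channels i and j at angular frequency w is

    phi_ij(w) = |S_ij(w)|^2 / (S_ii(w) S_jj(w)),

with cross- and auto-spectra averaged over epochs (one epoch = one
segment, Hamming-windowed, zero-padded to nfft). Band matrices are the
mean of phi over the bins inside the band; each subject/band matrix is
then thresholded at the midpoint of its off-diagonal range,

    U = min(m_ij) + (max(m_ij) - min(m_ij)) / 2,

and the survivors are normalized by the off-diagonal maximum, giving the
connectivity matrix W whose nonzero entries are the graph edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming

from .bands import BandDefinition
from .montage import N_CHANNELS

logger = logging.getLogger(__name__)

_OFFDIAG = ~np.eye(N_CHANNELS, dtype=bool)


@dataclass
class CoherenceSpectrum:
    """Full MSC spectrum: 19 x 19 x F, values in [0, 1]."""

    phi: np.ndarray
    freqs: np.ndarray
    n_epochs_used: int

    def __post_init__(self) -> None:
        if self.phi.shape[:2] != (N_CHANNELS, N_CHANNELS):
            raise ValueError("phi must be 19 x 19 x F")
        if self.phi.shape[2] != self.freqs.size:
            raise ValueError("freqs length must match phi's last axis")

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandCoherenceMatrix:
    """Band-averaged MSC matrix M for one subject and band."""

    M: np.ndarray
    band: BandDefinition
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.M.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("M must be 19 x 19")


@dataclass
class ConnectivityMatrix:
    """Thresholded, max-normalized coherence matrix W (graph weights)."""

    W: np.ndarray
    threshold_value: float
    band: BandDefinition
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.W.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("W must be 19 x 19")


def coherence_spectrum(epochs, nfft: int = 256) -> CoherenceSpectrum:
    """Estimate the MSC spectrum from an epoch set.

    Each epoch is one segment: Hamming-windowed, zero-padded to ``nfft``;
    cross-/auto-spectra are averaged across epochs before forming the MSC
    ratio. Frequency spacing is fs/nfft (0.78125 Hz at fs 200, nfft 256).
    The DC bin is dropped; frequencies span (0, fs/2].
    """
    data = epochs.epochs
    n_ep, n_ch, n_s = data.shape
    if n_ep < 2:
        raise ValueError(
            "MSC needs at least 2 epochs: with a single segment the "
            "cross-spectrum magnitude cancels the auto-spectra and the "
            "estimate is identically 1"
        )
    if nfft < n_s:
        raise ValueError(f"nfft ({nfft}) must be >= epoch length ({n_s})")

    win = hamming(n_s, sym=False)
    X = np.fft.rfft(data * win[None, None, :], n=nfft, axis=2)
    X = X[:, :, 1:]  # drop DC
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epochs.fs)[1:]

    # S[i, j, f] averaged over epochs
    S = np.einsum("eif,ejf->ijf", X, np.conj(X)) / n_ep
    auto = np.real(np.einsum("iif->if", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.abs(S) ** 2 / denom
    phi = np.where(denom > 0, phi, 0.0)
    np.clip(phi, 0.0, 1.0, out=phi)
    idx = np.arange(n_ch)
    phi[idx, idx, :] = 1.0
    phi = 0.5 * (phi + phi.transpose(1, 0, 2))  # enforce exact symmetry
    return CoherenceSpectrum(phi=phi, freqs=freqs, n_epochs_used=n_ep)


def band_average(
    spectrum: CoherenceSpectrum, band: BandDefinition, subject_id: str = ""
) -> BandCoherenceMatrix:
    """Average the MSC spectrum over the bins inside a band (edges inclusive)."""
    mask = (spectrum.freqs >= band.ll) & (spectrum.freqs <= band.ul)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.ll}, {band.ul}] Hz contains no frequency bins"
        )
    M = spectrum.phi[:, :, mask].mean(axis=2)
    return BandCoherenceMatrix(M=M, band=band, subject_id=subject_id)


def threshold_normalize(
    matrix: BandCoherenceMatrix, binarize: bool = False
) -> ConnectivityMatrix:
    """Apply the dynamic midpoint threshold and max-normalize.

    U is the midpoint of the off-diagonal [min, max] range. Entries below
    U become 0; survivors are divided by the off-diagonal maximum (or set
    to 1 when ``binarize``). The diagonal is removed first and stays zero.
    """
    M = matrix.M
    off = M[_OFFDIAG]
    lo, hi = float(off.min()), float(off.max())
    U = lo + (hi - lo) / 2.0
    if lo == hi:
        logger.warning(
            "subject %s band %s: degenerate coherence matrix (all off-diagonal "
            "entries equal %.4g); every entry survives the threshold",
            matrix.subject_id, matrix.band.name, lo,
        )
    W = np.where(M >= U, M, 0.0)
    if hi > 0:
        W = W / hi
    if binarize:
        W = (W > 0).astype(float)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    return ConnectivityMatrix(
        W=W, threshold_value=U, band=matrix.band, subject_id=matrix.subject_id
    )


def upper_triangle(W: np.ndarray) -> np.ndarray:
    """The 171 distinct off-diagonal coefficients of a symmetric 19 x 19 matrix."""
    iu = np.triu_indices(N_CHANNELS, k=1)
    return np.asarray(W)[iu]
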