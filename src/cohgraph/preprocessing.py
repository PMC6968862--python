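"""EEG preprocessing: ICA artifact removal, event-locked epoching, surface Laplacian.

The cleanup stage decomposes the 19-channel record into independent
components (FastICA), flags ocular/muscular components by deterministic
heuristics, zeroes them, and reconstructs the record. Epochs are then cut
from 100 ms before to 900 ms after each correct-response stimulus onset,
and a spherical-spline surface Laplacian suppresses volume-conduction
smearing before coherence estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import eval_legendre
from scipy.stats import kurtosis as _kurtosis
from sklearn.decomposition import FastICA

from .montage import CHANNELS, N_CHANNELS, canonical_label, electrode_positions

logger = logging.getLogger(__name__)

EPOCH_PRE_S = 0.1   # seconds before stimulus onset
EPOCH_POST_S = 0.9  # seconds after stimulus onset


# ---------------------------------------------------------------------------
# Containers


@dataclass
class EEGRecording:
    """A 19-channel scalp recording in canonical montage order.

    samples are channels x time, in microvolts.
    """

    samples: np.ndarray
    fs: float = 200.0
    channel_labels: tuple[str, ...] = CHANNELS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(
                f"samples must be {N_CHANNELS} x T, got shape {self.samples.shape}"
            )
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        labels = tuple(canonical_label(c) for c in self.channel_labels)
        if labels != CHANNELS:
            raise ValueError("channel_labels must be the canonical 19-label montage order")
        self.channel_labels = labels

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventLog:
    """Stimulus onsets (sample indices) and per-trial response correctness."""

    onsets: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.onsets.shape != self.correct.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and correct must be matching 1-D arrays")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class EpochSet:
    """Event-locked epochs: n_epochs x 19 channels x n_samples."""

    epochs: np.ndarray
    fs: float
    subject_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != N_CHANNELS:
            raise ValueError(
                f"epochs must be n_epochs x {N_CHANNELS} x n_samples, "
                f"got {self.epochs.shape}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


@dataclass
class IcaDecomposition:
    """Audit record of an ICA cleanup pass."""

    unmixing: np.ndarray                 # k x 19
    mixing: np.ndarray                   # 19 x k
    components: np.ndarray               # k x T source time courses
    mean: np.ndarray                     # per-channel mean removed by ICA
    artifact_flags: np.ndarray           # bool per component
    flag_evidence: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(self.artifact_flags.sum())


@dataclass(frozen=True)
class FlagCriteria:
    """Deterministic component-flagging thresholds.

    A component is treated as artifactual when any criterion fires:
    its scalp projection correlates with the frontal ocular pattern
    (blinks / eye movements), most of its spectral power lies above
    ``hf_cutoff_hz`` (muscle), or its time course is strongly peaked
    (excess kurtosis; transient artifacts).
    """

    frontal_corr: float = 0.7
    hf_ratio: float = 0.6
    hf_cutoff_hz: float = 15.0
    kurtosis: float = 10.0


#: Scalp pattern of ocular activity: frontal-pole dominant.
OCULAR_PATTERN = np.zeros(N_CHANNELS)
for _lab, _w in (("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.45), ("F8", 0.45),
                 ("F3", 0.15), ("F4", 0.15)):
    OCULAR_PATTERN[CHANNELS.index(_lab)] = _w


# ---------------------------------------------------------------------------
# Artifact removal


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def remove_artifacts(
    recording: EEGRecording,
    criteria: FlagCriteria = FlagCriteria(),
    seed: int = 0,
    n_components: int = N_CHANNELS,
    max_iter: int = 1000,
) -> tuple[EEGRecording, IcaDecomposition]:
    """Decompose into independent components, zero flagged ones, reconstruct.

    With nothing flagged the reconstruction is the identity up to numerical
    tolerance (exactly so at full rank). Raises when the data rank is below
    ``n_components`` (e.g. a constant channel at full rank), which makes
    the decomposition degenerate.
    """
    X = recording.samples
    if recording.n_samples < 10 * N_CHANNELS:
        raise ValueError(
            f"need at least {10 * N_CHANNELS} samples for a stable decomposition, "
            f"got {recording.n_samples}"
        )
    centered = X - X.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[n_components - 1] < 1e-10 * sv[0]:
        raise ValueError(
            "rank-deficient recording (constant or duplicated channel) for "
            f"a {n_components}-component decomposition"
        )

    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        sources = ica.fit_transform(X.T).T          # k x T
    mixing = ica.mixing_                            # 19 x k
    k = sources.shape[0]

    frontal = np.array([abs(_corr(mixing[:, c], OCULAR_PATTERN)) for c in range(k)])

    freqs, psd = sps.periodogram(sources, fs=recording.fs, axis=1)
    total = psd.sum(axis=1)
    hf = psd[:, freqs > criteria.hf_cutoff_hz].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hf_ratio = np.where(total > 0, hf / total, 0.0)

    kurt = _kurtosis(sources, axis=1, fisher=True)

    flags = (
        (frontal > criteria.frontal_corr)
        | (hf_ratio > criteria.hf_ratio)
        | (kurt > criteria.kurtosis)
    )

    clean_sources = sources.copy()
    clean_sources[flags, :] = 0.0
    reconstructed = mixing @ clean_sources + ica.mean_[:, None]

    decomposition = IcaDecomposition(
        unmixing=ica.components_,
        mixing=mixing,
        components=sources,
        mean=ica.mean_.copy(),
        artifact_flags=flags,
        flag_evidence={
            "frontal_corr": frontal,
            "hf_ratio": hf_ratio,
            "kurtosis": kurt,
        },
    )
    if flags.any():
        logger.info(
            "subject %s: flagged %d/%d ICA components",
            recording.subject_id, int(flags.sum()), k,
        )
    cleaned = EEGRecording(
        samples=reconstructed, fs=recording.fs, subject_id=recording.subject_id
    )
    return cleaned, decomposition


# ---------------------------------------------------------------------------
# Window selection


def select_windows(
    recording: EEGRecording, events: EventLog, n_keep: int
) -> EpochSet:
    """Cut the first ``n_keep`` correct-response epochs.

    Each epoch spans [onset - 100 ms, onset + 900 ms). Earliest correct
    trials are taken first so that every cohort member contributes the
    same number of windows deterministically.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be positive")
    pre = int(round(EPOCH_PRE_S * recording.fs))
    post = int(round(EPOCH_POST_S * recording.fs))
    n_samples = pre + post

    correct_onsets = events.onsets[events.correct]
    n_correct = correct_onsets.size
    if n_correct < n_keep:
        raise ValueError(
            f"requested {n_keep} epochs but only {n_correct} correct trials "
            f"are available (deficit {n_keep - n_correct})"
        )
    chosen = correct_onsets[:n_keep]
    if chosen.size and (chosen[0] - pre < 0 or chosen[-1] + post > recording.n_samples):
        raise ValueError("an epoch window extends beyond the recording")

    epochs = np.stack(
        [recording.samples[:, on - pre: on + post] for on in chosen], axis=0
    )
    assert epochs.shape == (n_keep, N_CHANNELS, n_samples)
    return EpochSet(epochs=epochs, fs=recording.fs, subject_id=recording.subject_id)


# ---------------------------------------------------------------------------
# Spherical-spline surface Laplacian


def _legendre_kernels(cosang: np.ndarray, m: int, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Perrin spherical-spline kernels g (potential) and h (Laplacian)."""
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, n_terms + 1):
        P = eval_legendre(n, cosang)
        w = (2 * n + 1) / (n * (n + 1)) ** m
        g += w * P
        h += (n * (n + 1)) * w * P  # = (2n+1) / (n(n+1))^(m-1)
    return g / (4 * np.pi), h / (4 * np.pi)


def surface_laplacian(
    epochs: EpochSet,
    spline_order: int = 4,
    regularization: float = 1e-5,
    n_legendre_terms: int = 50,
    positions: np.ndarray | None = None,
) -> EpochSet:
    """Spherical-spline surface Laplacian of every epoch.

    Interpolates the 19 scalp potentials with a spherical spline of order
    ``spline_order`` on unit-sphere 10-20 coordinates and evaluates its
    surface Laplacian at the electrodes. The operation is linear and
    reference-free (insensitive to a common offset), and maps a spatially
    constant field to zero. Output units are proportional to current
    source density; the scale is the unit-sphere spline scale, not a
    physical head-size calibration.
    """
    pos = electrode_positions() if positions is None else np.asarray(positions, float)
    if pos.shape != (N_CHANNELS, 3):
        raise ValueError(f"positions must be {N_CHANNELS} x 3")
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(N_CHANNELS, dtype=bool)] > 1 - 1e-12):
        raise ValueError("duplicate electrode coordinates make the spline singular")

    G, H = _legendre_kernels(cosang, spline_order, n_legendre_terms)

    # Solve the constrained system [[G + lambda*I, 1], [1^T, 0]] once and
    # reuse its factorization for every time sample of every epoch.
    n = N_CHANNELS
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + regularization * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0

    flat = epochs.epochs.transpose(1, 0, 2).reshape(n, -1)  # channels x (epochs*time)
    rhs = np.vstack([flat, np.zeros((1, flat.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    coefs = sol[:n, :]
    lap = H @ coefs
    out = lap.reshape(n, epochs.n_epochs, epochs.n_samples).transpose(1, 0, 2)
    return EpochSet(
        epochs=out, fs=epochs.fs,
        subject_id=epochs.subject_id, class_label=epochs.class_label,
    )
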