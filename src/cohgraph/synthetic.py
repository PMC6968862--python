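"""Synthetic EEG cohorts with planted, class-dependent coherence structure.

The generator emulates the study conditions of the recording regime this
pipeline targets: 19-channel 10-20 montage at 200 Hz, signals band-limited
to 0.5-30 Hz over a 1/f background, 57 one-second stimulus-locked epochs
per subject, and three achievement classes (HA/AA/LA).

Signal model
------------
Each recording is one stationary Gaussian process synthesized on the
full-record frequency grid, so it is exactly band-limited. All channels
carry independent 1/f-shaped noise. Within the planted band (plus a
small spectral guard covering the MSC estimator's mainlobe), the
planted electrodes share a common source mixed with channel-private
noise:

    Z_i(f) = A(f) * (a * S(f) + b * N_i(f)),   a^2 + b^2 = 1.

Because MSC between two channels sharing a fraction ``a^2`` of their
power is ``a^4``, setting ``a = c**0.25`` plants a magnitude-squared
coherence of exactly ``c`` at every in-band frequency — making planted
coupling an analytically known, recoverable ground truth.

Everything is driven by one ``numpy`` Generator seeded from the config,
so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .bands import get_band
from .graph_features import CLASS_COLUMN, CLASS_LABELS, FeatureTable
from .montage import CHANNELS, N_CHANNELS, canonical_label
from .preprocessing import EEGRecording, EventLog

#: seconds of padding on each side of the 1-s epoch inside a trial slot
_TRIAL_PAD_S = 0.2
_TARGET_RMS_UV = 20.0


@dataclass
class SimConfig:
    """Conditions of a simulated cohort."""

    n_subjects_per_class: int = 19
    class_labels: tuple[str, ...] = CLASS_LABELS
    fs: float = 200.0
    n_epochs_per_subject: int = 57
    epoch_ms: float = 1000.0
    planted_band: str = "alpha"
    planted_electrodes: tuple[str, ...] = ("T3", "Cz")
    coupling_strength_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"HA": 0.2, "AA": 0.45, "LA": 0.8}
    )
    noise_exponent: float = 1.0
    #: widen the planted interval by this margin (Hz) on each side, so the
    #: finite-window MSC estimator's band-edge bins are not diluted by
    #: leakage from incoherent neighbors; half the 1-s epoch resolution
    band_guard_hz: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_samp = self.epoch_ms * self.fs / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_ms x fs must give an integer sample count")
        bad = [c for c in self.class_labels if c not in CLASS_LABELS]
        if bad:
            raise ValueError(f"class labels must be drawn from {CLASS_LABELS}, got {bad}")
        get_band(self.planted_band)  # raises on invalid band
        self.planted_electrodes = tuple(
            canonical_label(e) for e in self.planted_electrodes
        )
        for cls, c in self.coupling_strength_by_class.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling for {cls} must be in [0, 1], got {c}")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_ms * self.fs / 1000.0))


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    subject_classes: dict[str, str]
    planted_electrodes: tuple[str, ...]
    planted_band: str
    coupling_strength_by_class: dict[str, float]
    expected_ranking: tuple[str, ...]  # classes sorted by planted effect, desc

    def to_json_dict(self) -> dict:
        return {
            "subject_classes": self.subject_classes,
            "planted_electrodes": list(self.planted_electrodes),
            "planted_band": self.planted_band,
            "coupling_strength_by_class": self.coupling_strength_by_class,
            "expected_ranking": list(self.expected_ranking),
        }


# ---------------------------------------------------------------------------
# Spectral synthesis helpers


def _spectral_amplitude(freqs: np.ndarray, slope: float) -> np.ndarray:
    """1/f^(slope/2) amplitude profile, band-limited to 0.5-30 Hz."""
    amp = np.zeros_like(freqs)
    mask = (freqs >= 0.5) & (freqs <= 30.0)
    amp[mask] = freqs[mask] ** (-slope / 2.0)
    return amp


def _amplitude_scale(amp: np.ndarray, n: int) -> float:
    """Scale factor giving ~_TARGET_RMS_UV per channel after irfft."""
    # var(irfft of independent CN(0,1) bins with weights amp) = 2*sum(amp^2)/n^2
    var = 2.0 * float((amp ** 2).sum()) / n ** 2
    return _TARGET_RMS_UV / np.sqrt(var) if var > 0 else 0.0


def _complex_normal(rng: np.random.Generator, shape) -> np.ndarray:
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)


def _synth_recording(
    rng: np.random.Generator,
    config: SimConfig,
    coupling: float,
    n_samples: int,
) -> np.ndarray:
    """One stationary 19 x n_samples recording with planted coherence.

    The whole record is synthesized on the rfft grid, so it is exactly
    band-limited to 0.5-30 Hz and free of splice discontinuities; the
    planted electrodes share the common source at every in-band bin.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.fs)
    amp = _spectral_amplitude(freqs, config.noise_exponent)
    scale = _amplitude_scale(amp, n_samples)
    band = get_band(config.planted_band)
    g = config.band_guard_hz
    in_band = (freqs >= band.ll - g) & (freqs <= band.ul + g) & (amp > 0)

    a = coupling ** 0.25
    b = np.sqrt(1.0 - np.sqrt(coupling))
    planted_idx = [CHANNELS.index(e) for e in config.planted_electrodes]

    noise = _complex_normal(rng, (N_CHANNELS, freqs.size))
    shared = _complex_normal(rng, freqs.size)
    Z = amp[None, :] * noise
    for i in planted_idx:
        Z[i, in_band] = amp[in_band] * (a * shared[in_band] + b * noise[i, in_band])
    return np.fft.irfft(Z, n=n_samples, axis=1) * scale


# ---------------------------------------------------------------------------
# Cohort generation


def _subject_ids(config: SimConfig) -> list[tuple[str, str]]:
    out = []
    i = 1
    for cls in config.class_labels:
        for _ in range(config.n_subjects_per_class):
            out.append((f"s{i:03d}", cls))
            i += 1
    return out


def generate_cohort(
    config: SimConfig,
) -> tuple[list[EEGRecording], list[EventLog], GroundTruth]:
    """Simulate one recording + event log per subject.

    Trials are laid out in non-overlapping slots; each slot holds one
    1-s stimulus-locked window (100 ms pre + 900 ms post onset) whose
    content carries the class's planted coherence. All simulated
    responses are correct.
    """
    fs = config.fs
    n_epoch = config.epoch_samples
    pad = int(round(_TRIAL_PAD_S * fs))
    slot = n_epoch + 2 * pad
    n_trials = config.n_epochs_per_subject
    n_samples = slot * n_trials
    pre = int(round(0.1 * fs))

    rng = np.random.default_rng(config.seed)
    recordings, logs = [], []
    subject_classes = {}
    for sid, cls in _subject_ids(config):
        subject_classes[sid] = cls
        coupling = float(config.coupling_strength_by_class.get(cls, 0.0))
        samples = _synth_recording(rng, config, coupling, n_samples)
        onsets = (np.arange(n_trials) * slot + pad + pre).astype(int)
        recordings.append(EEGRecording(samples=samples, fs=fs, subject_id=sid))
        logs.append(EventLog(onsets=onsets, correct=np.ones(n_trials, dtype=bool)))

    ranking = tuple(
        sorted(
            config.class_labels,
            key=lambda c: -float(config.coupling_strength_by_class.get(c, 0.0)),
        )
    )
    truth = GroundTruth(
        subject_classes=subject_classes,
        planted_electrodes=config.planted_electrodes,
        planted_band=config.planted_band,
        coupling_strength_by_class=dict(config.coupling_strength_by_class),
        expected_ranking=ranking,
    )
    return recordings, logs, truth


# ---------------------------------------------------------------------------
# Feature-level cohort generation


def generate_feature_cohort(
    config: SimConfig,
    metric: str = "Cv",
    baseline_mean: float = 0.55,
    baseline_sd: float = 0.06,
    class_offsets: Mapping[str, float] | None = None,
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> tuple[FeatureTable, GroundTruth]:
    """Draw a feature table directly, with class-separated planted electrodes.

    Every electrode's value is Gaussian around ``baseline_mean``; at the
    planted electrodes each class's mean is shifted by its entry in
    ``class_offsets`` (default: proportional to the configured coupling
    strengths, scaled so the strongest class sits ~0.25 above baseline).
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    if class_offsets is None:
        coup = config.coupling_strength_by_class
        top = max(float(v) for v in coup.values()) or 1.0
        class_offsets = {c: 0.25 * float(coup.get(c, 0.0)) / top
                         for c in config.class_labels}
    rng = np.random.default_rng(config.seed)
    planted_idx = [CHANNELS.index(e) for e in config.planted_electrodes]

    rows, index, classes = [], [], []
    subject_classes = {}
    for sid, cls in _subject_ids(config):
        vals = rng.normal(baseline_mean, baseline_sd, size=N_CHANNELS)
        vals[planted_idx] += float(class_offsets.get(cls, 0.0))
        if clip is not None:
            vals = np.clip(vals, *clip)
        rows.append(vals)
        index.append(sid)
        classes.append(cls)
        subject_classes[sid] = cls

    data = pd.DataFrame(rows, index=pd.Index(index, name="Participant"),
                        columns=list(CHANNELS))
    data[CLASS_COLUMN] = classes
    table = FeatureTable(data=data, band=get_band(config.planted_band).name,
                         metric=metric)
    ranking = tuple(
        sorted(config.class_labels,
               key=lambda c: -float(class_offsets.get(c, 0.0)))
    )
    truth = GroundTruth(
        subject_classes=subject_classes,
        planted_electrodes=config.planted_electrodes,
        planted_band=config.planted_band,
        coupling_strength_by_class=dict(config.coupling_strength_by_class),
        expected_ranking=ranking,
    )
    return table, truth


def generate_outlier_cohort(
    n_by_class: Mapping[str, int] | None = None,
    n_outliers_by_class: Mapping[str, int] | None = None,
    seed: int = 0,
    class_centers: Mapping[str, float] | None = None,
    sd: float = 0.02,
) -> tuple[dict[str, FeatureTable], list[str]]:
    """All 15 feature-table variants for a cohort with planted outliers.

    Each class occupies a tight Gaussian ball around its own center in
    the 19-electrode feature space; the designated outliers are drawn
    around a *foreign* class's center instead, so their silhouette
    against their nominal label is non-positive while everyone else
    scores positive. Defaults reproduce an 18/20/19 cohort with 3/6/4
    planted outliers (13 in total, leaving 15/14/15).

    Returns the table variants keyed by tag and the outlier subject ids.
    """
    n_by_class = dict(n_by_class or {"HA": 18, "AA": 20, "LA": 19})
    n_outliers_by_class = dict(n_outliers_by_class or {"HA": 3, "AA": 6, "LA": 4})
    class_centers = dict(class_centers or {"HA": 0.25, "AA": 0.5, "LA": 0.75})
    if sd <= 0:
        raise ValueError("sd must be positive")
    for cls, k in n_outliers_by_class.items():
        if k >= n_by_class.get(cls, 0):
            raise ValueError(f"class {cls}: outliers must be a strict minority")

    rng = np.random.default_rng(seed)
    rows, index, classes, outliers = [], [], [], []
    i = 1
    for cls in CLASS_LABELS:
        foreign = [c for c in CLASS_LABELS if c != cls]
        for j in range(n_by_class.get(cls, 0)):
            sid = f"s{i:03d}"
            i += 1
            if j < n_outliers_by_class.get(cls, 0):
                center = class_centers[foreign[j % len(foreign)]]
                outliers.append(sid)
            else:
                center = class_centers[cls]
            rows.append(rng.normal(center, sd, size=N_CHANNELS))
            index.append(sid)
            classes.append(cls)

    base = pd.DataFrame(rows, index=pd.Index(index, name="Participant"),
                        columns=list(CHANNELS))
    tables: dict[str, FeatureTable] = {}
    from .bands import CANONICAL_BANDS
    from .graph_features import METRICS

    for band in CANONICAL_BANDS:
        for metric in METRICS:
            # per-variant jitter keeps variants distinct but consistent
            data = base + rng.normal(0.0, sd / 10.0, size=base.shape)
            data[CLASS_COLUMN] = classes
            t = FeatureTable(data=data, band=band.name, metric=metric)
            tables[t.tag] = t
    return tables, outliers


# ---------------------------------------------------------------------------
# Artifact templates and injection


@dataclass
class ArtifactTemplate:
    """A stereotyped artifact: spatial pattern x time course x amplitude."""

    kind: str                   # "ocular" or "muscular"
    spatial_weights: np.ndarray  # 19-vector
    time_course: np.ndarray      # unit-scale waveform
    amplitude: float             # microvolts
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.spatial_weights = np.asarray(self.spatial_weights, dtype=float)
        self.time_course = np.asarray(self.time_course, dtype=float)
        if self.spatial_weights.shape != (N_CHANNELS,):
            raise ValueError(f"spatial_weights must have length {N_CHANNELS}")
        if self.kind == "ocular":
            frontal = [CHANNELS.index(e) for e in ("Fp1", "Fp2", "F7", "F8")]
            mass = np.abs(self.spatial_weights)
            if mass.sum() == 0 or mass[frontal].sum() / mass.sum() < 0.8:
                raise ValueError(
                    "ocular template must concentrate >=80% of its spatial "
                    "weight on Fp1/Fp2/F7/F8"
                )
        elif self.kind == "muscular":
            freqs = np.fft.rfftfreq(self.time_course.size, d=1.0 / self.fs)
            power = np.abs(np.fft.rfft(self.time_course)) ** 2
            if power.sum() == 0 or power[freqs > 15.0].sum() / power.sum() < 0.5:
                raise ValueError("muscular template must have spectral mass above 15 Hz")
        else:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def ocular_template(fs: float = 200.0, amplitude: float = 120.0) -> ArtifactTemplate:
    """A blink: ~300 ms frontal-dominant smooth deflection."""
    n = int(round(0.3 * fs))
    tc = hann(n) ** 2
    weights = np.zeros(N_CHANNELS)
    for lab, w in (("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.45), ("F8", 0.45),
                   ("F3", 0.1), ("F4", 0.1)):
        weights[CHANNELS.index(lab)] = w
    return ArtifactTemplate("ocular", weights, tc, amplitude, fs)


def muscular_template(
    fs: float = 200.0, amplitude: float = 40.0, seed: int = 12345
) -> ArtifactTemplate:
    """A ~500 ms temporal-region burst of >15 Hz activity."""
    n = int(round(0.5 * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    Z = np.where((freqs >= 18) & (freqs <= 45), 1.0, 0.0) * _complex_normal(rng, freqs.size)
    burst = np.fft.irfft(Z, n=n) * n
    burst *= hann(n)
    burst /= np.abs(burst).max()
    weights = np.zeros(N_CHANNELS)
    for lab, w in (("T3", 1.0), ("T4", 1.0), ("F7", 0.6), ("F8", 0.6),
                   ("T5", 0.4), ("T6", 0.4)):
        weights[CHANNELS.index(lab)] = w
    return ArtifactTemplate("muscular", weights, burst, amplitude, fs)


def inject_artifacts(
    recording: EEGRecording,
    template: ArtifactTemplate,
    rate: float,
    seed: int = 0,
) -> EEGRecording:
    """Superimpose template occurrences at random onsets (``rate`` events/min).

    Returns a new recording; the input is untouched. The event count is
    ``round(rate * duration_minutes)`` with onsets drawn uniformly.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    out = recording.samples.copy()
    n_events = int(round(rate * recording.duration_s / 60.0))
    tc_len = template.time_course.size
    if n_events > 0:
        if recording.n_samples <= tc_len:
            raise ValueError("recording too short for the artifact template")
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.integers(0, recording.n_samples - tc_len, size=n_events))
        patch = template.amplitude * np.outer(template.spatial_weights, template.time_course)
        for on in onsets:
            out[:, on: on + tc_len] += patch
    return EEGRecording(samples=out, fs=recording.fs, subject_id=recording.subject_id)
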