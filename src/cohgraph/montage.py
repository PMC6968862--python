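"""The fixed 19-channel 10-20 montage and its unit-sphere geometry.

All pipeline stages assume exactly these 19 scalp sites. Channel order is
fixed (alphabetical) so that matrices and feature tables from different
stages always line up by position.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order used everywhere downstream.
CHANNELS: tuple[str, ...] = (
    "C3", "C4", "Cz", "F3", "F4", "F7", "F8", "Fz", "Fp1", "Fp2",
    "O1", "O2", "P3", "P4", "Pz", "T3", "T4", "T5", "T6",
)

N_CHANNELS = len(CHANNELS)

_CANONICAL = {name.lower(): name for name in CHANNELS}

#: Sites whose position the 10-20 system defines directly on the two
#: cardinal circles: (inclination from vertex, azimuth) in degrees.
#: Azimuth is measured counterclockwise from the right pre-auricular
#: axis (+x = right ear, +y = nasion, +z = vertex).
_DIRECT_ANGLES: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "Fz": (45.0, 90.0),
    "Pz": (45.0, 270.0),
    "C3": (45.0, 180.0),
    "C4": (45.0, 0.0),
    "T3": (90.0, 180.0),
    "T4": (90.0, 0.0),
    "Fp1": (90.0, 108.0),
    "Fp2": (90.0, 72.0),
    "O1": (90.0, 252.0),
    "O2": (90.0, 288.0),
    "F7": (90.0, 144.0),
    "F8": (90.0, 36.0),
    "T5": (90.0, 216.0),
    "T6": (90.0, 324.0),
}

#: Sites the 10-20 system defines as the midpoint of an arc between two
#: already-placed sites (e.g. F3 lies midway between Fz and F7).
_MIDPOINTS: dict[str, tuple[str, str]] = {
    "F3": ("Fz", "F7"),
    "F4": ("Fz", "F8"),
    "P3": ("Pz", "T5"),
    "P4": ("Pz", "T6"),
}


def canonical_label(label: str) -> str:
    """Normalize a channel label (case-insensitive) to canonical casing.

    Raises ``ValueError`` for labels outside the 19-site montage.
    """
    key = label.strip().lower()
    if key not in _CANONICAL:
        raise ValueError(f"unknown 10-20 channel label: {label!r}")
    return _CANONICAL[key]


def channel_index(label: str) -> int:
    return CHANNELS.index(canonical_label(label))


def _unit_vector(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    th = np.deg2rad(inclination_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp_midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mid = a + b
    return mid / np.linalg.norm(mid)


def electrode_positions() -> np.ndarray:
    """Unit-sphere xyz coordinates for the 19 channels, in canonical order.

    Returns an array of shape (19, 3) with rows ordered as :data:`CHANNELS`.
    """
    pos: dict[str, np.ndarray] = {
        name: _unit_vector(*angles) for name, angles in _DIRECT_ANGLES.items()
    }
    for name, (p, q) in _MIDPOINTS.items():
        pos[name] = _slerp_midpoint(pos[p], pos[q])
    return np.array([pos[name] for name in CHANNELS])
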