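"""Canonical EEG frequency-band definitions."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A closed frequency interval [ll, ul] in Hz.

    Band edges are inclusive; a spectrum bin on a shared edge belongs to
    both adjacent bands (band ranges are approximate at the analysis
    resolution anyway).
    """

    name: str
    ll: float
    ul: float

    def __post_init__(self) -> None:
        if not 0 < self.ll < self.ul:
            raise ValueError(f"band limits must satisfy 0 < ll < ul, got {self}")

    def contains(self, freq: float) -> bool:
        return self.ll <= freq <= self.ul


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
BROADBAND = BandDefinition("broadband", 0.5, 30.0)

CANONICAL_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, BROADBAND)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}
# Greek aliases accepted on input.
_ALIASES = {"δ": "delta", "θ": "theta", "α": "alpha", "β": "beta",
            "0.5-30": "broadband", "0.5-30hz": "broadband"}


def get_band(name: str) -> BandDefinition:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _BY_NAME:
        raise ValueError(
            f"unknown band {name!r}; expected one of {sorted(_BY_NAME)}"
        )
    return _BY_NAME[key]
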