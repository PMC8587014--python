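"""Canonical EEG frequency bands.

The seven-band partition used throughout resting-state EEG source
connectivity work: delta (2-4 Hz), theta (4-8), alpha1 (8-10.5),
alpha2 (10.5-13), beta1 (13-20), beta2 (20-30) and gamma (30-45).
Band membership of a spectral bin is half-open, ``lo <= f < hi``, so a
bin at a shared edge (e.g. 10.5 Hz) belongs to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidBandError

__all__ = ["BandSpec", "CANONICAL_BANDS", "BAND_NAMES", "get_band"]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with half-open edges ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 <= lo < hi, got [{self.lo}, {self.hi})"
            )

    def contains(self, freqs):
        """Boolean mask of frequencies falling in ``[lo, hi)``."""
        return (freqs >= self.lo) & (freqs < self.hi)


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.5),
    BandSpec("alpha2", 10.5, 13.0),
    BandSpec("beta1", 13.0, 20.0),
    BandSpec("beta2", 20.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandSpec:
    """Look up a canonical band by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise InvalidBandError(
            f"unknown band {name!r}; canonical bands are {', '.join(BAND_NAMES)}"
        ) from None
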