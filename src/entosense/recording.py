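"""In-memory container for the sensor's 8-channel raw data stream.

A quadrant photodiode (QPD) splits the receiver focal plane into four
segments; lock-in demodulation separates the two emitter bands (808 nm and
980 nm) on each segment, so one recording carries 4 x 2 = 8 synchronous
sample streams, nominally at 20 kHz.

Quadrant orientation convention used throughout the package::

    Q1 | Q2        Q1 = top-left,  Q2 = top-right
    ---+---
    Q3 | Q4        Q3 = bottom-left, Q4 = bottom-right
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

QUADRANTS = (1, 2, 3, 4)
BANDS = (808, 980)
#: Canonical channel order; row ``i`` of :attr:`RawRecording.data` is ``CHANNELS[i]``.
CHANNELS = tuple(f"Q{q}_{b}" for q in QUADRANTS for b in BANDS)

LEFT_QUADRANTS = (1, 3)
RIGHT_QUADRANTS = (2, 4)
TOP_QUADRANTS = (1, 2)
BOTTOM_QUADRANTS = (3, 4)


def channel_index(quadrant: int, band: int) -> int:
    """Row index of channel ``(quadrant, band)`` in the canonical order."""
    return CHANNELS.index(f"Q{quadrant}_{band}")


def band_indices(band: int) -> list[int]:
    """Row indices of the four quadrant channels of one spectral band."""
    return [i for i, name in enumerate(CHANNELS) if name.endswith(f"_{band}")]


def quadrant_indices(quadrants: tuple[int, ...]) -> list[int]:
    """Row indices (both bands) of a set of quadrants."""
    return [
        i
        for i, name in enumerate(CHANNELS)
        if int(name[1]) in quadrants
    ]


@dataclass
class RawRecording:
    """Eight aligned sample streams plus acquisition metadata.

    Parameters
    ----------
    data : ndarray of shape (8, n_samples)
        One row per channel, ordered as :data:`CHANNELS`.
    sample_rate : float
        Samples per second per channel (default 20 kHz).
    start_time : str
        ISO-8601 timestamp of the first sample.
    device_id : str
        Identifier of the emitting sensor unit.
    """

    data: np.ndarray
    sample_rate: float = 20000.0
    start_time: str = "1970-01-01T00:00:00"
    device_id: str = "synthetic-0"
    channel_names: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(CHANNELS):
            raise DataError(
                f"recording must have exactly {len(CHANNELS)} channels; "
                f"got array of shape {self.data.shape}"
            )
        if tuple(self.channel_names) != CHANNELS:
            raise DataError(f"channel names must be {CHANNELS}")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by label, e.g. ``"Q1_808"``."""
        try:
            return self.data[CHANNELS.index(name)]
        except ValueError as exc:
            raise DataError(f"unknown channel {name!r}") from exc

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to ``start_time``."""
        return np.arange(self.n_samples) / self.sample_rate
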