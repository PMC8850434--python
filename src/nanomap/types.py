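"""Shared in-memory containers for the pipeline.

Conventions used throughout the package:

* coordinates are 0-based ``(row, col)`` pairs with pixel centers at integer
  positions; crops use half-open intervals;
* physical scales travel with the data (``pixel_size_um`` for light
  microscopy, ``nm_per_px`` for replica EM masks), never as module globals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageChannel", "SpotSet"]


@dataclass
class ImageChannel:
    """A single-channel 2-D grayscale image with its physical pixel pitch.

    Parameters
    ----------
    data:
        2-D float array of intensities.
    pixel_size_um:
        Physical size of one pixel in micrometres.
    label:
        Free-form channel name (e.g. ``"clathrin"`` or ``"EGFR"``).
    """

    data: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"ImageChannel requires a 2-D array, got ndim={self.data.ndim}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SpotSet:
    """Punctum locations with peak intensities.

    ``coords`` is an ``(n, 2)`` float array of ``(row, col)`` positions
    (sub-pixel positions allowed for ground truth; detected spots sit on the
    pixel grid).  ``intensities`` holds the peak (or true amplitude) of each
    punctum.
    """

    coords: np.ndarray
    intensities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if self.intensities is None:
            self.intensities = np.full(len(self.coords), np.nan)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) != len(self.coords):
            raise ValueError("intensities length must match coords")

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self):
        return iter(zip(self.coords, self.intensities))
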