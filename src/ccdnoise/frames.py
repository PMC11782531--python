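"""Frame container and detector quadrant geometry.

A frame is a 2-D grid of detector counts with its acquisition time.  The
reference detector read out through four independent ADCs, one per quadrant
(2 x 2 blocks of the sensor), so read-out, row and offset statistics are
always handled per quadrant: Q1 top-left, Q2 top-right, Q3 bottom-left,
Q4 bottom-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Frame", "QUADRANTS", "quadrant_slices", "eels_band"]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def quadrant_slices(shape: tuple[int, int]) -> list[tuple[slice, slice]]:
    """Row/column slices of the four ADC quadrants of a 2x2 segmented sensor."""
    r, c = shape
    rh, ch = r // 2, c // 2
    return [
        (slice(0, rh), slice(0, ch)),
        (slice(0, rh), slice(ch, c)),
        (slice(rh, r), slice(0, ch)),
        (slice(rh, r), slice(ch, c)),
    ]


def eels_band(shape: tuple[int, int], height: int | None = None) -> tuple[slice, slice]:
    """Central horizontal band used for spectrum read-out.

    On the reference detector the band is 260 rows high, centred on the
    horizontal quadrant boundary so it spans all four segments; ``height``
    defaults to a proportional band on smaller simulated sensors.
    """
    r, c = shape
    if height is None:
        height = max(2, int(round(r * 260 / 2048)))
    height = min(height, r)
    top = r // 2 - height // 2
    return (slice(top, top + height), slice(0, c))


@dataclass
class Frame:
    """A single detector read-out: counts, exposure time and provenance."""

    data: np.ndarray
    t_acq: float
    kind: str = "signal"  # "signal" | "dark"
    seed: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D")
        if self.t_acq < 0:
            raise ValueError("acquisition time must be >= 0")
        if self.kind not in ("signal", "dark"):
            raise ValueError(f"unknown frame kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray, **meta) -> "Frame":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Frame(np.asarray(data, dtype=float), self.t_acq, self.kind, self.seed, new_meta)
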