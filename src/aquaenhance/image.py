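"""The in-memory greyscale image container used by every stage.

A :class:`GrayImage` is a 2-D float64 grid plus a declared bit depth.  Two
roles exist:

* **displayable** images hold values inside ``[0, 2**bit_depth - 1]`` and can
  be quantized and written to disk;
* **non-displayable** intermediates (log-domain Retinex output, normalized
  unit-range images) may hold any finite real values and are flagged
  ``displayable=False`` so they are never accidentally saved or quantized
  without an explicit range mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["GrayImage"]


@dataclass(frozen=True)
class GrayImage:
    """2-D greyscale image with a declared bit depth.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities; stored as float64.
    bit_depth : int
        Number of bits per pixel; the displayable range is
        ``[0, 2**bit_depth - 1]``. Default 8.
    displayable : bool
        True when pixel values are guaranteed to lie inside the displayable
        range (enforced at construction); False for log-domain or normalized
        intermediates.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    displayable: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError(
                f"pixels must be a non-empty 2-D array, got shape {px.shape}"
            )
        if not (isinstance(self.bit_depth, (int, np.integer)) and self.bit_depth >= 1):
            raise InvalidParameterError(f"bit_depth must be a positive integer, got {self.bit_depth}")
        if not np.all(np.isfinite(px)):
            raise InvalidInputError("pixels must be finite")
        if self.displayable and (px.min() < 0 or px.max() > self.max_level):
            raise InvalidInputError(
                "displayable image has values outside "
                f"[0, {self.max_level}]: range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_level(self) -> int:
        """Largest representable grey level, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def quantized(self) -> "GrayImage":
        """Round-half-up to integer grey levels (displayable images only)."""
        if not self.displayable:
            raise InvalidInputError("cannot quantize a non-displayable image; map it to the displayable range first")
        q = np.floor(self.pixels + 0.5)
        q = np.clip(q, 0, self.max_level)
        return GrayImage(q, bit_depth=self.bit_depth, displayable=True)

    def is_integer_valued(self) -> bool:
        return bool(np.all(self.pixels == np.floor(self.pixels)))
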