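"""Image-quality measures: contrast (grey-value variance), MSE, PSNR, entropy.

* ``contrast`` is the population variance of grey values, mean-of-squares
  minus square-of-mean; it doubles as the optimizer's fitness function, so
  the objective being maximized and the reported "Contrast" column are the
  same computation.
* ``mse``/``psnr`` compare an (original, processed) pair;
  PSNR = 10·log10(m²/MSE) with m the maximum representable level
  (255 for 8-bit).  Zero MSE means infinite PSNR and is signalled as a
  degenerate case, not returned as a number.
* ``entropy`` is the Shannon entropy, in bits (base-2 log), of the empirical
  grey-level histogram of an integer-quantized image; it lies in
  [0, bit_depth].  Base 2 is the convention under which typical 8-bit tank
  images score 5–7.

Contrast is computed on the real-valued (pre-quantization) pipeline output
and entropy on the quantized output, matching each measure's domain.  A
histogram-weighted contrast shortcut is provided for the optimizer's inner
loop; on quantized inputs it agrees with the per-pixel path to 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError
from .image import GrayImage

__all__ = [
    "QualityReport",
    "contrast",
    "contrast_from_histogram",
    "mse",
    "psnr",
    "entropy",
    "report",
]


def contrast(image: GrayImage) -> float:
    """Population variance of grey values (mean of squares − square of mean)."""
    px = image.pixels
    mean = float(px.mean())
    mean_sq = float(np.mean(px * px))
    return max(mean_sq - mean * mean, 0.0)


def contrast_from_histogram(levels: np.ndarray, probabilities: np.ndarray) -> float:
    """Contrast of a discrete distribution over grey ``levels``.

    Equivalent to :func:`contrast` on any image whose values are drawn from
    ``levels`` with the given empirical frequencies; used as the optimizer's
    cheap fitness path.
    """
    levels = np.asarray(levels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    mean = float(np.dot(p, levels))
    mean_sq = float(np.dot(p, levels * levels))
    return max(mean_sq - mean * mean, 0.0)


def _check_same_shape(original: GrayImage, processed: GrayImage) -> None:
    if original.shape != processed.shape:
        raise InvalidInputError(
            f"image dimensions differ: {original.shape} vs {processed.shape}"
        )


def mse(original: GrayImage, processed: GrayImage) -> float:
    """Mean squared per-pixel difference."""
    _check_same_shape(original, processed)
    diff = original.pixels - processed.pixels
    return float(np.mean(diff * diff))


def psnr(original: GrayImage, processed: GrayImage, bit_depth: int | None = None) -> float:
    """Peak signal-to-noise ratio, 10·log10(m² / MSE), in dB.

    Raises :class:`DegenerateInputError` when MSE is zero (infinite PSNR);
    :func:`report` represents that case as an absent value.
    """
    if bit_depth is None:
        bit_depth = original.bit_depth
    err = mse(original, processed)
    if err == 0.0:
        raise DegenerateInputError("images are identical: MSE is zero, PSNR is infinite")
    m = (1 << bit_depth) - 1
    return 10.0 * math.log10(m * m / err)


def entropy(image: GrayImage) -> float:
    """Shannon entropy (bits) of the grey-level histogram.

    Requires an integer-quantized image; zero-probability levels
    contribute nothing.
    """
    if not image.is_integer_valued():
        raise InvalidInputError(
            "entropy requires integer grey levels; quantize the image first"
        )
    levels = image.pixels.astype(np.int64).ravel()
    if levels.min() < 0 or levels.max() > image.max_level:
        raise InvalidInputError("grey levels outside the displayable range")
    counts = np.bincount(levels)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class QualityReport:
    """The four quality measures for an (original, processed) pair.

    ``psnr`` is None when the images are identical (zero MSE).
    """

    contrast: float
    mse: float
    psnr: float | None
    entropy: float

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "mse": self.mse,
            "psnr": self.psnr,
            "entropy": self.entropy,
        }

    def to_text(self) -> str:
        """Flat key-value serialization, one metric per line."""
        lines = []
        for key, value in self.to_dict().items():
            lines.append(f"{key} = {'inf' if value is None else f'{value:.6f}'}")
        return "\n".join(lines) + "\n"


def report(original: GrayImage, processed: GrayImage) -> QualityReport:
    """Bundle the four metrics for an (original, processed) pair.

    Contrast is computed on the processed image as given (real-valued);
    entropy on its round-half-up quantized copy; MSE and PSNR on the pair.
    """
    _check_same_shape(original, processed)
    err = mse(original, processed)
    return QualityReport(
        contrast=contrast(processed),
        mse=err,
        psnr=None if err == 0.0 else psnr(original, processed),
        entropy=entropy(processed if processed.is_integer_valued() else processed.quantized()),
    )
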