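"""Classical comparison enhancements: linear stretch and histogram equalization.

Both preserve pixel rank order (non-strictly) and serve as reference points
for the adaptive pipeline: the linear stretch is the simplest contrast
enhancement but depends heavily on its cut-off choice, while plain histogram
equalization tends to amplify background noise at the dominant grey levels.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .image import GrayImage

__all__ = ["linear_enhance", "hist_equalize"]


def linear_enhance(
    image: GrayImage, low_percentile: float = 1.0, high_percentile: float = 99.0
) -> GrayImage:
    """Percentile-based linear contrast stretch.

    Levels at or below the low percentile map to 0, at or above the high
    percentile to the maximum level, linearly in between.  The default
    (1, 99) cut-offs keep single outliers from dominating the stretch.
    Output is real-valued; quantize explicitly for file output.
    """
    if not (0.0 <= low_percentile < high_percentile <= 100.0):
        raise InvalidParameterError(
            f"need 0 <= low < high <= 100, got ({low_percentile}, {high_percentile})"
        )
    px = image.pixels
    lo = float(np.percentile(px, low_percentile))
    hi = float(np.percentile(px, high_percentile))
    if hi == lo:
        raise DegenerateInputError(
            f"percentile window is flat (both cut-offs equal {lo}); "
            "cannot stretch a constant range"
        )
    out = (px - lo) / (hi - lo) * image.max_level
    out = np.clip(out, 0.0, image.max_level)
    return GrayImage(out, bit_depth=image.bit_depth, displayable=True)


def hist_equalize(image: GrayImage) -> GrayImage:
    """Classic CDF-mapping histogram equalization.

    Level v maps to round_half_up(max_level · cdf(v)) where the CDF is the
    non-exceedance (current level included) empirical distribution.  The
    output maximum always reaches the top level since cdf(max level) = 1.
    """
    if not image.is_integer_valued():
        raise InvalidInputError("histogram equalization requires an integer-quantized image")
    levels = image.pixels.astype(np.int64)
    if levels.min() < 0 or levels.max() > image.max_level:
        raise InvalidInputError("grey levels outside the displayable range")
    counts = np.bincount(levels.ravel(), minlength=image.max_level + 1)
    cdf = np.cumsum(counts) / levels.size
    mapping = np.floor(image.max_level * cdf + 0.5)
    out = mapping[levels]
    return GrayImage(out, bit_depth=image.bit_depth, displayable=True)
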