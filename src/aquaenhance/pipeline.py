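"""The six-step adaptive enhancement pipeline, plus image file I/O.

Given a displayable greyscale image the pipeline

1. takes the grey values of the input,
2. corrects uneven illumination with Multi-Scale Retinex (log domain),
3. normalizes the MSR output onto [0, 1] using its own min/max (the MSR
   output lives in the log domain, so its own range — not the raw image's —
   is the one that maps into the unit interval),
4. runs PSO to pick the incomplete-Beta shape pair (α, β) maximizing the
   grey-value variance (contrast) of the final image,
5. applies the winning transform pixelwise, and
6. maps the result back onto the displayable range.

The optimizer's inner loop never touches full images: the normalized MSR
output is quantized once to the 2**bit_depth attainable levels and reduced
to a histogram; each candidate (α, β) is then scored by evaluating the
transform exactly at those levels and taking the histogram-weighted
variance, which agrees with the per-pixel evaluation on the quantized image
to floating-point accuracy.  The final transform is applied per pixel to
the unquantized normalized image.

Everything is deterministic given the PSO seed (default 0).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, asdict

import imageio.v3 as iio
import numpy as np

from . import metrics
from .beta_transform import (
    BetaParams,
    apply_beta,
    denormalize,
    incomplete_beta,
    normalize,
)
from .errors import DegenerateInputError, ImageIOError, InvalidInputError
from .image import GrayImage
from .metrics import QualityReport, contrast_from_histogram
from .pso import PSOConfig, PSOResult, optimize
from .retinex import RetinexParams, msr

__all__ = [
    "EnhancementResult",
    "enhance",
    "enhance_beta_only",
    "load_image",
    "save_image",
]

#: ITU-R 601 luma weights for collapsing RGB input to a single channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EnhancementResult:
    """Everything a pipeline run produces.

    ``enhanced`` keeps real values for metric computation; use
    ``enhanced.quantized()`` for file output.  ``pso_result`` is None when
    the shape pair was forced rather than optimized.
    """

    enhanced: GrayImage
    selected_params: BetaParams
    pso_result: PSOResult | None
    report: QualityReport
    config_snapshot: dict


def _histogram_fitness(unit_pixels: np.ndarray, max_level: int):
    """Build the cheap contrast objective from a normalized image.

    Quantizes the unit-range values to the attainable levels v/max_level,
    keeps only the occupied levels and their frequencies, and returns a
    closure scoring a candidate (α, β) by the variance of the transformed,
    re-expanded levels.
    """
    q = np.floor(unit_pixels * max_level + 0.5)
    occupied, counts = np.unique(q, return_counts=True)
    u_levels = occupied / max_level
    probabilities = counts / unit_pixels.size

    def fitness(position: np.ndarray) -> float:
        params = BetaParams(float(position[0]), float(position[1]))
        transformed = incomplete_beta(params, u_levels)
        return contrast_from_histogram(max_level * np.asarray(transformed), probabilities)

    return fitness


def _finish(
    original: GrayImage,
    unit: GrayImage,
    params: BetaParams,
    pso_result: PSOResult | None,
    snapshot: dict,
) -> EnhancementResult:
    transformed = apply_beta(unit, params, method="exact")
    enhanced = denormalize(transformed, original.bit_depth)
    return EnhancementResult(
        enhanced=enhanced,
        selected_params=params,
        pso_result=pso_result,
        report=metrics.report(original, enhanced),
        config_snapshot=snapshot,
    )


def _select_params(unit: GrayImage, pso_config: PSOConfig) -> tuple[BetaParams, PSOResult]:
    fitness = _histogram_fitness(unit.pixels, unit.max_level)
    result = optimize(fitness, pso_config)
    params = BetaParams(float(result.best_position[0]), float(result.best_position[1]))
    return params, result


def _snapshot(step_msr: bool, retinex_params, pso_config, forced) -> dict:
    snap = {
        "msr": step_msr,
        "retinex": asdict(retinex_params) if retinex_params is not None else None,
        "pso": asdict(pso_config) if pso_config is not None else None,
        "forced_params": asdict(forced) if forced is not None else None,
    }
    return snap


def enhance(
    image: GrayImage,
    retinex_params: RetinexParams | None = None,
    pso_config: PSOConfig | None = None,
    forced_params: BetaParams | None = None,
) -> EnhancementResult:
    """Run the full adaptive pipeline (MSR + PSO-selected Beta transform).

    ``forced_params`` bypasses the optimizer and applies the given shape
    pair directly (useful for ablation: α=β=1 reduces the pipeline to MSR
    followed by a full-range linear rescale).
    """
    if retinex_params is None:
        retinex_params = RetinexParams()
    if pso_config is None:
        pso_config = PSOConfig()
    corrected = msr(image, retinex_params)
    try:
        unit = normalize(corrected)
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            f"illumination correction produced a constant image: {exc}"
        ) from exc
    snapshot = _snapshot(True, retinex_params, pso_config, forced_params)
    if forced_params is not None:
        return _finish(image, unit, forced_params, None, snapshot)
    params, result = _select_params(unit, pso_config)
    return _finish(image, unit, params, result, snapshot)


def enhance_beta_only(
    image: GrayImage,
    pso_config: PSOConfig | None = None,
    forced_params: BetaParams | None = None,
) -> EnhancementResult:
    """Run the pipeline without the illumination-correction step.

    The raw image is normalized directly and the transform's shape pair is
    optimized (or forced) exactly as in :func:`enhance`.
    """
    if pso_config is None:
        pso_config = PSOConfig()
    try:
        unit = normalize(image)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"constant input image: {exc}") from exc
    snapshot = _snapshot(False, None, pso_config, forced_params)
    if forced_params is not None:
        return _finish(image, unit, forced_params, None, snapshot)
    params, result = _select_params(unit, pso_config)
    return _finish(image, unit, params, result, snapshot)


_SUPPORTED = {".png", ".bmp", ".tif", ".tiff"}


def load_image(path) -> GrayImage:
    """Load a PNG/BMP/TIFF image as an 8-bit greyscale :class:`GrayImage`.

    Multi-channel input is collapsed with the ITU-R 601 luma weighting
    (0.299 R + 0.587 G + 0.114 B).
    """
    p = pathlib.Path(path)
    if p.suffix.lower() not in _SUPPORTED:
        raise ImageIOError(f"unsupported image format {p.suffix!r} for {p}")
    try:
        arr = iio.imread(p)
    except FileNotFoundError as exc:
        raise ImageIOError(f"cannot read {p}: file not found") from exc
    except Exception as exc:
        raise ImageIOError(f"cannot read {p}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        arr = np.floor(arr + 0.5)
    if arr.ndim != 2:
        raise ImageIOError(f"cannot interpret {p} as a 2-D greyscale image")
    return GrayImage(np.clip(arr, 0, 255), bit_depth=8, displayable=True)


def save_image(image: GrayImage, path) -> None:
    """Write a displayable image (round-half-up quantized) as 8-bit raster."""
    p = pathlib.Path(path)
    if p.suffix.lower() not in _SUPPORTED:
        raise ImageIOError(f"unsupported image format {p.suffix!r} for {p}")
    if not image.displayable:
        raise InvalidInputError("cannot save a non-displayable (log/unit-domain) image")
    if image.bit_depth != 8:
        raise ImageIOError(f"only 8-bit output supported, got bit depth {image.bit_depth}")
    data = image.quantized().pixels.astype(np.uint8)
    try:
        iio.imwrite(p, data)
    except Exception as exc:
        raise ImageIOError(f"cannot write {p}: {exc}") from exc
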