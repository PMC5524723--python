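"""Seeded synthetic tank scenes for testing every stage without real data.

Each scene emulates the acquisition conditions of an overhead camera above a
circular fish tank under a single lamp: a reflectance field (a lighter tank
background carrying darker elliptical fish-shaped blobs) is multiplied by a
smooth, spatially uneven illumination field, sensor noise is added, and the
result is quantized to the displayable range.  The multiplicative structure
makes the scenes a ground-truthed testbed for illumination correction: the
generator returns the reflectance and illumination grids alongside the
image, so tests can measure how much of the illumination gradient a method
removes.

The illumination field is a radial Gaussian rescaled so the brightest pixel
has relative brightness 1 and the dimmest exactly ``illumination_floor``
(default 0.35 — a strongly uneven lamp).  The defaults produce genuinely
low-contrast 8-bit images (grey-value variance well under 1200, versus
~16000 for a full-range bimodal image), so "enhancement increases contrast"
is a meaningful property to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .image import GrayImage

__all__ = ["SceneConfig", "SceneTruth", "generate", "fixture_suite"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic tank scene.

    Reflectances are in (0, 1]; blob axes in pixels; ``illumination_sigma``
    is a fraction of the image diagonal; ``noise_sigma`` is in grey levels.
    """

    width: int = 256
    height: int = 256
    n_blobs: int = 8
    blob_intensity_range: tuple[float, float] = (0.15, 0.35)
    background_reflectance: float = 0.55
    blob_axes_range: tuple[float, float] = (6.0, 20.0)
    illumination_center: tuple[float, float] = (0.15, 0.10)
    illumination_sigma: float = 0.6
    illumination_floor: float = 0.35
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InvalidParameterError("image dimensions must be positive")
        if self.n_blobs < 0:
            raise InvalidParameterError("n_blobs must be nonnegative")
        lo, hi = self.blob_intensity_range
        if not (0.0 < lo <= hi <= 1.0) or not (0.0 < self.background_reflectance <= 1.0):
            raise InvalidParameterError("reflectances must lie in (0, 1]")
        alo, ahi = self.blob_axes_range
        if not (0.0 < alo <= ahi):
            raise InvalidParameterError("blob axes range must be positive and ordered")
        if 2.0 * ahi > min(self.width, self.height):
            raise InvalidParameterError(
                f"blob axes up to {ahi} px cannot fit a {self.width}x{self.height} image"
            )
        if not (0.0 < self.illumination_floor <= 1.0):
            raise InvalidParameterError("illumination_floor must lie in (0, 1]")
        if self.illumination_sigma <= 0:
            raise InvalidParameterError("illumination_sigma must be positive")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class SceneTruth:
    """Ground-truth grids of a generated scene."""

    reflectance: np.ndarray
    illumination: np.ndarray


def _illumination_field(config: SceneConfig) -> np.ndarray:
    h, w = config.height, config.width
    diag = math.hypot(w, h)
    cx = (0.5 + config.illumination_center[0]) * w
    cy = (0.5 + config.illumination_center[1]) * h
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    sigma = config.illumination_sigma * diag
    raw = np.exp(-r2 / (2.0 * sigma * sigma))
    lo, hi = raw.min(), raw.max()
    floor = config.illumination_floor
    if hi == lo:
        return np.full((h, w), 1.0)
    return floor + (1.0 - floor) * (raw - lo) / (hi - lo)


def _reflectance_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    field = np.full((h, w), config.background_reflectance)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    lo_i, hi_i = config.blob_intensity_range
    lo_a, hi_a = config.blob_axes_range
    for _ in range(config.n_blobs):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        a = rng.uniform(lo_a, hi_a)
        b = rng.uniform(lo_a, hi_a)
        theta = rng.uniform(0, math.pi)
        value = rng.uniform(lo_i, hi_i)
        dx, dy = xx - cx, yy - cy
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        field[mask] = value
    return field


def generate(config: SceneConfig | None = None) -> tuple[GrayImage, SceneTruth]:
    """Generate one seeded scene plus its ground truth.

    image = quantize(255 · reflectance · illumination + noise), clipped to
    the 8-bit range.  Identical configs (including seed) give identical
    output.
    """
    if config is None:
        config = SceneConfig()
    rng = np.random.default_rng(config.seed)
    reflectance = _reflectance_field(config, rng)
    illumination = _illumination_field(config)
    signal = 255.0 * reflectance * illumination
    if config.noise_sigma > 0:
        signal = signal + rng.normal(0.0, config.noise_sigma, signal.shape)
    signal = np.clip(signal, 0.0, 255.0)
    quantized = np.floor(signal + 0.5)
    image = GrayImage(np.clip(quantized, 0, 255), bit_depth=8, displayable=True)
    return image, SceneTruth(reflectance=reflectance, illumination=illumination)


def fixture_suite(
    n: int, base_seed: int, config: SceneConfig | None = None
) -> list[tuple[GrayImage, SceneTruth]]:
    """Generate ``n`` scenes with seeds base_seed..base_seed+n−1.

    Blob counts vary per scene (derived deterministically from each scene's
    seed, so overlapping suites share images for shared seeds).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    base = config if config is not None else SceneConfig()
    scenes = []
    for seed in range(base_seed, base_seed + n):
        n_blobs = int(np.random.default_rng([seed, 0x5CE7E]).integers(5, 13))
        scenes.append(generate(replace(base, seed=seed, n_blobs=n_blobs)))
    return scenes
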