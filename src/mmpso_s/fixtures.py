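"""Synthetic histology-like image generation with exact ground truth.

H&E-stained tissue shows dark purple nuclei (hematoxylin) on a lighter
pink stroma (eosin); the segmentation pipeline exploits exactly this
polarity, selecting the sub-threshold dark map as the ROI map.  The
generator here emulates that structure — non-overlapping dark elliptical
"nuclei" with a purple tint on a brighter pink textured background — with
pixel-exact masks and centre lists, so every pipeline stage is testable
without downloading any histopathology dataset.

A second generator draws i.i.d. pixels from a three-component Gaussian
intensity mixture and reports the analytic decision boundaries (valleys)
between adjacent modes, giving a parameter-recovery target for the
two-threshold search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import ConfigError, InvalidInputError

__all__ = ["FixtureSpec", "make_nuclei_image", "make_trimodal_image", "mixture_valleys"]

_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class FixtureSpec:
    """Parameters of the synthetic nuclei image.

    Intensity modes are grayscale (BT.601 luminance) targets in [0, 255];
    the nucleus mode must be darker than the background mode.  Hues are
    RGB direction vectors, rescaled so the rendered region hits its
    luminance mode: nuclei purple-ish, background pink-ish.
    """

    shape: tuple[int, int] = (160, 160)
    n_nuclei: int = 25
    radius_range: tuple[float, float] = (6.0, 13.0)
    nucleus_mode: float = 70.0
    nucleus_sigma: float = 6.0
    background_mode: float = 185.0
    background_sigma: float = 6.0
    noise_sigma: float = 4.0
    nucleus_hue: tuple[float, float, float] = (0.50, 0.30, 0.75)
    background_hue: tuple[float, float, float] = (1.00, 0.75, 0.85)
    seed: int = 0
    max_attempts: int = 2000

    def validate(self) -> "FixtureSpec":
        if not (0 <= self.nucleus_mode <= 255 and 0 <= self.background_mode <= 255):
            raise ConfigError("intensity modes must lie in [0, 255]")
        if self.nucleus_mode >= self.background_mode:
            raise ConfigError(
                "nucleus_mode must be darker than background_mode (ROIs are dark)"
            )
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ConfigError(f"invalid radius_range {self.radius_range}")
        if self.n_nuclei < 0:
            raise ConfigError(f"n_nuclei must be >= 0, got {self.n_nuclei}")
        return self


def _tinted(hue: tuple[float, float, float], luminance: np.ndarray) -> np.ndarray:
    """RGB field whose BT.601 luminance equals ``luminance``, tinted along
    the given hue direction."""
    hue = np.asarray(hue, dtype=np.float64)
    scale = hue / float(hue @ _BT601)
    return luminance[..., None] * scale[None, None, :]


def make_nuclei_image(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the synthetic H&E-like image.

    Returns
    -------
    img : (H, W, 3) uint8 RGB image.
    gt : (H, W) boolean mask — union of the ellipse interiors.
    centres : (n, 2) float array of nucleus centres as (x, y).

    Nuclei are placed by rejection sampling without overlap; if the
    requested count cannot be placed within the attempt cap an error
    suggests fewer or smaller nuclei.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    params: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    while len(placed) < spec.n_nuclei:
        if attempts >= spec.max_attempts:
            raise InvalidInputError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in "
                f"{spec.max_attempts} attempts; use fewer or smaller nuclei"
            )
        attempts += 1
        a = rng.uniform(*spec.radius_range)
        b = rng.uniform(*spec.radius_range)
        r = max(a, b)
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        if any((cx - px) ** 2 + (cy - py) ** 2 < (r + pr + 1.0) ** 2 for px, py, pr in placed):
            continue
        theta = rng.uniform(0, np.pi)
        placed.append((cx, cy, r))
        params.append((cx, cy, a, b, theta))

    gt = np.zeros((h, w), dtype=bool)
    lum = rng.normal(spec.background_mode, spec.background_sigma, size=(h, w))
    img = _tinted(spec.background_hue, lum)
    for cx, cy, a, b, theta in params:
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        gt |= inside
        lum_n = rng.normal(spec.nucleus_mode, spec.nucleus_sigma, size=int(inside.sum()))
        hue = np.asarray(spec.nucleus_hue, dtype=np.float64)
        img[inside] = lum_n[:, None] * (hue / (hue @ _BT601))[None, :]
    img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    centres = np.array([(cx, cy) for cx, cy, _, _, _ in params]).reshape(-1, 2)
    return img, gt, centres


def mixture_valleys(modes, sigmas, weights) -> list[float]:
    """Decision boundaries between adjacent components of a Gaussian
    mixture: the point between two modes where the weighted densities
    cross.  For equal weights and sigmas this is the midpoint."""
    valleys = []
    for i in range(len(modes) - 1):
        m1, m2 = modes[i], modes[i + 1]
        s1, s2 = sigmas[i], sigmas[i + 1]
        w1, w2 = weights[i], weights[i + 1]

        def diff(x):
            return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

        valleys.append(float(brentq(diff, m1, m2)))
    return valleys


def make_trimodal_image(
    modes=(40, 128, 215),
    sigmas=(8.0, 8.0, 8.0),
    weights=(1 / 3, 1 / 3, 1 / 3),
    shape=(128, 128),
    seed: int = 0,
) -> tuple[np.ndarray, list[float]]:
    """Grayscale image of i.i.d. draws from a 3-component Gaussian
    intensity mixture, plus the analytic valley locations between modes.

    Modes must be strictly increasing and separated by at least 4 sigma
    from their neighbours so the valleys are well defined.
    """
    modes = list(modes)
    sigmas = list(sigmas)
    weights = list(np.asarray(weights, dtype=np.float64) / np.sum(weights))
    if len(modes) < 2:
        raise ConfigError("need at least two mixture components")
    if not (len(modes) == len(sigmas) == len(weights)):
        raise ConfigError("modes, sigmas and weights must have equal length")
    for i in range(len(modes) - 1):
        sep = modes[i + 1] - modes[i]
        if sep <= 0:
            raise ConfigError(f"modes must be strictly increasing, got {modes}")
        if sep < 4 * max(sigmas[i], sigmas[i + 1]):
            raise ConfigError(
                f"modes {modes[i]} and {modes[i + 1]} overlap: separation {sep} "
                f"< 4 sigma; increase separation or reduce sigma"
            )
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    comp = rng.choice(len(modes), size=n, p=weights)
    vals = rng.normal(np.asarray(modes)[comp], np.asarray(sigmas)[comp])
    img = np.clip(np.rint(vals), 0, 255).astype(np.uint8).reshape(shape)
    return img, mixture_valleys(modes, sigmas, weights)
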