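"""SLIC-style superpixel clustering and threshold-guided refinement.

The RGB image is clustered by local k-means over the joint feature
``[R, G, B, X, Y]``: centers start on a regular grid with spacing
``S = sqrt(np / nc)`` (``np`` pixels, ``nc`` requested clusters) and each
pixel is assigned, within a 2S x 2S window around each center, to the
center minimizing

    Dm = dRGB + (p / S) * dXY

where ``dRGB`` and ``dXY`` are Euclidean distances in color and image
coordinates and ``p`` controls compactness (larger p -> more compact,
grid-like clusters).  Centers move to the mean of their members; clusters
that lose all members are dropped, which is how the actual cluster count
``nc'`` can fall below ``nc``.  Iteration stops when the summed center
displacement (residual error E) falls below a tolerance.

Refinement keeps only the clusters whose mean pre-processed intensity lies
below the dark threshold ``t1`` found by the swarm search — whole clusters
are kept or discarded, never split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "SuperpixelConfig",
    "SuperpixelResult",
    "init_centers",
    "assign_pixels",
    "update_centers",
    "run_superpixel",
    "refine_clusters",
]


@dataclass
class SuperpixelConfig:
    """Superpixel stage parameters.

    nc : requested cluster count (an upper bound on the actual count).
    compactness : the weight p on the spatial term of the distance.
    max_iter : iteration cap; local k-means settles in ~10 passes.
    e_tol : stop once the summed center displacement E drops below this.
    """

    nc: int = 1000
    compactness: float = 10.0
    max_iter: int = 10
    e_tol: float = 1.0

    def validate(self) -> "SuperpixelConfig":
        if self.nc < 1:
            raise ConfigError(f"nc must be >= 1, got {self.nc}")
        if self.compactness <= 0:
            raise ConfigError(f"compactness must be > 0, got {self.compactness}")
        if self.max_iter < 1:
            raise ConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.e_tol < 0:
            raise ConfigError(f"e_tol must be >= 0, got {self.e_tol}")
        return self


@dataclass
class SuperpixelResult:
    """labels : (H, W) integer label image with values in [1, nc_actual];
    centers : (nc_actual, 5) array of per-cluster mean [R, G, B, X, Y]
    (X = column, Y = row); nc_actual : actual cluster count."""

    labels: np.ndarray
    centers: np.ndarray
    nc_actual: int


def _features(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return img, xx, yy


def init_centers(img: np.ndarray, nc: int) -> tuple[np.ndarray, float]:
    """Seed cluster centers on a regular grid.

    The grid spacing is ``S = sqrt(np / nc)``; centers sit at the grid
    intersections and take the (R, G, B) of the pixel underneath.  At most
    ``nc`` centers are produced.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    n_pixels = h * w
    if nc > n_pixels:
        raise ConfigError(f"nc={nc} exceeds the pixel count {n_pixels}")
    s = float(np.sqrt(n_pixels / nc))
    nx = max(1, int(w // s))
    ny = max(1, int(h // s))
    xs = (np.arange(nx) + 0.5) * (w / nx)
    ys = (np.arange(ny) + 0.5) * (h / ny)
    centers = np.empty((ny * nx, 5))
    i = 0
    for cy in ys:
        for cx in xs:
            px = img[int(cy), int(cx)].astype(np.float64)
            centers[i] = [px[0], px[1], px[2], cx, cy]
            i += 1
    return centers, s


def assign_pixels(
    img: np.ndarray, centers: np.ndarray, s: float, compactness: float
) -> np.ndarray:
    """Assign every pixel to its best center under ``Dm = dRGB + (p/S) dXY``.

    Each center only competes for pixels inside its 2S x 2S window; the
    rare pixel covered by no window falls back to a global nearest-center
    search.  Returns 0-based labels.
    """
    rgb, xx, yy = _features(img)
    h, w = rgb.shape[:2]
    best = np.full((h, w), np.inf)
    labels = np.full((h, w), -1, dtype=np.int64)
    ratio = compactness / s
    for j, (r, g, b, cx, cy) in enumerate(centers):
        y0, y1 = max(0, int(cy - s)), min(h, int(np.ceil(cy + s)) + 1)
        x0, x1 = max(0, int(cx - s)), min(w, int(np.ceil(cx + s)) + 1)
        sub = rgb[y0:y1, x0:x1]
        drgb = np.sqrt(
            (sub[..., 0] - r) ** 2 + (sub[..., 1] - g) ** 2 + (sub[..., 2] - b) ** 2
        )
        dxy = np.sqrt((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2)
        dm = drgb + ratio * dxy
        win = dm < best[y0:y1, x0:x1]
        best[y0:y1, x0:x1][win] = dm[win]
        labels[y0:y1, x0:x1][win] = j
    orphan = labels < 0
    if np.any(orphan):
        ys_o, xs_o = np.nonzero(orphan)
        pts_rgb = rgb[ys_o, xs_o]
        for j, (r, g, b, cx, cy) in enumerate(centers):
            drgb = np.sqrt(((pts_rgb - [r, g, b]) ** 2).sum(axis=1))
            dxy = np.sqrt((xs_o - cx) ** 2 + (ys_o - cy) ** 2)
            dm = drgb + ratio * dxy
            win = dm < best[ys_o, xs_o]
            best[ys_o[win], xs_o[win]] = dm[win]
            labels[ys_o[win], xs_o[win]] = j
    return labels


def update_centers(
    img: np.ndarray, labels: np.ndarray, prev_centers: np.ndarray
) -> tuple[np.ndarray, float]:
    """Move centers to the mean [R, G, B, X, Y] of their members.

    Empty clusters are dropped.  Returns the surviving centers and the
    residual error E: the summed Euclidean displacement between each
    surviving center and its predecessor.
    """
    rgb, xx, yy = _features(img)
    flat = labels.ravel()
    n = len(prev_centers)
    counts = np.bincount(flat, minlength=n).astype(np.float64)
    feats = np.stack(
        [rgb[..., 0].ravel(), rgb[..., 1].ravel(), rgb[..., 2].ravel(), xx.ravel(), yy.ravel()],
        axis=1,
    )
    sums = np.zeros((n, 5))
    np.add.at(sums, flat, feats)
    alive = counts > 0
    new = sums[alive] / counts[alive, None]
    e = float(np.linalg.norm(new - prev_centers[alive], axis=1).sum())
    return new, e


def run_superpixel(img: np.ndarray, cfg: SuperpixelConfig | None = None) -> SuperpixelResult:
    """Iterate assignment and center updates to convergence.

    On exit the labels are relabeled to the contiguous range [1, nc'] and
    the reported centers are the exact means of their member pixels.
    """
    cfg = (cfg or SuperpixelConfig()).validate()
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    centers, s = init_centers(img, cfg.nc)
    labels = assign_pixels(img, centers, s, cfg.compactness)
    for _ in range(cfg.max_iter):
        new_centers, e = update_centers(img, labels, centers)
        centers = new_centers
        labels = assign_pixels(img, centers, s, cfg.compactness)
        if e <= cfg.e_tol:
            break
    # final labels come from the final centers; recompute means so that each
    # reported center is exactly the mean of its members
    centers, _ = update_centers(img, labels, centers)
    used = np.unique(labels)
    remap = np.zeros(used.max() + 1, dtype=np.int64)
    remap[used] = np.arange(1, len(used) + 1)
    return SuperpixelResult(labels=remap[labels], centers=centers, nc_actual=len(used))


def refine_clusters(sp: SuperpixelResult, ipre: np.ndarray, t1: int) -> np.ndarray:
    """Threshold-guided refinement: keep whole clusters whose mean
    pre-processed intensity falls below ``t1`` (the dark side of the swarm
    threshold), discard the rest.  Returns the binary map Ithresh."""
    ipre = np.asarray(ipre)
    if ipre.shape != sp.labels.shape:
        raise InvalidInputError(
            f"label map shape {sp.labels.shape} does not match image shape {ipre.shape}"
        )
    if not 0 <= t1 <= 256:
        raise InvalidInputError(f"t1 must lie in [0, 256], got {t1}")
    flat = sp.labels.ravel()
    counts = np.bincount(flat, minlength=sp.nc_actual + 1)
    sums = np.bincount(flat, weights=ipre.ravel().astype(np.float64), minlength=sp.nc_actual + 1)
    means = np.divide(sums, counts, out=np.full_like(sums, np.inf), where=counts > 0)
    keep = means < t1
    keep[0] = False  # label 0 unused
    return keep[sp.labels]
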