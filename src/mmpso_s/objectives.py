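"""Multilevel-thresholding objective functions.

Given a 256-bin intensity histogram with probabilities ``P_i = n_i / n_p``,
``k`` thresholds ``t_1 < ... < t_k`` split the gray range into ``k+1``
regions, where region ``r`` covers the levels ``[t_{r-1}, t_r - 1]`` with
``t_0 = 0`` and the last region ending at 255.  Three criteria are computed
per threshold vector, all to be *maximized*:

* ``f1`` — Otsu's between-class variance ``sum_r w_r (mu_r - mu_T)^2``;
* ``f2`` — Kapur's entropy, the sum of Shannon entropies of the per-region
  normalized distributions;
* ``f3`` — Renyi's entropy of order ``alpha``, the one-parameter
  generalization that recovers Kapur's criterion as ``alpha -> 1``.

A region with zero probability mass contributes 0 to every criterion (and
its mean is defined as 0), so the search space is total even for
degenerate threshold vectors.

All functions accept a raw 256-bin count histogram (see :func:`histogram`).
:class:`ObjectiveTables` precomputes the cumulative sums that make a single
evaluation O(k), which the swarm engine relies on.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "N_LEVELS",
    "histogram",
    "region_stats",
    "otsu_objective",
    "kapur_objective",
    "renyi_objective",
    "evaluate_all",
    "ObjectiveTables",
    "OBJECTIVE_NAMES",
]

N_LEVELS = 256

#: canonical objective order: (f1, f2, f3)
OBJECTIVE_NAMES = ("otsu", "kapur", "renyi")


def histogram(img: np.ndarray) -> np.ndarray:
    """256-bin count histogram of an 8-bit grayscale image.

    Bin ``i`` counts the pixels of exact intensity ``i``; the counts sum
    to the pixel count.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("cannot histogram an empty image")
    return np.bincount(img.astype(np.int64).ravel(), minlength=N_LEVELS)[:N_LEVELS]


def _check_hist(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (N_LEVELS,):
        raise InvalidInputError(f"histogram must have exactly {N_LEVELS} bins, got {counts.shape}")
    if counts.sum() <= 0:
        raise InvalidInputError("histogram is empty")
    return counts


def _check_thresholds(tv) -> np.ndarray:
    tv = np.atleast_1d(np.asarray(tv, dtype=np.int64))
    if tv.ndim != 1 or tv.size < 1:
        raise InvalidInputError("threshold vector must contain at least one threshold")
    if np.any(np.diff(tv) <= 0):
        raise InvalidInputError(f"thresholds must be strictly increasing, got {tv.tolist()}")
    if tv[0] < 1 or tv[-1] > 255:
        raise InvalidInputError(f"thresholds must lie in [1, 255], got {tv.tolist()}")
    return tv


class ObjectiveTables:
    """Cumulative-sum tables over a histogram for O(k) objective evaluation.

    Parameters
    ----------
    counts : 256 histogram counts.
    alpha : Renyi order; must be positive and different from 1.
    """

    def __init__(self, counts: np.ndarray, alpha: float = 2.0):
        counts = _check_hist(counts)
        if alpha <= 0:
            raise ConfigError(f"Renyi alpha must be > 0, got {alpha}")
        if alpha == 1.0:
            raise ConfigError("Renyi alpha == 1 reduces to Kapur's entropy; use kapur_objective")
        self.alpha = float(alpha)
        p = counts / counts.sum()
        self.p = p
        levels = np.arange(N_LEVELS, dtype=np.float64)
        # cum_*[t] holds the sum over levels i < t (length 257).
        self.cum_p = np.concatenate(([0.0], np.cumsum(p)))
        self.cum_ip = np.concatenate(([0.0], np.cumsum(levels * p)))
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        self.cum_plogp = np.concatenate(([0.0], np.cumsum(plogp)))
        self.cum_pa = np.concatenate(([0.0], np.cumsum(p**self.alpha)))
        self.mu_t = self.cum_ip[-1]
        self.global_variance = float(np.sum(p * (levels - self.mu_t) ** 2))

    def _edges(self, tvs: np.ndarray) -> np.ndarray:
        """Region edges [0, t1, ..., tk, 256] for a (N, k) batch."""
        n = tvs.shape[0]
        return np.hstack(
            [np.zeros((n, 1), dtype=np.int64), tvs, np.full((n, 1), N_LEVELS, dtype=np.int64)]
        )

    def evaluate_batch(self, tvs: np.ndarray, which=OBJECTIVE_NAMES) -> np.ndarray:
        """Evaluate objectives for a batch of integer threshold vectors.

        Parameters
        ----------
        tvs : (N, k) array of integer thresholds; rows need not be strictly
            increasing (equal consecutive thresholds just create empty
            regions, which score 0).
        which : subset of ``OBJECTIVE_NAMES`` selecting the active
            objectives, in canonical (f1, f2, f3) order.

        Returns
        -------
        (N, len(which)) array of fitness values.
        """
        tvs = np.asarray(tvs, dtype=np.int64)
        if tvs.ndim == 1:
            tvs = tvs[None, :]
        edges = self._edges(np.clip(tvs, 0, N_LEVELS))
        n, m = tvs.shape[0], len(which)
        out = np.zeros((n, m))
        for r in range(edges.shape[1] - 1):
            a, b = edges[:, r], edges[:, r + 1]
            b = np.maximum(a, b)  # tolerate unsorted rows: empty region
            w = self.cum_p[b] - self.cum_p[a]
            nonempty = w > 0
            wsafe = np.where(nonempty, w, 1.0)
            col = 0
            if "otsu" in which:
                mu = (self.cum_ip[b] - self.cum_ip[a]) / wsafe
                out[:, col] += np.where(nonempty, w * (mu - self.mu_t) ** 2, 0.0)
                col += 1
            if "kapur" in which:
                s = self.cum_plogp[b] - self.cum_plogp[a]
                out[:, col] += np.where(nonempty, -s / wsafe + np.log(wsafe), 0.0)
                col += 1
            if "renyi" in which:
                sa = self.cum_pa[b] - self.cum_pa[a]
                sa = np.where(nonempty & (sa > 0), sa, 1.0)
                out[:, col] += np.where(
                    nonempty,
                    (np.log(sa) - self.alpha * np.log(wsafe)) / (1.0 - self.alpha),
                    0.0,
                )
                col += 1
        return out


def region_stats(counts: np.ndarray, tv) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-region probability masses and means.

    Returns
    -------
    omegas : (k+1,) region probability masses, summing to 1.
    mus : (k+1,) region mean intensities (0 for an empty region).
    mu_t : global mean intensity; satisfies ``sum(omegas * mus) == mu_t``
        when every region is non-empty.
    """
    counts = _check_hist(counts)
    tv = _check_thresholds(tv)
    p = counts / counts.sum()
    levels = np.arange(N_LEVELS, dtype=np.float64)
    edges = np.concatenate(([0], tv, [N_LEVELS]))
    omegas = np.empty(len(edges) - 1)
    mus = np.empty(len(edges) - 1)
    for r in range(len(edges) - 1):
        sl = slice(edges[r], edges[r + 1])
        w = p[sl].sum()
        omegas[r] = w
        mus[r] = (levels[sl] * p[sl]).sum() / w if w > 0 else 0.0
    return omegas, mus, float((levels * p).sum())


def otsu_objective(counts: np.ndarray, tv) -> float:
    """Otsu between-class variance ``f1`` of a threshold vector."""
    counts = _check_hist(counts)
    tv = _check_thresholds(tv)
    omegas, mus, mu_t = region_stats(counts, tv)
    mask = omegas > 0
    return float(np.sum(omegas[mask] * (mus[mask] - mu_t) ** 2))


def kapur_objective(counts: np.ndarray, tv) -> float:
    """Kapur between-class entropy ``f2`` of a threshold vector."""
    counts = _check_hist(counts)
    tv = _check_thresholds(tv)
    p = counts / counts.sum()
    edges = np.concatenate(([0], tv, [N_LEVELS]))
    total = 0.0
    for r in range(len(edges) - 1):
        pr = p[edges[r] : edges[r + 1]]
        w = pr.sum()
        if w <= 0:
            continue
        q = pr[pr > 0] / w
        total += float(-(q * np.log(q)).sum())
    return total


def renyi_objective(counts: np.ndarray, tv, alpha: float = 2.0) -> float:
    """Renyi entropy ``f3`` of order ``alpha`` of a threshold vector."""
    counts = _check_hist(counts)
    tv = _check_thresholds(tv)
    if alpha <= 0:
        raise ConfigError(f"Renyi alpha must be > 0, got {alpha}")
    if alpha == 1.0:
        raise ConfigError("Renyi alpha == 1 reduces to Kapur's entropy; use kapur_objective")
    p = counts / counts.sum()
    edges = np.concatenate(([0], tv, [N_LEVELS]))
    total = 0.0
    for r in range(len(edges) - 1):
        pr = p[edges[r] : edges[r + 1]]
        w = pr.sum()
        if w <= 0:
            continue
        q = pr[pr > 0] / w
        total += float(np.log((q**alpha).sum()) / (1.0 - alpha))
    return total


def evaluate_all(counts: np.ndarray, tv, alpha: float = 2.0) -> np.ndarray:
    """Fitness vector ``(f1, f2, f3)`` for one threshold vector."""
    return np.array(
        [
            otsu_objective(counts, tv),
            kapur_objective(counts, tv),
            renyi_objective(counts, tv, alpha=alpha),
        ]
    )
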