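"""Histogram construction and multilevel thresholding objectives.

Multilevel thresholding partitions the intensity range [0, L) of a grayscale
image with ``m`` ordered cut-points ``TH = [th_1, ..., th_m]`` into ``m + 1``
classes.  Throughout this package classes are the half-open intensity bins

    [0, th_1), [th_1, th_2), ..., [th_m, L)

so every intensity belongs to exactly one class and a pixel equal to a
threshold falls in the class *above* it.

Two criteria are provided:

* Otsu's between-class variance ``sigma_B^2 = sum_i w_i (mu_i - mu_T)^2``,
  maximised when the cut-points separate the histogram modes.
* Kapur's entropy criterion, the sum of Shannon entropies (nats) of the
  per-class conditional intensity distributions.

An exhaustive brute-force search over all threshold vectors is included as
the correctness anchor for the stochastic optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "NormalizedHistogram",
    "ClassStats",
    "compute_histogram",
    "class_stats",
    "otsu_objective",
    "kapur_objective",
    "exhaustive_optimal_thresholds",
    "load_histogram_txt",
    "save_histogram_txt",
]

_MAX_EXHAUSTIVE_COMBINATIONS = 10**7


@dataclass(frozen=True)
class NormalizedHistogram:
    """Per-intensity probability distribution of a grayscale image.

    Attributes
    ----------
    probs : ndarray, shape (L,)
        ``counts / total``; sums to 1 when ``total > 0``.
    counts : ndarray, shape (L,)
        Raw pixel counts per intensity level.
    L : int
        Number of intensity levels (256 for 8-bit images).
    total : int
        Total number of pixels counted.
    """

    probs: np.ndarray
    counts: np.ndarray
    L: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("no pixels to histogram")
        if len(self.probs) != self.L or len(self.counts) != self.L:
            raise ValueError("histogram length does not match L")


@dataclass(frozen=True)
class ClassStats:
    """Per-class weights/means for a threshold vector, plus global stats."""

    weights: np.ndarray
    means: np.ndarray
    global_mean: float
    between_class_variance: float


def compute_histogram(image, mask=None, L: int = 256) -> NormalizedHistogram:
    """Tally the normalized intensity histogram of ``image``.

    Parameters
    ----------
    image : array-like of int
        2-D intensity grid with values in ``[0, L - 1]``.
    mask : array-like of bool, optional
        Only pixels where the mask is true are counted.
    L : int
        Number of intensity levels.
    """
    arr = np.asarray(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError("mask shape does not match image shape")
        values = arr[mask]
    else:
        values = arr.ravel()
    if values.size == 0:
        raise ValueError("no pixels to histogram")
    values = values.astype(np.int64, copy=False)
    if values.min() < 0 or values.max() >= L:
        raise ValueError(f"intensity out of range [0, {L - 1}]")
    counts = np.bincount(values, minlength=L).astype(np.int64)
    total = int(counts.sum())
    return NormalizedHistogram(probs=counts / total, counts=counts, L=L, total=total)


def _validate_thresholds(TH, L: int) -> np.ndarray:
    th = np.asarray(TH, dtype=np.int64).ravel()
    if th.size == 0:
        raise ValueError("threshold vector is empty")
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if th[0] < 1 or th[-1] > L - 1:
        raise ValueError(f"thresholds must lie in [1, {L - 1}]")
    return th


def class_stats(hist: NormalizedHistogram, TH) -> ClassStats:
    """Class weights, means and between-class variance for a cut-point vector.

    Empty classes carry weight 0 and (by convention) mean 0; they contribute
    nothing to the variance, which keeps degenerate threshold vectors usable
    by the optimizer.
    """
    th = _validate_thresholds(TH, hist.L)
    edges = np.concatenate(([0], th, [hist.L]))
    p = hist.probs
    levels = np.arange(hist.L, dtype=float)
    cum_p = np.concatenate(([0.0], np.cumsum(p)))
    cum_ip = np.concatenate(([0.0], np.cumsum(levels * p)))
    w = cum_p[edges[1:]] - cum_p[edges[:-1]]
    s = cum_ip[edges[1:]] - cum_ip[edges[:-1]]
    mu_T = float(cum_ip[-1])
    means = np.divide(s, w, out=np.zeros_like(s), where=w > 0)
    sigma_b2 = float(np.sum(w * (means - mu_T) ** 2))
    return ClassStats(weights=w, means=means, global_mean=mu_T,
                      between_class_variance=sigma_b2)


def otsu_objective(hist: NormalizedHistogram, TH) -> float:
    """Between-class variance ``sum_i w_i (mu_i - mu_T)^2`` (intensity^2)."""
    return class_stats(hist, TH).between_class_variance


def kapur_objective(hist: NormalizedHistogram, TH) -> float:
    """Sum of per-class conditional Shannon entropies (nats).

    For each class with mass ``w``, adds ``-sum_i (p_i / w) ln(p_i / w)``
    over the nonzero bins of the class; empty classes contribute 0.
    """
    th = _validate_thresholds(TH, hist.L)
    edges = np.concatenate(([0], th, [hist.L]))
    total = 0.0
    p = hist.probs
    for a, b in zip(edges[:-1], edges[1:]):
        seg = p[a:b]
        w = seg.sum()
        if w <= 0.0:
            continue
        q = seg[seg > 0] / w
        total += float(-np.sum(q * np.log(q)))
    return total


def _objective_fn(name_or_fn):
    if callable(name_or_fn):
        return name_or_fn
    table = {"otsu": otsu_objective, "kapur": kapur_objective}
    try:
        return table[name_or_fn]
    except KeyError:
        raise ValueError(f"unknown objective {name_or_fn!r}; use 'otsu' or 'kapur'")


def exhaustive_optimal_thresholds(hist: NormalizedHistogram, m: int,
                                  objective="otsu"):
    """Globally optimal thresholds by enumerating every candidate vector.

    Enumerates all C(L-1, m) strictly increasing integer vectors in
    ``[1, L-1]`` and returns ``(thresholds, score)`` for the maximum; ties
    are broken to the lexicographically smallest vector.  Refuses problems
    with more than 10^7 combinations — use the EMO optimizer there.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n_comb = comb(hist.L - 1, m)
    if n_comb > _MAX_EXHAUSTIVE_COMBINATIONS:
        raise ValueError(
            f"{n_comb} threshold combinations exceed the exhaustive-search "
            "guard; use the EMO optimizer instead")
    fn = _objective_fn(objective)
    best_th, best_score = None, -np.inf
    for cand in combinations(range(1, hist.L), m):
        score = fn(hist, cand)
        if score > best_score:  # first hit in lex order wins ties
            best_score = score
            best_th = cand
    return np.asarray(best_th, dtype=np.int64), float(best_score)


def save_histogram_txt(path, hist: NormalizedHistogram) -> None:
    """Write a histogram as two-column plain text (intensity, count)."""
    data = np.column_stack([np.arange(hist.L), hist.counts])
    np.savetxt(path, data, fmt="%d")


def load_histogram_txt(path) -> NormalizedHistogram:
    """Read a two-column (intensity, count) text file into a histogram."""
    data = np.loadtxt(path, dtype=np.int64, ndmin=2)
    levels, counts_in = data[:, 0], data[:, 1]
    L = int(levels.max()) + 1
    counts = np.zeros(L, dtype=np.int64)
    counts[levels] = counts_in
    total = int(counts.sum())
    return NormalizedHistogram(probs=counts / total, counts=counts, L=L,
                               total=total)
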