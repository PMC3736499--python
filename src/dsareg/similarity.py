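"""Similarity measures for template matching.

The registration pipeline uses ENT — the entropy of the normalized
histogram of the pixelwise difference between two patches.  ENT is zero
exactly when the difference is constant, so it is invariant to mean
gray-level offsets between mask and live frames, and it degrades
gracefully when part of a patch is dissimilar (e.g. a contrast-filled
vessel present in only one frame): the dissimilar pixels form an extra
histogram mode instead of corrupting patch moments.

EHD (energy of the same histogram), Pearson correlation (CC), mutual
information (MI) and SSIM are provided for the measure-comparison
harness.  Each measure has a fixed polarity; :func:`cost` converts any of
them into a minimization objective for the matcher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "DifferenceHistogram",
    "MEASURES",
    "POLARITY",
    "diff_histogram",
    "ent",
    "ehd",
    "cc",
    "mi",
    "ssim",
    "score",
    "cost",
]

#: polarity per measure: "min" = smaller is better, "max" = larger is better
POLARITY = {"ent": "min", "ehd": "max", "cc": "max", "mi": "max", "ssim": "max"}
MEASURES = tuple(POLARITY)


@dataclass
class DifferenceHistogram:
    """Normalized histogram of a pixelwise difference patch.

    ``bin_edges`` are the histogram edges covering [-255.5, 255.5] (for
    unit-width bins each bin is centered on an integer difference);
    ``probabilities`` sum to 1; ``n`` is the pixel count.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n: int


def diff_histogram(a, b, bin_width: int = 1) -> DifferenceHistogram:
    """Histogram of ``a - b`` over [-255, 255], normalized to probabilities.

    Unit bins are lossless for 8-bit data; float differences are rounded to
    the nearest gray level and clipped into range.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    d = np.clip(np.rint(a - b).astype(np.int64), -255, 255) + 255
    counts = np.bincount(d.ravel(), minlength=511)
    if bin_width > 1:
        nbins = -(-511 // bin_width)
        pad = np.zeros(nbins * bin_width)
        pad[:511] = counts
        counts = pad.reshape(nbins, bin_width).sum(axis=1)
    edges = -255.5 + bin_width * np.arange(len(counts) + 1)
    n = a.size
    return DifferenceHistogram(edges, counts / n, n)


def _probs(h) -> np.ndarray:
    if isinstance(h, DifferenceHistogram):
        return h.probabilities
    return np.asarray(h, dtype=np.float64)


def ent(h) -> float:
    """Entropy of the difference histogram in bits; 0 iff one bin holds all mass."""
    p = _probs(h)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def ehd(h) -> float:
    """Energy (sum of squared probabilities) of the difference histogram."""
    p = _probs(h)
    return float(np.sum(p * p))


def cc(a, b) -> float:
    """Pearson correlation coefficient of the flattened intensities."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a constant patch")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def mi(a, b, n_bins: int = 32) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Intensities are binned into ``n_bins`` equal-width bins spanning
    [0, 255].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    rng = ((-0.5, 255.5), (-0.5, 255.5))
    joint, _, _ = np.histogram2d(np.clip(a, 0, 255), np.clip(b, 0, 255), bins=n_bins, range=rng)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def ssim(a, b) -> float:
    """Mean single-scale SSIM with the conventional constants for L = 255.

    Uses an 11-tap Gaussian weighting window (sigma = 1.5).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a, b, data_range=255.0, gaussian_weights=True, sigma=1.5, use_sample_covariance=False
        )
    )


def score(measure: str, a, b, *, bin_width: int = 1, mi_bins: int = 32) -> float:
    """Raw similarity value of ``measure`` between two equally-shaped patches."""
    m = measure.lower()
    if m == "ent":
        return ent(diff_histogram(a, b, bin_width))
    if m == "ehd":
        return ehd(diff_histogram(a, b, bin_width))
    if m == "cc":
        return cc(a, b)
    if m == "mi":
        return mi(a, b, mi_bins)
    if m == "ssim":
        return ssim(a, b)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def cost(measure: str, a, b, **kw) -> float:
    """Polarity-adjusted score: always to be minimized."""
    v = score(measure, a, b, **kw)
    return v if POLARITY[measure.lower()] == "min" else -v
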