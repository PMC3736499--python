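"""Hybrid edge / Harris-corner control-point selection on the live image.

Motion artifacts in subtraction angiography appear where strong edges of
the mask and live frames fail to coincide, so control points are taken
from strong edges; Harris corners add locally unique neighborhoods that
match more reliably than points on a straight edge.  The two cues are
fused into a single saliency map ``Rhat = alpha*G + beta*R`` from which
well-separated local maxima are selected greedily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageio import as_gray_image, normalize01

__all__ = [
    "SelectionParams",
    "ControlPointSet",
    "gradient_magnitude",
    "threshold_edges",
    "harris_response",
    "combine_maps",
    "find_candidates",
    "select_control_points",
    "select_from_image",
]


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the control-point selector.

    sigma : Gaussian-derivative scale of the edge filter (px).
    k : Harris sensitivity.
    sigma_w : scale of the circular Gaussian window of the Harris
        second-moment products (px).
    alpha, beta : fusion weights of the edge and corner maps (sum to 1).
    t1 : candidate threshold on the fused map.
    r : non-maximum-suppression radius (px, Euclidean).
    d_min : minimum distance between selected control points (px).
    border_margin : candidates closer than this to any image border are
        discarded, so every selected point admits a full matching template
        plus the full displacement search range.
    """

    sigma: float = 1.0
    k: float = 0.12
    sigma_w: float = 2.0
    alpha: float = 0.3
    beta: float = 0.7
    t1: float = 0.1
    r: float = 5.0
    d_min: float = 25.0
    border_margin: int = 45

    def __post_init__(self):
        if not np.isclose(self.alpha + self.beta, 1.0):
            raise ValueError("alpha + beta must equal 1")
        if not 0.0 < self.t1 < 1.0:
            raise ValueError("t1 must lie in (0, 1)")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")


@dataclass
class ControlPointSet:
    """Selected feature points, ordered by descending saliency score.

    ``points`` is an ``(n, 2)`` array of ``(x, y)`` pixel coordinates;
    ``scores`` the fused-map value at each point.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        if len(self.points) != len(self.scores):
            raise ValueError("points and scores must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def _gaussian_derivatives(img, sigma):
    ix = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    iy = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    return ix, iy


def gradient_magnitude(img, sigma: float = 1.0, normalize: bool = True) -> np.ndarray:
    """Gaussian-derivative gradient magnitude, normalized onto [0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = as_gray_image(img)
    ix, iy = _gaussian_derivatives(img, sigma)
    mag = np.hypot(ix, iy)
    return normalize01(mag) if normalize else mag


def threshold_edges(gradmap, t0: float | None = None) -> np.ndarray:
    """Zero out weak-gradient pixels; keep strong edges unchanged.

    ``t0`` defaults to the mean of the (normalized) gradient map.
    """
    gradmap = as_gray_image(gradmap)
    if t0 is None:
        t0 = float(gradmap.mean())
    out = gradmap.copy()
    out[out < t0] = 0.0
    return out


def harris_response(img, k: float = 0.12, sigma: float = 1.0, sigma_w: float = 2.0) -> np.ndarray:
    """Harris corner response, negatives clipped and positives mapped to [0, 1].

    The response is ``det - k * trace**2`` of the second-moment matrix whose
    entries are the derivative products ``Ix*Ix``, ``Iy*Iy``, ``Ix*Iy``
    smoothed by a circular Gaussian window of scale ``sigma_w`` (truncated
    at 3 sigma).  Derivatives reuse the same Gaussian-derivative filters as
    the edge map.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    img = as_gray_image(img)
    ix, iy = _gaussian_derivatives(img, sigma)
    win = dict(sigma=sigma_w, mode="nearest", truncate=3.0)
    ixx = ndimage.gaussian_filter(ix * ix, **win)
    iyy = ndimage.gaussian_filter(iy * iy, **win)
    ixy = ndimage.gaussian_filter(ix * iy, **win)
    r = ixx * iyy - ixy * ixy - k * (ixx + iyy) ** 2
    np.clip(r, 0.0, None, out=r)
    return normalize01(r)


def combine_maps(g, r, alpha: float = 0.3, beta: float = 0.7) -> np.ndarray:
    """Fused saliency map ``alpha*G + beta*R``."""
    g = as_gray_image(g)
    r = as_gray_image(r)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    return alpha * g + beta * r


def _disk_offsets(radius: float):
    n = int(np.floor(radius))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    keep = (dx * dx + dy * dy <= radius * radius) & ~((dx == 0) & (dy == 0))
    return dx[keep], dy[keep]


def find_candidates(rhat, t1: float = 0.1, r: float = 5.0):
    """Local maxima of the fused map above ``t1``, sorted by descending value.

    A pixel is a candidate iff its value exceeds ``t1``, is maximal over
    the circular (Euclidean) neighborhood of radius ``r``, and strictly
    exceeds at least one neighbor (an entirely flat neighborhood holds no
    maximum, so constant regions yield nothing).  Within a tie plateau
    only the lexicographically first pixel by ``(y, x)`` survives.
    Returns ``(points, scores)`` with points as ``(x, y)`` rows.
    """
    rhat = as_gray_image(rhat)
    if not (0.0 < t1 < 1.0):
        raise ValueError("t1 must lie in (0, 1)")
    h, w = rhat.shape
    n = int(np.floor(r))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    foot = dx * dx + dy * dy <= r * r
    local_max = ndimage.maximum_filter(rhat, footprint=foot, mode="nearest")
    ys, xs = np.nonzero((rhat > t1) & (rhat == local_max))
    if len(ys) == 0:
        return np.empty((0, 2)), np.empty(0)
    odx, ody = _disk_offsets(r)
    keep_pts, keep_scores = [], []
    for y, x in zip(ys, xs):
        v = rhat[y, x]
        nx = x + odx
        ny = y + ody
        inside = (nx >= 0) & (nx < w) & (ny >= 0) & (ny < h)
        nx, ny = nx[inside], ny[inside]
        vals = rhat[ny, nx]
        if not np.any(vals < v):  # fully flat neighborhood: no maximum here
            continue
        tied = vals == v
        # drop this pixel if an equal-valued neighbor precedes it in (y, x)
        if np.any(tied & ((ny < y) | ((ny == y) & (nx < x)))):
            continue
        keep_pts.append((x, y))
        keep_scores.append(v)
    if not keep_pts:
        return np.empty((0, 2)), np.empty(0)
    pts = np.asarray(keep_pts, dtype=np.float64)
    scores = np.asarray(keep_scores)
    order = np.lexsort((pts[:, 0], pts[:, 1], -scores))
    return pts[order], scores[order]


def select_control_points(points, scores, d_min: float = 25.0) -> ControlPointSet:
    """Greedy minimum-distance thinning of a descending-sorted candidate list.

    The best remaining candidate is accepted and every candidate within
    ``d_min`` of it removed, until none remain.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    alive = np.ones(len(points), dtype=bool)
    sel = []
    for i in range(len(points)):
        if not alive[i]:
            continue
        sel.append(i)
        d2 = np.sum((points - points[i]) ** 2, axis=1)
        alive &= d2 >= d_min * d_min
        alive[i] = False
    return ControlPointSet(points[sel], scores[sel])


def select_from_image(img, params: SelectionParams | None = None) -> ControlPointSet:
    """Full selection chain: edges -> Harris -> fuse -> NMS -> greedy thinning.

    Candidates within ``border_margin`` of any image edge are discarded
    before the greedy stage.
    """
    params = params or SelectionParams()
    img = as_gray_image(img)
    h, w = img.shape
    if w <= 2 * params.border_margin or h <= 2 * params.border_margin:
        raise ValueError("image too small for the configured border margin")
    g = threshold_edges(gradient_magnitude(img, params.sigma))
    r = harris_response(img, params.k, params.sigma, params.sigma_w)
    rhat = combine_maps(g, r, params.alpha, params.beta)
    pts, scores = find_candidates(rhat, params.t1, params.r)
    if len(pts):
        m = params.border_margin
        inb = (pts[:, 0] >= m) & (pts[:, 0] <= w - 1 - m) & (pts[:, 1] >= m) & (pts[:, 1] <= h - 1 - m)
        pts, scores = pts[inb], scores[inb]
    return select_control_points(pts, scores, params.d_min)
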