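"""Synthetic coronary angiogram phantoms and simulated registration pairs.

No public angiographic data sets with ground-truth correspondences
exist, so quantitative evaluation runs on phantoms that emulate the
structures the registration pipeline interacts with: a smooth
soft-tissue background, a few high-contrast rib/diaphragm-like bands
(the strong edges feature selection relies on), a dark branching vessel
tree of bounded width, and mild additive Gaussian noise.  A cine
sequence adds sub-pixel background jitter, small frame-to-frame gain
fluctuations and a vessel-contrast inflow ramp, which is what the
temporal-maximum mask synthesis exploits.

Simulated pairs apply a known elastic warp — drawn from the same
multilevel B-spline family the registration estimates — to a phantom
live frame, so every correspondence is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .imageio import as_gray_image
from .mbspline import DisplacementField, build_displacement_field, warp_image

__all__ = [
    "PhantomParams",
    "PhantomScene",
    "SimulatedPair",
    "gen_phantom",
    "make_mask_from_sequence",
    "simulate_pair",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings.

    Vessel contrast and band amplitudes are in gray levels; the maximum
    rendered vessel width must stay below the enhancement ball diameter.
    """

    size: tuple = (512, 512)  # (width, height)
    base_intensity: float = 165.0
    smooth_amplitude: float = 12.0
    smooth_scale: float = 45.0
    texture_amplitude: float = 24.0
    texture_scale: float = 2.0
    n_bands: tuple = (2, 4)  # min/max rib-like bands
    band_amplitude: tuple = (12.0, 20.0)
    max_vessel_width: float = 10.0
    vessel_contrast: float = 45.0
    noise_sigma: float = 2.0
    n_frames: int = 30
    inflow_start: int = 10  # last frame index with zero vessel contrast
    full_contrast_frame: int = 15
    live_frame: int = 15
    jitter_px: float = 0.3
    gain_jitter: float = 1.5


@dataclass
class PhantomScene:
    """A generated scene: noiseless background, vessel mask, live frame, cine."""

    background: np.ndarray
    vessel_mask: np.ndarray
    live: np.ndarray
    frames: np.ndarray  # (K, H, W)
    max_vessel_width: float
    seed: int
    params: PhantomParams = dc_field(default_factory=PhantomParams)


@dataclass
class SimulatedPair:
    """A live frame, its elastically warped version and the known ground truth."""

    live: np.ndarray
    sim_live: np.ndarray
    true_points: np.ndarray  # (n, 2) live coordinates p_i
    shifts: np.ndarray  # (n, 2) displacements d_i; mask correspondence q_i = p_i + d_i
    true_field: DisplacementField
    seed: int

    @property
    def shifted_points(self) -> np.ndarray:
        return self.true_points + self.shifts


def _smooth_field(shape, scale, amplitude, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="nearest")
    peak = np.abs(f).max()
    return f * (amplitude / peak) if peak > 0 else f


def _texture_field(shape, scale, amplitude, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="nearest")
    return f * (amplitude / f.std())


def _rib_bands(shape, params, rng):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    out = np.zeros(shape)
    lo, hi = params.n_bands
    for _ in range(rng.integers(lo, hi + 1)):
        theta = rng.uniform(0, np.pi)
        u = np.cos(theta) * xx + np.sin(theta) * yy
        v = -np.sin(theta) * xx + np.cos(theta) * yy
        u = u + rng.uniform(-2e-3, 2e-3) * (v - v.mean()) ** 2  # slight curvature
        c = rng.uniform(u.min(), u.max())
        width = rng.uniform(20.0, 40.0)
        amp = rng.uniform(*params.band_amplitude) * rng.choice([-1.0, 1.0])
        # flat-top profile: sharp blurred flanks give strong, localizable edges
        out += amp * np.exp(-(((u - c) / width) ** 4))
    # diaphragm-like circular step entering from a corner
    cx, cy = rng.uniform(-0.4, 0.0, 2) * np.array([w, h])
    radius = rng.uniform(0.7, 1.1) * min(w, h)
    rho = np.hypot(xx - cx, yy - cy)
    out += rng.uniform(12.0, 20.0) * rng.choice([-1.0, 1.0]) / (1.0 + np.exp(-(rho - radius) / 3.0))
    return ndimage.gaussian_filter(out, 1.5, mode="nearest")


def _stamp(depth, x, y, radius):
    h, w = depth.shape
    r = int(np.ceil(radius))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    rho2 = ((xx - x) ** 2 + (yy - y) ** 2) / (radius * radius)
    prof = np.sqrt(np.clip(1.0 - rho2, 0.0, None))
    np.maximum(depth[y0:y1, x0:x1], prof, out=depth[y0:y1, x0:x1])


def _vessel_depth(shape, max_width, rng):
    """Recursive branching random walk rendered as a rounded depth profile.

    Depth is 1 on centerlines, falling to 0 at the lumen edge; every
    stamped disc radius stays <= max_width / 2.
    """
    h, w = shape
    depth = np.zeros(shape)
    stack = []
    for _ in range(2):  # two epicardial-artery-like roots
        if rng.random() < 0.5:
            x, y = rng.uniform(0.1, 0.9) * w, 0.0
            ang = np.pi / 2 + rng.uniform(-0.5, 0.5)
        else:
            x, y = 0.0, rng.uniform(0.1, 0.9) * h
            ang = rng.uniform(-0.5, 0.5)
        stack.append((x, y, ang, max_width * rng.uniform(0.8, 1.0)))
    steps = 0
    while stack and steps < 40000:
        x, y, ang, wd = stack.pop()
        while wd >= 2.0 and 0 <= x < w and 0 <= y < h:
            steps += 1
            if steps >= 40000:
                break
            _stamp(depth, x, y, wd / 2.0)
            ang += rng.normal(0.0, 0.08)
            x += 2.0 * np.cos(ang)
            y += 2.0 * np.sin(ang)
            wd *= 0.998
            if wd > 3.0 and rng.random() < 0.02:
                branch_ang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9)
                stack.append((x, y, branch_ang, wd * 0.75))
                wd *= 0.9
    return depth


def gen_phantom(params: PhantomParams | None = None, seed: int = 0) -> PhantomScene:
    """Generate a deterministic phantom scene from ``seed``.

    The live frame is the full-contrast cine frame with no jitter or gain
    offset, so it is directly comparable to ``background``.
    """
    params = params or PhantomParams()
    w, h = params.size
    if w < 8 or h < 8:
        raise ValueError(f"invalid phantom dimensions {params.size}")
    rng = np.random.default_rng(seed)
    shape = (h, w)
    background = (
        params.base_intensity
        + _smooth_field(shape, params.smooth_scale, params.smooth_amplitude, rng)
        + _rib_bands(shape, params, rng)
        # fine parenchymal/trabecular texture: locally unique neighborhoods
        # everywhere, as in clinical frames
        + _texture_field(shape, params.texture_scale, params.texture_amplitude, rng)
    )
    background = np.clip(background, 40.0, 230.0)
    depth = _vessel_depth(shape, params.max_vessel_width, rng)
    vessel_mask = (depth > 0.2).astype(np.uint8)

    k = params.n_frames
    frames = np.empty((k, h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    live = None
    for t in range(k):
        if t <= params.inflow_start:
            contrast = 0.0
        else:
            ramp = (t - params.inflow_start) / max(params.full_contrast_frame - params.inflow_start, 1)
            contrast = min(ramp, 1.0)
        if t == params.live_frame:
            bg_t, gain = background, 0.0
        else:
            jx, jy = rng.uniform(-params.jitter_px, params.jitter_px, 2)
            bg_t = ndimage.map_coordinates(background, [yy + jy, xx + jx], order=1, mode="nearest")
            gain = rng.uniform(-params.gain_jitter, params.gain_jitter)
        frame = bg_t - contrast * params.vessel_contrast * depth + gain
        frame += rng.normal(0.0, params.noise_sigma, shape)
        frames[t] = np.clip(frame, 0.0, 255.0)
        if t == params.live_frame:
            live = frames[t]
    if live is None:
        live = frames[-1]
    return PhantomScene(background, vessel_mask, live, frames, params.max_vessel_width, seed, params)


def make_mask_from_sequence(frames, vessel_mask, k: int = 15, delta: int = 5) -> np.ndarray:
    """Synthesize a mask frame from a cine sequence and a vessel segmentation.

    Off-vessel pixels copy the live frame ``frames[k]``; vessel pixels take
    the temporal maximum over frames ``k - delta .. k + delta``, which —
    vessels being dark and contrast flowing in — recovers the vessel-free
    background.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be a (K, H, W) stack")
    b = np.asarray(vessel_mask)
    if b.shape != frames.shape[1:]:
        raise ValueError("vessel mask shape must match the frames")
    if k - delta < 0 or k + delta > len(frames) - 1:
        raise ValueError(f"window [{k - delta}, {k + delta}] outside sequence of length {len(frames)}")
    live = frames[k]
    tmax = frames[k - delta : k + delta + 1].max(axis=0)
    return np.where(b == 0, live, tmax)


def simulate_pair(
    live,
    n: int = 30,
    shift_max: float = 10.0,
    seed: int = 0,
    margin: int = 45,
    min_dist: float | None = None,
    h: int = 7,
    s0: float = 512.0,
) -> SimulatedPair:
    """Warp ``live`` by a known random elastic deformation.

    ``n`` well-separated points are drawn with continuous uniform shifts in
    ``[-shift_max, shift_max]`` per axis; the minimum pairwise distance
    (default ``2 * shift_max + 5``) keeps the per-point motion neighborhoods
    from overlapping.  The true field is the multilevel B-spline fit of the
    drawn shifts, so it reproduces them at the points to numerical
    precision, and ``sim_live = warp(live, field)``.
    """
    live = as_gray_image(live)
    ih, iw = live.shape
    if min_dist is None:
        min_dist = 2.0 * shift_max + 5.0
    lo_x, hi_x = margin, iw - 1 - margin
    lo_y, hi_y = margin, ih - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("margin leaves no room for points")
    rng = np.random.default_rng(seed)
    pts: list = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(f"cannot place {n} points at separation {min_dist}; reduce n")
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    points = np.array(pts)
    shifts = rng.uniform(-shift_max, shift_max, (n, 2))
    field = build_displacement_field(points, shifts, (iw, ih), h, s0)
    sim = warp_image(live, field)
    return SimulatedPair(live, sim, points, shifts, field, seed)
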