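"""Multilevel B-spline scattered-data approximation and elastic warping.

A uniform cubic B-spline surface is defined by a control lattice of
coefficients ``phi`` overlaid on the image domain.  The BA fit computes,
for every scattered sample, the 4x4 neighborhood of lattice coefficients
that would reproduce it exactly, and resolves conflicting assignments in
the weighted least-squares sense.  A single lattice trades smoothness
against accuracy, so a coarse-to-fine hierarchy of lattices is used: the
coarsest level fits the raw data and every finer level fits the residual
left by the sum of the previous levels.  With a finest cell spacing well
below the minimum pairwise sample distance the summed surface
interpolates the data to numerical precision.

Two such surfaces (one per displacement component, anchored in
live-image coordinates) form the dense displacement field used for
backward-mapped elastic warping of the mask image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import as_gray_image

__all__ = [
    "bspline_basis",
    "ControlLattice",
    "MultilevelSurface",
    "DisplacementField",
    "ba_fit",
    "eval_surface",
    "mba_fit",
    "build_displacement_field",
    "warp_image",
]


def bspline_basis(t):
    """The four uniform cubic B-spline basis values at fraction ``t`` in [0, 1).

    Returns ``(B0, B1, B2, B3)``; the values always sum to 1.  Accepts
    scalars or arrays.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0) or np.any(t >= 1):
        raise ValueError("t must lie in [0, 1)")
    t2 = t * t
    t3 = t2 * t
    b0 = (1 - t) ** 3 / 6.0
    b1 = (3 * t3 - 6 * t2 + 4) / 6.0
    b2 = (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0
    b3 = t3 / 6.0
    return b0, b1, b2, b3


@dataclass
class ControlLattice:
    """An ``(m+3) x (n+3)`` grid of B-spline coefficients over a pixel domain.

    ``phi[i+1, j+1]`` stores the coefficient with lattice index ``(i, j)``,
    ``i in [-1, m+1]`` along x and ``j in [-1, n+1]`` along y.  ``spacing``
    is the cell size in pixels; the surface domain is
    ``[0, width) x [0, height)``.
    """

    phi: np.ndarray
    spacing: float
    domain: tuple  # (width, height) in px

    @property
    def resolution(self):
        return self.phi.shape[0] - 3, self.phi.shape[1] - 3

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        m, n = self.resolution
        if m < 1 or n < 1:
            raise ValueError("lattice must be at least (1+3) x (1+3)")


def _lattice_units(x, y, spacing, domain):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w, h = domain
    if np.any(x < 0) or np.any(x >= w) or np.any(y < 0) or np.any(y >= h):
        raise ValueError("coordinates outside the surface domain")
    return x / spacing, y / spacing


def _resolution_for(domain, spacing):
    w, h = domain
    return int(np.ceil(w / spacing)), int(np.ceil(h / spacing))


def ba_fit(data, spacing: float, domain) -> ControlLattice:
    """One-level B-spline approximation of scattered samples.

    ``data`` is an ``(ns, 3)`` array of ``(x, y, z)`` samples inside the
    pixel domain.  Each sample assigns values to the 4x4 coefficient
    neighborhood that would reproduce it exactly; coefficients claimed by
    several samples take the weighted least-squares compromise, and
    coefficients touched by no sample are zero.
    """
    data = np.asarray(data, dtype=np.float64).reshape(-1, 3)
    m, n = _resolution_for(domain, spacing)
    phi = np.zeros((m + 3, n + 3))
    if len(data) == 0:
        return ControlLattice(phi, spacing, tuple(domain))
    u, v = _lattice_units(data[:, 0], data[:, 1], spacing, domain)
    z = data[:, 2]
    iu = np.floor(u).astype(np.intp)
    iv = np.floor(v).astype(np.intp)
    bx = np.stack(bspline_basis(u - iu), axis=1)  # (ns, 4)
    by = np.stack(bspline_basis(v - iv), axis=1)
    wkl = bx[:, :, None] * by[:, None, :]  # (ns, 4, 4)
    w2 = wkl * wkl
    s = w2.sum(axis=(1, 2))  # sum of squared weights per sample
    # numerator accumulates w^2 * phi_c with phi_c = w z / s
    num_contrib = w2 * wkl * (z / s)[:, None, None]
    num = np.zeros_like(phi)
    den = np.zeros_like(phi)
    for k in range(4):
        for l in range(4):
            np.add.at(num, (iu + k, iv + l), num_contrib[:, k, l])
            np.add.at(den, (iu + k, iv + l), w2[:, k, l])
    nz = den > 0
    phi[nz] = num[nz] / den[nz]
    return ControlLattice(phi, spacing, tuple(domain))


def eval_surface(lattice: ControlLattice, x, y):
    """Evaluate the B-spline surface at pixel coordinates (scalar or array).

    Tensor-product sum of the 4x4 coefficient neighborhood of each
    location.
    """
    u, v = _lattice_units(x, y, lattice.spacing, lattice.domain)
    scalar = u.ndim == 0
    u, v = np.atleast_1d(u), np.atleast_1d(v)
    iu = np.floor(u).astype(np.intp)
    iv = np.floor(v).astype(np.intp)
    bx = np.stack(bspline_basis(u - iu), axis=1)
    by = np.stack(bspline_basis(v - iv), axis=1)
    out = np.zeros_like(u)
    phi = lattice.phi
    for k in range(4):
        for l in range(4):
            out += bx[:, k] * by[:, l] * phi[iu + k, iv + l]
    return float(out[0]) if scalar else out


@dataclass
class MultilevelSurface:
    """Coarse-to-fine hierarchy of control lattices; the surface is their sum."""

    lattices: list

    @property
    def h(self) -> int:
        return len(self.lattices)

    def __call__(self, x, y):
        vals = eval_surface(self.lattices[0], x, y)
        for lat in self.lattices[1:]:
            vals = vals + eval_surface(lat, x, y)
        return vals


def mba_fit(data, domain, h: int = 7, s0: float = 512.0) -> MultilevelSurface:
    """Multilevel B-spline approximation with ``h`` halving levels.

    The coarsest lattice (cell spacing ``s0`` px) fits the raw samples;
    each subsequent level fits the residuals of the running sum.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    data = np.asarray(data, dtype=np.float64).reshape(-1, 3)
    residual = data.copy()
    lattices = []
    for level in range(h):
        spacing = s0 / (2.0**level)
        lat = ba_fit(residual, spacing, domain)
        lattices.append(lat)
        if len(residual):
            residual[:, 2] -= eval_surface(lat, residual[:, 0], residual[:, 1])
    return MultilevelSurface(lattices)


class DisplacementField:
    """Dense 2-D displacement field built from two multilevel surfaces.

    ``fx`` and ``fy`` map live-image pixel coordinates to the x and y
    displacement components toward the mask image (``q = p + d``).
    """

    def __init__(self, fx: MultilevelSurface, fy: MultilevelSurface, domain):
        self.fx = fx
        self.fy = fy
        self.domain = tuple(domain)
        self._dense = None

    def __call__(self, x, y):
        return self.fx(x, y), self.fy(x, y)

    def dense(self):
        """Per-pixel ``(dx, dy)`` rasters over the full domain (cached)."""
        if self._dense is None:
            w, h = self.domain
            yy, xx = np.mgrid[0:h, 0:w]
            xf = xx.ravel().astype(np.float64)
            yf = yy.ravel().astype(np.float64)
            dx = self.fx(xf, yf).reshape(h, w)
            dy = self.fy(xf, yf).reshape(h, w)
            self._dense = (dx, dy)
        return self._dense


def build_displacement_field(points, displacements, domain, h: int = 7, s0: float = 512.0) -> DisplacementField:
    """Fit the two displacement-component surfaces from matched control points.

    ``points`` is ``(n, 2)`` of ``(x, y)`` live coordinates, ``displacements``
    ``(n, 2)`` of ``(dx, dy)``.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    disps = np.asarray(displacements, dtype=np.float64).reshape(-1, 2)
    if len(points) != len(disps):
        raise ValueError("points and displacements must pair up")
    if len(points) == 0:
        raise ValueError("at least one control point is required")
    fx = mba_fit(np.column_stack([points, disps[:, 0]]), domain, h, s0)
    fy = mba_fit(np.column_stack([points, disps[:, 1]]), domain, h, s0)
    return DisplacementField(fx, fy, domain)


def warp_image(img, field: DisplacementField) -> np.ndarray:
    """Backward-mapped elastic warp: ``out(x, y) = img(x + dx, y + dy)``.

    Bilinear interpolation; source coordinates outside the image replicate
    the nearest border pixel.  A zero field reproduces the input exactly.
    """
    img = as_gray_image(img)
    dx, dy = field.dense()
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1, mode="nearest")
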