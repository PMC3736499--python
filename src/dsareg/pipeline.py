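"""End-to-end registration of a mask/live angiogram pair.

The model object holds the image pair and configuration; ``fit()`` runs
the four registration stages — control-point selection on the live
image, block matching against the original mask, bottom-hat enhancement
of both images, and multilevel B-spline warping of the enhanced mask —
and returns a results object carrying the estimated displacement field,
the matches, the registered mask and the subtraction images, with a
``summary()`` diagnostic table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imageio
from .enhance import StructuringElement, enhance_pair
from .features import ControlPointSet, SelectionParams, select_from_image
from .matching import MatchConfig, match_all
from .mbspline import DisplacementField, build_displacement_field, warp_image

__all__ = [
    "RegistrationConfig",
    "DegradedInputError",
    "DSARegistration",
    "DSARegistrationResults",
    "register",
    "dsa_subtract",
]


class DegradedInputError(RuntimeError):
    """Raised when the live image yields too few control points to register."""


@dataclass(frozen=True)
class RegistrationConfig:
    """All tunable parameters of the registration pipeline.

    Defaults follow the reference operating point for 512 x 512 8-bit
    coronary angiograms: edge scale sigma = 1, minimum control-point
    distance D_min = 25, template size w = 51, lattice hierarchy depth
    h = 7, ENT similarity with four-start hill climbing.
    """

    selection: SelectionParams = dc_field(default_factory=SelectionParams)
    match: MatchConfig = dc_field(default_factory=MatchConfig)
    measure: str = "ent"
    h: int = 7
    s0: float = 512.0
    se: StructuringElement = dc_field(default_factory=StructuringElement)

    def __post_init__(self):
        # the enhancement ball must not fit inside a vessel
        if self.se.diameter < 3:
            raise ValueError("structuring element too small")


class DSARegistration:
    """Nonrigid registration model for one (mask, live) image pair.

    Parameters
    ----------
    mask : 2-D array
        Pre-contrast frame to be warped onto the live frame.
    live : 2-D array
        Contrast frame; control points are selected here.
    config : RegistrationConfig, optional
    """

    def __init__(self, mask, live, config: RegistrationConfig | None = None):
        self.mask = imageio.as_gray_image(mask)
        self.live = imageio.as_gray_image(live)
        if self.mask.shape != self.live.shape:
            raise ValueError(f"mask {self.mask.shape} and live {self.live.shape} shapes differ")
        self.config = config or RegistrationConfig()
        m = self.config.selection.border_margin
        if min(self.live.shape) <= 2 * m:
            raise ValueError("images too small for the configured border margin")

    @classmethod
    def from_files(cls, mask_path, live_path, config: RegistrationConfig | None = None):
        return cls(imageio.read_image(mask_path), imageio.read_image(live_path), config)

    def fit(self) -> "DSARegistrationResults":
        cfg = self.config
        points = select_from_image(self.live, cfg.selection)
        if len(points) < 3:
            raise DegradedInputError(
                f"only {len(points)} control points found; the live image is too "
                "featureless to support an elastic fit (need >= 3)"
            )
        matches = match_all(self.live, self.mask, points.points, cfg.match, cfg.measure)
        mask_enh, live_enh = enhance_pair(self.mask, self.live, cfg.se)
        h_img, w_img = self.live.shape
        field = build_displacement_field(
            [m.p for m in matches], [m.d for m in matches], (w_img, h_img), cfg.h, cfg.s0
        )
        registered = warp_image(mask_enh, field)
        return DSARegistrationResults(self, points, matches, field, mask_enh, live_enh, registered)


class DSARegistrationResults:
    """Fitted registration: displacement field, matches and subtractions."""

    def __init__(self, model, control_points, match_list, field, mask_enh, live_enh, registered_mask):
        self.model = model
        self.control_points: ControlPointSet = control_points
        self.match_list = match_list
        self.field: DisplacementField = field
        self.mask_enhanced = mask_enh
        self.live_enhanced = live_enh
        self.registered_mask = registered_mask
        self.dsa_before_signed, self.dsa_before = dsa_subtract(live_enh, mask_enh)
        self.dsa_after_signed, self.dsa_after = dsa_subtract(live_enh, registered_mask)

    @property
    def matches(self) -> pd.DataFrame:
        """Matched pairs as a table: x, y, x', y', dx, dy, score."""
        rows = [
            dict(x=m.p[0], y=m.p[1], xp=m.q[0], yp=m.q[1], dx=m.d[0], dy=m.d[1], score=m.score)
            for m in self.match_list
        ]
        return pd.DataFrame(rows, columns=["x", "y", "xp", "yp", "dx", "dy", "score"])

    @property
    def displacements(self) -> np.ndarray:
        return np.array([m.d for m in self.match_list], dtype=np.float64)

    def residual_energy(self) -> tuple:
        """Variance of the signed subtraction before and after registration."""
        return float(self.dsa_before_signed.var()), float(self.dsa_after_signed.var())

    def summary(self) -> str:
        d = self.displacements
        before, after = self.residual_energy()
        mag = np.hypot(d[:, 0], d[:, 1]) if len(d) else np.zeros(0)
        lines = [
            "DSA nonrigid registration results",
            "=" * 46,
            f"{'image size':<32}{self.model.live.shape[1]} x {self.model.live.shape[0]}",
            f"{'similarity measure':<32}{self.model.config.measure.upper()}",
            f"{'control points':<32}{len(self.match_list)}",
            f"{'mean |d| (px)':<32}{mag.mean():.3f}" if len(mag) else f"{'mean |d| (px)':<32}n/a",
            f"{'max |d| (px)':<32}{mag.max():.3f}" if len(mag) else f"{'max |d| (px)':<32}n/a",
            f"{'lattice hierarchy levels':<32}{self.model.config.h}",
            f"{'residual energy before':<32}{before:.2f}",
            f"{'residual energy after':<32}{after:.2f}",
            f"{'residual reduction':<32}{(1 - after / before) * 100 if before > 0 else 0:.1f}%",
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write DSA images, matches table and displacement-field rasters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        imageio.write_image(self.dsa_before, outdir / "dsa_before.png")
        imageio.write_image(self.dsa_after, outdir / "dsa_after.png")
        imageio.write_image(np.clip(self.registered_mask, 0, 255), outdir / "registered_mask.png")
        self.matches.to_csv(outdir / "matches.csv", index=False)
        import tifffile

        dx, dy = self.field.dense()
        tifffile.imwrite(outdir / "field.tif", np.stack([dx, dy]).astype(np.float32))

    def plot(self, ax=None):
        """Overlay the matched displacements on the live image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(self.model.live, cmap="gray", vmin=0, vmax=255)
        d = self.displacements
        pts = np.array([m.p for m in self.match_list], dtype=np.float64)
        if len(pts):
            ax.quiver(pts[:, 0], pts[:, 1], d[:, 0], d[:, 1], color="red", angles="xy", scale_units="xy", scale=0.5)
        ax.set_title("matched control-point displacements")
        ax.set_axis_off()
        return ax


def register(mask, live, config: RegistrationConfig | None = None) -> DSARegistrationResults:
    """Functional wrapper: build the model and fit it."""
    return DSARegistration(mask, live, config).fit()


def dsa_subtract(live_enh, mask_reg):
    """Signed subtraction ``live - mask`` and its display rendering.

    The display image maps zero difference to mid-gray 128 and clamps to
    [0, 255]; injected (dark) vessels therefore appear dark.
    """
    live_enh = np.asarray(live_enh, dtype=np.float64)
    mask_reg = np.asarray(mask_reg, dtype=np.float64)
    if live_enh.shape != mask_reg.shape:
        raise ValueError("shape mismatch in subtraction")
    signed = live_enh - mask_reg
    display = np.clip(signed + 128.0, 0.0, 255.0)
    return signed, display
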