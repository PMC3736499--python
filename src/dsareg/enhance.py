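"""Gray-level distortion reduction by bottom-hat subtraction.

Even with a perfect geometric correction, tissue contraction and X-ray
intensity fluctuation leave low-amplitude gray-level differences in the
subtraction background.  Subtracting the morphological bottom-hat
(closing minus original, computed with a nonflat ball structuring
element wider than any vessel) from both mask and live images deepens
dark thin structures while flattening everything the ball fits, which
makes the subtraction background more homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import as_gray_image

__all__ = ["StructuringElement", "ball_element", "bottom_hat", "enhance_pair"]


@dataclass(frozen=True)
class StructuringElement:
    """Nonflat ball: ellipsoidal height profile over a circular support.

    ``diameter`` (px in the image plane) must exceed the largest expected
    vessel width — a clinical prior supplied through configuration.
    ``height`` is the peak of the profile in gray levels.
    """

    diameter: int = 15
    height: float = 15.0

    def __post_init__(self):
        if self.diameter < 3 or self.diameter % 2 != 1:
            raise ValueError("diameter must be an odd integer >= 3")
        if self.height <= 0:
            raise ValueError("height must be positive")

    @property
    def footprint(self) -> np.ndarray:
        r = self.diameter // 2
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        return dx * dx + dy * dy <= r * r

    @property
    def structure(self) -> np.ndarray:
        """Height profile ``h * sqrt(1 - (rho/r)^2)`` on the circular support."""
        r = self.diameter // 2
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        rho2 = (dx * dx + dy * dy) / float(r * r)
        prof = self.height * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        prof[~self.footprint] = 0.0
        return prof


def bottom_hat(img, se: StructuringElement | None = None) -> np.ndarray:
    """Grayscale closing with the nonflat ball, minus the original image.

    Nonnegative everywhere (closing is extensive); positive over dark
    structures narrower than the ball support.
    """
    se = se or StructuringElement()
    img = as_gray_image(img)
    if se.diameter >= min(img.shape):
        raise ValueError("structuring element must be smaller than the image")
    closed = ndimage.grey_closing(img, footprint=se.footprint, structure=se.structure, mode="nearest")
    return closed - img


def ball_element(diameter: int = 15, height: float = 15.0) -> StructuringElement:
    """Convenience constructor for the default nonflat ball."""
    return StructuringElement(diameter, height)


def enhance_pair(mask, live, se: StructuringElement | None = None):
    """Enhanced pair ``(M - Bhat(M), L - Bhat(L))``, kept in float.

    Values may dip below 0; clamping happens only at display/export.
    """
    se = se or StructuringElement()
    return mask - bottom_hat(mask, se), live - bottom_hat(live, se)
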