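"""Color-space conversions and CIEDE2000 color difference on image regions.

Used in two places: quantifying how closely a phantom's fluorescence color
matches reference tissue (region-mean colors compared with Delta E 2000),
and as the fluorescence gate in well classification (chromatic difference
of a well versus its same-size control well, plus an xyY luminance
saturation check).

Conventions: sRGB with the standard transfer function, D65 white point,
2-degree observer.  8-bit images are normalized by 255, 16-bit by 65535,
floats are passed through.  Conversions are delegated to scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "ColorSRGB",
    "ColorLab",
    "ColorxyY",
    "ROI",
    "srgb_to_lab",
    "srgb_to_xyY",
    "delta_e_2000",
    "roi_mean_color",
    "roi_delta_e",
    "relative_luminance",
    "normalize_image",
    "roi_mask",
]

# D65 chromaticity (2-degree observer), used for zero-luminance pixels.
_D65_xy = (0.3127, 0.3290)


@dataclass(frozen=True)
class ColorSRGB:
    """Nonlinear (gamma-encoded) sRGB color with channels in [0, 1]."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for ch in (self.r, self.g, self.b):
            if not 0.0 <= ch <= 1.0:
                raise ValueError("sRGB channels must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)

    @classmethod
    def from_8bit(cls, r: int, g: int, b: int) -> "ColorSRGB":
        return cls(r / 255.0, g / 255.0, b / 255.0)


@dataclass(frozen=True)
class ColorLab:
    """CIE L*a*b* color (D65/2-degree unless stated otherwise)."""

    L_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star], dtype=float)


@dataclass(frozen=True)
class ColorxyY:
    """CIE xyY: chromaticity (x, y) plus relative luminance Y in [0, 1]."""

    x: float
    y: float
    Y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.x + self.y > 1.0 + 1e-9:
            raise ValueError("chromaticity must satisfy x, y >= 0 and x + y <= 1")
        if self.Y < 0:
            raise ValueError("luminance must be >= 0")


@dataclass(frozen=True)
class ROI:
    """Circular region of interest in pixel coordinates (row, col, radius)."""

    center_row: float
    center_col: float
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Return an (H, W, 3) float image in [0, 1] from uint8/uint16/float input."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    img = img[..., :3]
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    out = img.astype(float)
    if out.min() < 0 or out.max() > 1:
        raise ValueError("float images must already be scaled to [0, 1]")
    return out


def srgb_to_lab(c: ColorSRGB) -> ColorLab:
    """Convert sRGB to CIE L*a*b* (linearize, sRGB->XYZ, XYZ->Lab, D65/2deg)."""
    lab = _skcolor.rgb2lab(c.as_array().reshape(1, 1, 3)).reshape(3)
    return ColorLab(float(lab[0]), float(lab[1]), float(lab[2]))


def srgb_to_xyY(c: ColorSRGB) -> ColorxyY:
    """Convert sRGB to CIE xyY.

    A black pixel (X = Y = Z = 0) has undefined chromaticity; by convention
    it is assigned the D65 white-point chromaticity with Y = 0.
    """
    xyz = _skcolor.rgb2xyz(c.as_array().reshape(1, 1, 3)).reshape(3)
    s = float(xyz.sum())
    if s <= 0.0:
        return ColorxyY(_D65_xy[0], _D65_xy[1], 0.0)
    return ColorxyY(float(xyz[0] / s), float(xyz[1] / s), float(xyz[1]))


def relative_luminance(c: ColorSRGB) -> float:
    """Relative luminance Y in [0, 1] (the Y of xyY)."""
    return srgb_to_xyY(c).Y


def delta_e_2000(
    c1: ColorLab, c2: ColorLab, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0
) -> float:
    """CIEDE2000 color difference between two L*a*b* colors.

    The full formula with lightness/chroma/hue weighting functions and the
    blue-region rotation term; parametric weights default to 1.
    """
    return float(
        _skcolor.deltaE_ciede2000(c1.as_array(), c2.as_array(), kL=kL, kC=kC, kH=kH)
    )


def roi_mask(shape: tuple[int, int], roi: ROI) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI circle.

    A radius that rounds to zero pixels degrades to the single pixel
    containing the ROI center.
    """
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    mask = (rows - roi.center_row) ** 2 + (cols - roi.center_col) ** 2 <= roi.radius**2
    if not mask.any():
        r = int(round(roi.center_row))
        c = int(round(roi.center_col))
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            mask[r, c] = True
    return mask


def roi_mean_color(image: np.ndarray, roi: ROI) -> ColorSRGB:
    """Arithmetic mean sRGB color over the pixels inside the ROI circle.

    Raises ``ValueError`` if the circle does not overlap the image at all.
    """
    img = normalize_image(image)
    mask = roi_mask(img.shape[:2], roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.label or roi} does not overlap the image")
    mean = img[mask].mean(axis=0)
    return ColorSRGB(float(mean[0]), float(mean[1]), float(mean[2]))


def roi_delta_e(
    image_a: np.ndarray, roi_a: ROI, image_b: np.ndarray, roi_b: ROI
) -> float:
    """Delta E 2000 between the mean colors of two ROIs (mean-then-Delta-E).

    The region means are taken in sRGB first and converted once; this is
    deliberately not the mean of per-pixel Delta E values, which differs on
    nonuniform regions.
    """
    lab_a = srgb_to_lab(roi_mean_color(image_a, roi_a))
    lab_b = srgb_to_lab(roi_mean_color(image_b, roi_b))
    return delta_e_2000(lab_a, lab_b)
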