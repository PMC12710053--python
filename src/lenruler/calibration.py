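"""Pixel-to-millimetre calibration from a quadrilateral reference object.

A single image of a bright quadrilateral of known physical area (by default
one sixty-fourth of an A4 sheet) on a dark background fixes the scale. The
quad is detected by morphological denoising, Canny edge extraction and
largest-closed-contour selection; its pixel area ``S_p`` comes from the
shoelace (discrete Green's theorem) formula, and the pixel-per-millimetre
ratio is ``R = sqrt(S_p / S_r)`` with ``S_r`` the true area in mm². A pixel
length then converts as ``l_r = l_p / R``. The camera is assumed fixed
between the calibration image and the seed images; no lens-distortion
correction is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import feature, filters, morphology

from .io_core import SeedImage

# ISO 216: A4 is 210 mm x 297 mm; the reference object is 1/64 of the sheet.
A4_64_AREA_MM2 = 210.0 * 297.0 / 64.0       # 974.53125


@dataclass(frozen=True)
class Quad:
    """Four pixel-coordinate vertices, ordered counter-clockwise."""

    vertices: np.ndarray                      # (4, 2) float, (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (4, 2):
            raise ValueError("Quad needs exactly 4 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("Quad must be a simple polygon with positive area")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel area, true area and the derived px/mm ratio."""

    S_p: float        # px^2
    S_r: float        # mm^2
    R: float          # px per mm

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"pixel_area_px2": self.S_p, "true_area_mm2": self.S_r,
             "ratio_px_per_mm": self.R}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationScale":
        d = json.loads(Path(path).read_text())
        return cls(S_p=d["pixel_area_px2"], S_r=d["true_area_mm2"],
                   R=d["ratio_px_per_mm"])


class CalibrationError(RuntimeError):
    """Raised when no usable calibration object is found in the image."""


def detect_calibration_quad(image: SeedImage) -> Quad:
    """Locate the bright quadrilateral reference object.

    The grayscale image is binarised and denoised by erosion+dilation
    (morphological opening), Canny edges are extracted and filled into
    closed regions, the largest closed contour is selected, and the four
    vertices are the contour points nearest the corners of the contour's
    minimum-area rotated bounding rectangle, ordered counter-clockwise.
    """
    gray = image.pixels.astype(float).mean(axis=2) / 255.0
    thresh = filters.threshold_otsu(gray) if gray.max() > gray.min() else 1.0
    binary = gray > thresh
    if not binary.any():
        raise CalibrationError("no bright region found in calibration image")
    opened = ndimage.binary_opening(binary, structure=morphology.disk(2).astype(bool))
    edges = feature.canny(gray * opened, sigma=1.0)
    filled = ndimage.binary_fill_holes(opened | edges)
    labels, n = ndimage.label(filled)
    if n == 0:
        raise CalibrationError("no closed contour found in calibration image")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    region = labels == (int(np.argmax(sizes)) + 1)

    from skimage.measure import find_contours
    contours = [c for c in find_contours(region.astype(float), 0.5)
                if len(c) >= 8 and np.allclose(c[0], c[-1])]
    if not contours:
        raise CalibrationError("largest region has no closed contour")
    contour = max(contours, key=lambda c: abs(_shoelace(c[:, 1], c[:, 0])))
    pts = np.column_stack([contour[:, 1], contour[:, 0]])   # (x, y)

    rect = Polygon(pts).minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords)[:4]
    verts = []
    for c in corners:
        verts.append(pts[np.argmin(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]))])
    verts = np.array(verts)
    if len({tuple(np.round(v, 3)) for v in verts}) < 4:
        raise CalibrationError("contour has fewer than 4 distinct extremal points")
    return Quad(vertices=_order_ccw(verts))


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))


def _order_ccw(verts: np.ndarray) -> np.ndarray:
    centre = verts.mean(axis=0)
    ang = np.arctan2(verts[:, 1] - centre[1], verts[:, 0] - centre[0])
    verts = verts[np.argsort(ang)]
    # counter-clockwise = positive shoelace sum in (x, y) coordinates
    if _shoelace(verts[:, 0], verts[:, 1]) < 0:
        verts = verts[::-1]
    return verts


def polygon_pixel_area(quad: Quad | np.ndarray) -> float:
    """Shoelace area ``0.5 |sum_i (x_i y_{i+1} - y_i x_{i+1})|`` (cyclic).

    Accepts any simple polygon with n >= 3 vertices.
    """
    v = quad.vertices if isinstance(quad, Quad) else np.asarray(quad, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    return abs(_shoelace(v[:, 0], v[:, 1]))


def length_ratio(S_p: float, S_r: float) -> CalibrationScale:
    """Pixel-per-mm ratio ``R = sqrt(S_p / S_r)`` from pixel and true areas."""
    if S_p <= 0 or S_r <= 0:
        raise ValueError("areas must be positive")
    return CalibrationScale(S_p=float(S_p), S_r=float(S_r),
                            R=math.sqrt(S_p / S_r))


def to_true_length(l_p: float, scale: CalibrationScale) -> float:
    """Convert a pixel length to millimetres: ``l_r = l_p / R``."""
    if l_p < 0:
        raise ValueError("pixel length must be non-negative")
    return l_p / scale.R


def calibrate_image(image: SeedImage, true_area_mm2: float = A4_64_AREA_MM2) -> CalibrationScale:
    """Detect the reference quad and derive the full scale in one call."""
    quad = detect_calibration_quad(image)
    return length_ratio(polygon_pixel_area(quad), true_area_mm2)
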