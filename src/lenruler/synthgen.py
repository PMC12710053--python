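"""Seeded generator of synthetic germination scenes with exact ground truth.

The generator emulates the statistical structure the measurement pipeline
relies on: elliptical seed coats whose pixel chromaticity ``(R-B, G-B)``
follows a 2-D Gaussian, attached curved radicles of known centerline arc
length and a distinct (whitish) colour, a near-black background as in
imaging on non-reflective black cloth, optional seed adhesion, and an
optional bright calibration square of known physical size.

Ground truth is exact by construction: per-seed coat and radicle masks, the
detector-style bounding box (coat plus a configurable proximal stub of the
radicle, reproducing the truncation that box prompting suffers from), the
germination class, and the centerline polyline length of the radicle.

:func:`oracle_backend` wraps a scene as a promptable segmenter, optionally
corrupted (``box_clip`` truncates box-prompted masks at the box; ``dilate1``
adds one dilation of boundary error), so the whole pipeline can be exercised
without any pretrained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .io_core import Detection, SeedClass, SeedImage
from .segmentation import Prompt, PromptKind, register_backend

logger = logging.getLogger("lenruler")


@dataclass
class SceneParams:
    """Generator parameters; defaults describe a typical germination image.

    The coat chromaticity mean/covariance are in ``(R-B, G-B)`` feature
    units; the defaults model a brown seed coat on which a whitish radicle
    (features near the origin) is far from the coat distribution
    (Mahalanobis distance >> 6), so classification difficulty is controlled
    solely by moving ``radicle_feature`` closer to ``coat_mean``.
    """

    shape: tuple[int, int] = (480, 640)      # rows, cols
    n_seeds: int = 6
    coat_semi_axes: tuple[float, float] = (12.0, 22.0)   # min/max semi-axis px
    coat_mean: tuple[float, float] = (85.0, 35.0)        # m_true
    coat_cov: tuple[tuple[float, float], tuple[float, float]] = ((25.0, 6.0), (6.0, 16.0))
    coat_base_blue: int = 70                  # B channel of coat pixels
    radicle_length_range: tuple[float, float] = (20.0, 60.0)  # centerline arc px
    radicle_width: float = 3.0
    radicle_mode: str = "bezier"              # "straight_axis_aligned" | "bezier"
    radicle_feature: tuple[float, float] = (5.0, 5.0)
    radicle_base_blue: int = 200
    background_rgb: tuple[int, int, int] = (12, 12, 14)
    adhesion_prob: float = 0.1
    noise_sigma: float = 0.0                  # additive luminance noise (DN)
    box_radicle_fraction: float = 0.25        # proximal radicle stub inside GT box
    germination_prob: float = 1.0
    calibration_side_px: float | None = None
    calibration_side_mm: float | None = None
    calibration_angle_deg: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.coat_cov, dtype=float)
        if not np.allclose(C, C.T) or np.any(np.linalg.eigvalsh(C) <= 0):
            raise ValueError("coat_cov must be symmetric positive-definite")
        if self.radicle_length_range[0] <= 0:
            raise ValueError("radicle arc-length range must be positive")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")
        if self.radicle_mode not in ("straight_axis_aligned", "bezier"):
            raise ValueError(f"unknown radicle mode {self.radicle_mode!r}")


@dataclass
class SeedGroundTruth:
    """Exact per-seed ground truth."""

    seed_id: int
    coat_mask: np.ndarray
    radicle_mask: np.ndarray
    box: tuple[int, int, int, int]
    cls: SeedClass
    arc_length_px: float
    centerline: np.ndarray | None = None      # (n, 2) float (x, y), dense

    @property
    def union(self) -> np.ndarray:
        return np.logical_or(self.coat_mask, self.radicle_mask)


@dataclass
class SyntheticScene:
    image: SeedImage
    seeds: list[SeedGroundTruth]
    calibration_quad: np.ndarray | None = None     # (4, 2) float (x, y), CCW
    calibration_true_area_mm2: float | None = None

    def detections(self) -> list[Detection]:
        return [Detection(box=s.box, cls=s.cls, score=1.0) for s in self.seeds]


def draw_coat_features(n: int, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Continuous chromaticity draws from the coat model Normal(m_true, C_true).

    This is the sampler the renderer quantises to 8-bit RGB; exposed so
    calibration properties of the classifier can be checked against the
    exact generating distribution.
    """
    return rng.multivariate_normal(
        np.asarray(params.coat_mean, float), np.asarray(params.coat_cov, float), size=n)


def _features_to_rgb(features: np.ndarray, base_blue: int) -> np.ndarray:
    """Map (R-B, G-B) features to uint8 RGB at a fixed blue level, clipping."""
    b = np.full(features.shape[:-1], float(base_blue))
    rgb = np.stack([b + features[..., 0], b + features[..., 1], b], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _ellipse_mask(shape, cx, cy, a, b, theta) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _centerline(params: SceneParams, start: np.ndarray, heading: float,
                length: float, rng: np.random.Generator) -> np.ndarray:
    """Dense (step 0.25 px) centerline polyline of exact arc length ``length``."""
    step = 0.25
    n = int(round(length / step))
    pts = [start.astype(float)]
    h = heading
    if params.radicle_mode == "bezier":
        # slowly drifting heading: gentle curvature, bounded total turn
        curv = rng.uniform(-0.008, 0.008)   # rad per px
    else:
        curv = 0.0
    p = start.astype(float)
    for _ in range(n):
        p = p + step * np.array([np.cos(h), np.sin(h)])
        h += curv * step
        pts.append(p.copy())
    return np.array(pts)


def polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))


def _tube_mask(shape, centerline: np.ndarray, width: float) -> np.ndarray:
    rows, cols = shape
    r = width / 2.0
    x0 = max(0, int(np.floor(centerline[:, 0].min() - r - 1)))
    x1 = min(cols, int(np.ceil(centerline[:, 0].max() + r + 2)))
    y0 = max(0, int(np.floor(centerline[:, 1].min() - r - 1)))
    y1 = min(rows, int(np.ceil(centerline[:, 1].max() + r + 2)))
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d, _ = cKDTree(centerline).query(pts)
    mask[y0:y1, x0:x1] = (d <= r).reshape(yy.shape)
    return mask


def _rotate(pts: np.ndarray, angle: float, about: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (pts - about) @ rot.T + about


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render a synthetic germination scene; deterministic given ``rng_seed``.

    Seeds that cannot be placed inside the frame after 100 attempts are
    dropped with a warning.
    """
    rng = np.random.default_rng(params.rng_seed)
    rows, cols = params.shape
    img = np.empty((rows, cols, 3), dtype=np.uint8)
    img[:] = np.array(params.background_rgb, dtype=np.uint8)

    calibration_quad = None
    calibration_area = None
    occupied = np.zeros((rows, cols), dtype=bool)
    if params.calibration_side_px is not None:
        side = float(params.calibration_side_px)
        half_diag = side * np.sqrt(2) / 2          # rotation-safe placement margin
        cx, cy = cols - half_diag - 10, rows - half_diag - 10
        half = side / 2
        corners = np.array([
            [cx - half, cy - half], [cx + half, cy - half],
            [cx + half, cy + half], [cx - half, cy + half]])
        corners = _rotate(corners, np.deg2rad(params.calibration_angle_deg),
                          np.array([cx, cy]))
        # CCW in (x, y) with y down means clockwise on screen; orient by shoelace
        if _signed_area(corners) < 0:
            corners = corners[::-1]
        yy, xx = np.mgrid[0:rows, 0:cols]
        inside = _point_in_quad(xx, yy, corners)
        img[inside] = (230, 230, 230)
        occupied |= binary_dilation(inside, structure=np.ones((9, 9), bool))
        calibration_quad = corners
        if params.calibration_side_mm is not None:
            calibration_area = float(params.calibration_side_mm) ** 2

    seeds: list[SeedGroundTruth] = []
    placed_centers: list[tuple[float, float, float]] = []  # cx, cy, max semi-axis
    union_all = np.zeros((rows, cols), dtype=bool)
    for seed_id in range(params.n_seeds):
        placed = _place_seed(params, rng, occupied, union_all, placed_centers,
                             seed_id)
        if placed is None:
            logger.warning("seed %d could not be placed after 100 attempts; "
                           "scene has %d seeds", seed_id, len(seeds))
            continue
        gt, claim = placed
        seeds.append(gt)
        occupied |= claim
        union_all |= gt.union

    # paint: radicle first, coat on top (overlap shows coat colour)
    for gt in seeds:
        if gt.radicle_mask.any():
            n_px = int(gt.radicle_mask.sum())
            feats = np.asarray(params.radicle_feature, float) + rng.normal(0, 1.0, (n_px, 2))
            img[gt.radicle_mask] = _features_to_rgb(feats, params.radicle_base_blue)
    for gt in seeds:
        n_px = int(gt.coat_mask.sum())
        feats = draw_coat_features(n_px, params, rng)
        img[gt.coat_mask] = _features_to_rgb(feats, params.coat_base_blue)

    if params.noise_sigma > 0:
        noise = rng.normal(0, params.noise_sigma, (rows, cols, 1))
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=SeedImage(pixels=img, image_id=f"synthetic-{params.rng_seed}"),
        seeds=seeds,
        calibration_quad=calibration_quad,
        calibration_true_area_mm2=calibration_area,
    )


def _place_seed(params, rng, occupied, union_all, placed_centers, seed_id):
    rows, cols = params.shape
    a_lo, a_hi = params.coat_semi_axes
    for _ in range(100):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(a_lo, a)            # semi-minor <= semi-major
        theta = rng.uniform(0, np.pi)
        germinated = rng.random() < params.germination_prob
        length = rng.uniform(*params.radicle_length_range) if germinated else 0.0
        margin = a + length + params.radicle_width + 3
        adhere = placed_centers and rng.random() < params.adhesion_prob
        if adhere:
            # tangent to an existing seed: touching, never occluding
            pcx, pcy, pr = placed_centers[rng.integers(len(placed_centers))]
            ang = rng.uniform(0, 2 * np.pi)
            cx = pcx + (pr + a) * np.cos(ang)
            cy = pcy + (pr + a) * np.sin(ang)
        else:
            if margin >= cols / 2 or margin >= rows / 2:
                margin = max(a + 3, min(margin, min(rows, cols) / 2 - 1))
            cx = rng.uniform(margin, cols - margin)
            cy = rng.uniform(margin, rows - margin)
        if not (a < cx < cols - a and a < cy < rows - a):
            continue
        coat = _ellipse_mask((rows, cols), cx, cy, a, b, theta)
        if not coat.any():
            continue
        # adhered seeds may sit inside another seed's dilated claim but must
        # never overwrite any already-placed coat or radicle pixel
        blocked = union_all if adhere else occupied
        if np.logical_and(coat, blocked).any():
            continue

        radicle = np.zeros((rows, cols), dtype=bool)
        centerline = None
        if germinated:
            heading = rng.uniform(0, 2 * np.pi)
            if params.radicle_mode == "straight_axis_aligned":
                heading = rng.choice([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
            # start on the ellipse boundary along the heading direction
            start = _ellipse_boundary_point(cx, cy, a, b, theta, heading)
            centerline = _centerline(params, start, heading, length, rng)
            if (centerline[:, 0].min() < 2 or centerline[:, 0].max() > cols - 3 or
                    centerline[:, 1].min() < 2 or centerline[:, 1].max() > rows - 3):
                continue
            tube = _tube_mask((rows, cols), centerline, params.radicle_width)
            radicle = np.logical_and(tube, ~coat)
            if np.logical_and(tube, union_all if adhere else occupied).any():
                continue
            length = polyline_length(centerline)

        box = _gt_box(coat, centerline, params, (rows, cols))
        cls = SeedClass.GERMINATED if germinated else SeedClass.NON_GERMINATED
        gt = SeedGroundTruth(seed_id=seed_id, coat_mask=coat, radicle_mask=radicle,
                             box=box, cls=cls,
                             arc_length_px=length if germinated else 0.0,
                             centerline=centerline)
        claim = binary_dilation(gt.union, structure=np.ones((5, 5), bool))
        placed_centers.append((cx, cy, a))
        return gt, claim
    return None


def _ellipse_boundary_point(cx, cy, a, b, theta, heading) -> np.ndarray:
    """Point where the ray from the centre along ``heading`` exits the ellipse."""
    d = np.array([np.cos(heading), np.sin(heading)])
    ct, st = np.cos(theta), np.sin(theta)
    u = d[0] * ct + d[1] * st
    v = -d[0] * st + d[1] * ct
    t = 1.0 / np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return np.array([cx, cy]) + t * d


def _gt_box(coat, centerline, params, shape) -> tuple[int, int, int, int]:
    rows, cols = shape
    ys, xs = np.nonzero(coat)
    x0, x1 = xs.min(), xs.max() + 1
    y0, y1 = ys.min(), ys.max() + 1
    if centerline is not None and len(centerline) > 1:
        n_stub = max(2, int(round(params.box_radicle_fraction * len(centerline))))
        stub = centerline[:n_stub]
        r = params.radicle_width / 2 + 1
        x0 = min(x0, int(np.floor(stub[:, 0].min() - r)))
        x1 = max(x1, int(np.ceil(stub[:, 0].max() + r)))
        y0 = min(y0, int(np.floor(stub[:, 1].min() - r)))
        y1 = max(y1, int(np.ceil(stub[:, 1].max() + r)))
    return (max(0, int(x0)), max(0, int(y0)), min(cols, int(x1)), min(rows, int(y1)))


def _signed_area(quad: np.ndarray) -> float:
    x, y = quad[:, 0], quad[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))


def _point_in_quad(xx, yy, quad) -> np.ndarray:
    inside = np.ones(xx.shape, dtype=bool)
    n = len(quad)
    for i in range(n):
        x0, y0 = quad[i]
        x1, y1 = quad[(i + 1) % n]
        cross = (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0)
        inside &= cross >= 0 if _signed_area(quad) > 0 else cross <= 0
    return inside


class OracleSegmenter:
    """Ground-truth-backed promptable segmenter (test double for a neural one).

    Box prompts return the GT union of the seed overlapping the box most;
    with ``box_clip`` corruption the union is intersected with the box,
    emulating the coarse-stage truncation. Point prompts return the full GT
    union of the first seed containing any prompt point, regardless of any
    box — or an empty mask if no point hits a seed (a segmentation miss).
    ``dilate1`` adds one morphological dilation of boundary error.
    """

    accepts_boxes = True
    accepts_points = True

    def __init__(self, scene: SyntheticScene, corruption: str = "none"):
        if corruption not in ("none", "box_clip", "dilate1"):
            raise ValueError(f"unknown corruption {corruption!r}")
        self.scene = scene
        self.corruption = corruption

    def segment(self, image: SeedImage, prompt: Prompt) -> np.ndarray:
        shape = image.shape
        if prompt.kind is PromptKind.BOX:
            x0, y0, x1, y1 = prompt.box
            best, best_n = None, 0
            for gt in self.scene.seeds:
                n = int(gt.union[y0:y1, x0:x1].sum())
                if n > best_n:
                    best, best_n = gt, n
            if best is None:
                return np.zeros(shape, dtype=bool)
            mask = best.union.copy()
            if self.corruption == "box_clip":
                clipped = np.zeros(shape, dtype=bool)
                clipped[y0:y1, x0:x1] = mask[y0:y1, x0:x1]
                mask = clipped
        else:
            mask = None
            for x, y in prompt.points:
                for gt in self.scene.seeds:
                    if gt.union[int(y), int(x)]:
                        mask = gt.union.copy()
                        break
                if mask is not None:
                    break
            if mask is None:
                return np.zeros(shape, dtype=bool)
        if self.corruption == "dilate1":
            mask = binary_dilation(mask, structure=np.ones((3, 3), bool))
        return mask


def oracle_backend(scene: SyntheticScene, corruption: str = "none") -> OracleSegmenter:
    """Wrap a scene's ground truth as a :class:`SegmenterContract` backend."""
    return OracleSegmenter(scene, corruption)


register_backend("oracle", oracle_backend)
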