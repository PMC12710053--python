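"""Gaussian chromaticity model of the seed coat and coat/radicle pixel classification.

Each pixel is reduced to the chromaticity feature ``f = (R - B, G - B)``,
which is invariant to a uniform brightness shift of all three channels. A
2-D Gaussian ``G = (m, C)`` is fitted to a small patch of coat pixels around
the seed-mask centroid, and every pixel of the seed mask is scored with

    p(f) = exp(-0.5 (f - m)^T C^{-1} (f - m)),

the Gaussian density rescaled to 1 at the mean (a monotone transform of the
Mahalanobis distance). Pixels with ``p > T`` are classified seed coat,
otherwise radicle. When f is itself drawn from Normal(m, C), the squared
Mahalanobis distance is chi-square with 2 degrees of freedom, so
``P(p <= T) = T`` exactly — the threshold is the expected fraction of coat
pixels lost to the radicle class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import SeedImage

DEFAULT_THRESHOLD = 0.006


@dataclass(frozen=True)
class GaussianCoatModel:
    """Mean and covariance of coat chromaticity features, with cached inverse."""

    m: np.ndarray            # shape (2,)
    C: np.ndarray            # shape (2,2), symmetric
    C_inv: np.ndarray        # inverse of C + ridge*I
    ridge: float = 0.0


@dataclass(frozen=True)
class ComponentMasks:
    """Disjoint coat/radicle partition of one seed mask."""

    coat: np.ndarray
    radicle: np.ndarray
    seed_id: int = 0


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Chromaticity features (R-B, G-B) of an (..., 3) uint8 RGB array.

    Computed in signed arithmetic: no 8-bit wraparound.
    """
    p = np.asarray(pixels, dtype=np.float64)
    return np.stack([p[..., 0] - p[..., 2], p[..., 1] - p[..., 2]], axis=-1)


def mask_centroid(mask: np.ndarray) -> tuple[int, int]:
    """Centroid ``(x, y)`` of a binary mask, snapped onto the mask.

    The arithmetic mean of member coordinates is rounded to the nearest
    integer pixel; if that pixel is outside the mask (e.g. a C-shaped mask)
    it is snapped to the nearest mask pixel, ties broken by smallest
    (row, col).
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("mask_centroid: empty mask (degenerate segmentation)")
    # round-half-down so a symmetric mask snaps to the smaller coordinate
    mx = int(np.floor(xs.mean() + 0.5)) if (xs.mean() % 1) != 0.5 else int(np.floor(xs.mean()))
    my = int(np.floor(ys.mean() + 0.5)) if (ys.mean() % 1) != 0.5 else int(np.floor(ys.mean()))
    if 0 <= my < mask.shape[0] and 0 <= mx < mask.shape[1] and mask[my, mx]:
        return mx, my
    d2 = (ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2
    order = np.lexsort((xs, ys, d2))  # min distance, ties by (row, col)
    i = order[0]
    return int(xs[i]), int(ys[i])


def sample_patch_features(
    image: SeedImage, center: tuple[int, int], size: int = 3
) -> np.ndarray:
    """Features of the ``size x size`` window centred on ``center=(x, y)``.

    The window is clipped to the image bounds, so a corner centre yields
    fewer samples (4 for size=3).
    """
    x, y = center
    rows, cols = image.shape
    if not (0 <= x < cols and 0 <= y < rows):
        raise ValueError(f"patch centre {center} outside image of shape {image.shape}")
    h = size // 2
    y0, y1 = max(0, y - h), min(rows, y + h + 1)
    x0, x1 = max(0, x - h), min(cols, x + h + 1)
    patch = image.pixels[y0:y1, x0:x1]
    return pixel_features(patch).reshape(-1, 2)


def fit_gaussian(features: np.ndarray, ridge_floor: float = 1e-6) -> GaussianCoatModel:
    """Fit the coat model: sample mean and (n-1)-denominator covariance.

    Near-singular covariances (uniform patches are common) receive a ridge
    ``lambda = ridge_floor * max(trace(C), 1)`` so the model stays usable.
    """
    f = np.asarray(features, dtype=np.float64).reshape(-1, 2)
    if f.shape[0] < 2:
        raise ValueError("fit_gaussian needs at least 2 samples")
    m = f.mean(axis=0)
    C = np.cov(f, rowvar=False, ddof=1)
    ridge = 0.0
    if np.linalg.det(C) < 1e-12:
        ridge = ridge_floor * max(float(np.trace(C)), 1.0)
    C_inv = np.linalg.inv(C + ridge * np.eye(2))
    return GaussianCoatModel(m=m, C=C, C_inv=C_inv, ridge=ridge)


def coat_probability(model: GaussianCoatModel, f: np.ndarray) -> np.ndarray:
    """Rescaled Gaussian density of features under the coat model, in (0, 1].

    Accepts a single feature pair or an (..., 2) array; equals 1 iff f = m.
    """
    d = np.asarray(f, dtype=np.float64) - model.m
    q = np.einsum("...i,ij,...j->...", d, model.C_inv, d)
    return np.exp(-0.5 * q)


def classify_mask(
    image: SeedImage,
    seed_mask: np.ndarray,
    model: GaussianCoatModel,
    threshold: float = DEFAULT_THRESHOLD,
    seed_id: int = 0,
) -> ComponentMasks:
    """Partition a seed mask into coat (``p > T``, strict) and radicle.

    The partition is exact: coat and radicle are disjoint and their union is
    the input mask.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("classify_mask: empty seed mask")
    ys, xs = np.nonzero(seed_mask)
    feats = pixel_features(image.pixels[ys, xs])
    p = coat_probability(model, feats)
    coat = np.zeros_like(seed_mask)
    radicle = np.zeros_like(seed_mask)
    is_coat = p > threshold
    coat[ys[is_coat], xs[is_coat]] = True
    radicle[ys[~is_coat], xs[~is_coat]] = True
    return ComponentMasks(coat=coat, radicle=radicle, seed_id=seed_id)
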