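"""Coarse and fine segmentation orchestration over a promptable-segmenter contract.

The segmenter itself is pluggable: anything that, given an image and a
single box or point prompt, returns one binary mask of the image shape. The
coarse stage prompts with detector boxes and clips each returned mask to its
prompting box — this reproduces the documented limitation of box prompting,
where a long radicle leaving the box is truncated. The fine stage prompts
with the coat and radicle centroids recovered from the coarse
classification; point prompts are not clipped, which is the mechanism that
recovers the complete radicle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .io_core import Detection, SeedImage, SeedFlag

import logging

logger = logging.getLogger("lenruler")


class PromptKind(str, Enum):
    BOX = "box"
    POINTS = "points"


@dataclass(frozen=True)
class Prompt:
    """A single segmentation prompt: either one box or a set of foreground points."""

    kind: PromptKind
    box: tuple[int, int, int, int] | None = None
    points: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind is PromptKind.BOX and self.box is None:
            raise ValueError("box prompt requires a box")
        if self.kind is PromptKind.POINTS and not self.points:
            raise ValueError("point prompt requires at least one point")


@runtime_checkable
class SegmenterContract(Protocol):
    """Minimal promptable-segmenter interface.

    Implementations must be deterministic for identical inputs and return
    exactly one binary mask of the image shape per prompt.
    """

    accepts_boxes: bool
    accepts_points: bool

    def segment(self, image: SeedImage, prompt: Prompt) -> np.ndarray: ...


@dataclass
class SeedMask:
    """Per-seed binary mask produced by one segmentation stage."""

    seed_id: int
    mask: np.ndarray
    source: str  # "coarse" | "fine"
    flags: set[SeedFlag] = field(default_factory=set)


# Backend registry: config key -> zero-argument-or-config factory.
_BACKENDS: dict[str, Callable[..., SegmenterContract]] = {}


def register_backend(name: str, factory: Callable[..., SegmenterContract]) -> None:
    _BACKENDS[name] = factory


def get_backend(name: str, **kwargs) -> SegmenterContract:
    try:
        return _BACKENDS[name](**kwargs)
    except KeyError:
        raise KeyError(f"unknown segmentation backend {name!r}; "
                       f"registered: {sorted(_BACKENDS)}")


def coarse_segment(
    image: SeedImage,
    detections: Sequence[Detection],
    backend: SegmenterContract,
) -> list[SeedMask]:
    """Box-prompted segmentation, one mask per detection, clipped to its box.

    A backend failure or an empty returned mask flags the seed but never
    aborts the image.
    """
    if not backend.accepts_boxes:
        raise ValueError("backend does not accept box prompts")
    out: list[SeedMask] = []
    for seed_id, det in enumerate(detections):
        det.validate(image.shape)
        flags: set[SeedFlag] = set()
        try:
            raw = backend.segment(image, Prompt(kind=PromptKind.BOX, box=det.box))
            mask = np.zeros(image.shape, dtype=bool)
            x0, y0, x1, y1 = det.box
            mask[y0:y1, x0:x1] = np.asarray(raw, dtype=bool)[y0:y1, x0:x1]
        except Exception as exc:  # per-seed isolation
            logger.warning("coarse segmentation failed for seed %d: %s", seed_id, exc)
            mask = np.zeros(image.shape, dtype=bool)
            flags.add(SeedFlag.SEGMENTATION_EMPTY)
        if not mask.any():
            flags.add(SeedFlag.SEGMENTATION_EMPTY)
        out.append(SeedMask(seed_id=seed_id, mask=mask, source="coarse", flags=flags))
    _log_overlaps(out)
    return out


def fine_segment(
    image: SeedImage,
    seed_components: Sequence[tuple[int, tuple[int, int] | None, tuple[int, int] | None]],
    backend: SegmenterContract,
) -> list[SeedMask]:
    """Point-prompted segmentation from (seed_id, coat centroid, radicle centroid).

    Both centroids go into a single foreground-point prompt per seed; seeds
    without a radicle centroid are prompted with the coat centroid alone.
    The returned mask is not clipped to any box. Seeds with no coat centroid
    are flagged and skipped (empty mask).
    """
    if not backend.accepts_points:
        raise ValueError("backend does not accept point prompts")
    rows, cols = image.shape
    out: list[SeedMask] = []
    for seed_id, coat_c, rad_c in seed_components:
        flags: set[SeedFlag] = set()
        if coat_c is None:
            mask = np.zeros(image.shape, dtype=bool)
            flags.add(SeedFlag.SKELETON_DISCONNECTED)
            out.append(SeedMask(seed_id=seed_id, mask=mask, source="fine", flags=flags))
            continue
        points = [coat_c] + ([rad_c] if rad_c is not None else [])
        for x, y in points:
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValueError(f"prompt point {(x, y)} outside image bounds")
        try:
            mask = np.asarray(
                backend.segment(image, Prompt(kind=PromptKind.POINTS,
                                              points=tuple(points))),
                dtype=bool,
            )
        except Exception as exc:
            logger.warning("fine segmentation failed for seed %d: %s", seed_id, exc)
            mask = np.zeros(image.shape, dtype=bool)
            flags.add(SeedFlag.SEGMENTATION_EMPTY)
        if not mask.any():
            flags.add(SeedFlag.SEGMENTATION_EMPTY)
        out.append(SeedMask(seed_id=seed_id, mask=mask, source="fine", flags=flags))
    return out


def _log_overlaps(masks: Sequence[SeedMask]) -> None:
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            n = int(np.logical_and(masks[i].mask, masks[j].mask).sum())
            if n:
                logger.info("seed masks %d and %d overlap on %d px",
                            masks[i].seed_id, masks[j].seed_id, n)
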