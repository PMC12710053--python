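"""Readers and writers for images, detections, masks and measurement tables.

Coordinate conventions used throughout the package: pixel coordinates are
0-based ``(x=col, y=row)``; boxes are half-open ``(x_min, y_min, x_max, y_max)``
so that the box area is ``(x_max - x_min) * (y_max - y_min)``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger("lenruler")

MEASUREMENT_COLUMNS = [
    "image_id", "seed_id", "class", "x_min", "y_min", "x_max", "y_max",
    "pixel_length", "ratio", "true_length_mm", "flags",
]


class SeedClass(str, Enum):
    """Germination status assigned by the detector."""

    NON_GERMINATED = "non_germinated"
    GERMINATED = "germinated"


class SeedFlag(str, Enum):
    """Per-seed quality flags attached during measurement."""

    NO_RADICLE = "no_radicle"
    NO_INTERSECTION_FALLBACK = "no_intersection_fallback"
    SKELETON_DISCONNECTED = "skeleton_disconnected"
    SEGMENTATION_EMPTY = "segmentation_empty"


@dataclass(frozen=True)
class SeedImage:
    """An RGB raster with identity metadata.

    ``pixels`` is an ``(rows, cols, 3)`` uint8 array in R, G, B channel order.
    """

    pixels: np.ndarray
    image_id: str = ""
    path: str = ""

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise ValueError("SeedImage.pixels must be (rows, cols, 3) uint8")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("SeedImage must have at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class Detection:
    """A detector bounding box with germination class and confidence."""

    box: tuple[int, int, int, int]
    cls: SeedClass
    score: float = 1.0

    def validate(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 < x1 <= cols and 0 <= y0 < y1 <= rows):
            raise ValueError(f"box {self.box} violates bounds for shape {shape}")


@dataclass
class SeedRecord:
    """One measured seed: box, class, pixel length and optional true length."""

    image_id: str
    seed_id: int
    cls: SeedClass
    box: tuple[int, int, int, int]
    pixel_length: float = 0.0
    ratio: float | None = None
    true_length_mm: float | None = None
    flags: set[SeedFlag] = field(default_factory=set)


def load_image(path: str | Path) -> SeedImage:
    """Load a PNG/JPEG image as an RGB :class:`SeedImage`.

    Grayscale inputs are replicated to three channels.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return SeedImage(pixels=arr, image_id=path.stem, path=str(path))


def write_image(image: SeedImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a label-PNG mask: 0=background, 1=seed coat, 2=radicle."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise IOError(f"cannot read mask file {path}: {exc}") from exc
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError(f"label mask {path} contains values outside {{0,1,2}}")
    return arr


def write_mask(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("label mask must contain only values {0,1,2}")
    Image.fromarray(labels, mode="L").save(path)


def masks_to_labels(coat: np.ndarray, radicle: np.ndarray) -> np.ndarray:
    """Combine binary coat/radicle masks into a {0,1,2} label raster."""
    labels = np.zeros(coat.shape, dtype=np.uint8)
    labels[np.asarray(coat, bool)] = 1
    labels[np.asarray(radicle, bool)] = 2
    return labels


# Default YOLO class index mapping; the detector's convention, overridable
# via config (`io.yolo_class_map`).
DEFAULT_YOLO_CLASS_MAP = {0: SeedClass.NON_GERMINATED, 1: SeedClass.GERMINATED}


def load_detections(
    path: str | Path,
    fmt: str,
    image_shape: tuple[int, int],
    class_map: dict[int, SeedClass] | None = None,
) -> list[Detection]:
    """Load seed detections from YOLO-format text or JSON.

    YOLO lines are ``cls cx cy w h [score]`` with center/size normalised to
    the image; JSON is a list of objects with absolute-pixel ``box`` and a
    class name. Boxes are clipped to image bounds; boxes with zero area after
    clipping are dropped with a warning.
    """
    path = Path(path)
    rows, cols = image_shape
    class_map = class_map or DEFAULT_YOLO_CLASS_MAP
    out: list[Detection] = []
    if fmt == "yolo_txt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cls_idx = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:5])
                score = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed YOLO line: {exc}") from exc
            if cls_idx not in class_map:
                raise ValueError(f"{path}:{lineno}: unknown class index {cls_idx}")
            x0 = int(round((cx - w / 2) * cols))
            y0 = int(round((cy - h / 2) * rows))
            x1 = int(round((cx + w / 2) * cols))
            y1 = int(round((cy + h / 2) * rows))
            det = _clip_box((x0, y0, x1, y1), image_shape, class_map[cls_idx], score)
            if det is not None:
                out.append(det)
    elif fmt == "json":
        data = json.loads(path.read_text())
        for i, item in enumerate(data):
            x0, y0, x1, y1 = (int(v) for v in item["box"])
            cls = SeedClass(item["cls"])
            det = _clip_box((x0, y0, x1, y1), image_shape, cls, float(item.get("score", 1.0)))
            if det is not None:
                out.append(det)
    else:
        raise ValueError(f"unknown detection format {fmt!r}")
    return out


def _clip_box(
    box: tuple[int, int, int, int],
    shape: tuple[int, int],
    cls: SeedClass,
    score: float,
) -> Detection | None:
    rows, cols = shape
    x0, y0, x1, y1 = box
    x0, x1 = max(0, x0), min(cols, x1)
    y0, y1 = max(0, y0), min(rows, y1)
    if x0 >= x1 or y0 >= y1:
        logger.warning("dropping zero-area box %s after clipping to %s", box, shape)
        return None
    return Detection(box=(x0, y0, x1, y1), cls=cls, score=score)


def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    """Write detections as the JSON dialect accepted by :func:`load_detections`."""
    data = [
        {"box": list(d.box), "cls": d.cls.value, "score": d.score}
        for d in detections
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def _fmt(v: float | None) -> str:
    return "" if v is None else f"{v:.4f}"


def write_measurements(records: Iterable[SeedRecord], path: str | Path) -> None:
    """Write seed measurements as CSV (floats at 4 decimal places)."""
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MEASUREMENT_COLUMNS)
            for r in records:
                x0, y0, x1, y1 = r.box
                writer.writerow([
                    r.image_id, r.seed_id, r.cls.value, x0, y0, x1, y1,
                    _fmt(r.pixel_length), _fmt(r.ratio), _fmt(r.true_length_mm),
                    ";".join(sorted(f.value for f in r.flags)),
                ])
    except OSError as exc:
        raise IOError(f"cannot write measurements to {path}: {exc}") from exc


def read_measurements(path: str | Path) -> list[SeedRecord]:
    records: list[SeedRecord] = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            records.append(SeedRecord(
                image_id=row["image_id"],
                seed_id=int(row["seed_id"]),
                cls=SeedClass(row["class"]),
                box=(int(row["x_min"]), int(row["y_min"]),
                     int(row["x_max"]), int(row["y_max"])),
                pixel_length=float(row["pixel_length"]),
                ratio=float(row["ratio"]) if row["ratio"] else None,
                true_length_mm=float(row["true_length_mm"]) if row["true_length_mm"] else None,
                flags={SeedFlag(f) for f in row["flags"].split(";") if f},
            ))
    return records


@dataclass
class PipelineConfig:
    """Run configuration for the measurement pipeline.

    ``threshold`` is the Gaussian coat-probability cut T; pixels with
    probability strictly above T are coat, the rest radicle. ``patch_size``
    is the square training-patch side around a centroid. ``diagonal_weight``
    is the skeleton-graph weight of a diagonal step (2 by definition; the
    geometric sqrt(2) is available).
    """

    threshold: float = 0.006
    patch_size: int = 3
    ridge_floor: float = 1e-6
    diagonal_weight: float = 2.0
    denoise_radicle: bool = True
    backend: str = "oracle"
    rng_seed: int = 0
    yolo_class_map: dict[int, SeedClass] = field(
        default_factory=lambda: dict(DEFAULT_YOLO_CLASS_MAP))

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0,1)")
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if self.diagonal_weight <= 0:
            raise ValueError("diagonal_weight must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        classify = raw.get("classify", {})
        skeleton = raw.get("skeleton", {})
        io_cfg = raw.get("io", {})
        if "threshold" in classify:
            kwargs["threshold"] = float(classify["threshold"])
        if "patch_size" in classify:
            kwargs["patch_size"] = int(classify["patch_size"])
        if "ridge_floor" in classify:
            kwargs["ridge_floor"] = float(classify["ridge_floor"])
        if "diagonal_weight" in skeleton:
            kwargs["diagonal_weight"] = float(skeleton["diagonal_weight"])
        if "denoise_radicle" in raw.get("measure", {}):
            kwargs["denoise_radicle"] = bool(raw["measure"]["denoise_radicle"])
        if "backend" in raw:
            kwargs["backend"] = str(raw["backend"])
        if "rng_seed" in raw:
            kwargs["rng_seed"] = int(raw["rng_seed"])
        if "yolo_class_map" in io_cfg:
            kwargs["yolo_class_map"] = {
                int(k): SeedClass(v) for k, v in io_cfg["yolo_class_map"].items()}
        return cls(**kwargs)
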