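"""Five-step measurement pipeline: coarse segmentation, coarse classification,
fine segmentation, fine classification, radicle length.

Per germinated detection:

1. box-prompted coarse segmentation (mask clipped to the box);
2. Gaussian coat model fitted on the patch at the coarse-mask centroid,
   coat/radicle classification of the coarse mask;
3. point-prompted fine segmentation using the coat and radicle centroids
   from step 2 (unclipped — recovers radicle parts outside the box);
4. Gaussian model re-fitted on the patch at the step-2 coat centroid,
   classification of the fine mask;
5. skeleton-graph geodesic radicle pixel length, converted to millimetres
   when a calibration scale is available.

Non-germinated detections receive coat segmentation only and a zero length
with flag ``no_radicle``. Per-seed failures are flagged and recorded; they
never abort the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colorclass, skeletometry
from .calibration import CalibrationScale, to_true_length
from .colorclass import ComponentMasks
from .io_core import (Detection, PipelineConfig, SeedClass, SeedFlag,
                      SeedImage, SeedRecord, masks_to_labels)
from .metrics import MaskPair, segmentation_scores
from .segmentation import SegmenterContract, SeedMask, coarse_segment, fine_segment

import logging

logger = logging.getLogger("lenruler")


@dataclass
class SeedResult:
    """Record plus the intermediate artifacts of one seed's measurement."""

    record: SeedRecord
    coarse_mask: SeedMask | None = None
    coarse_components: ComponentMasks | None = None
    fine_mask: SeedMask | None = None
    fine_components: ComponentMasks | None = None
    measurement: skeletometry.RadicleMeasurement | None = None


def _classify_stage(
    image: SeedImage,
    seed_mask: np.ndarray,
    config: PipelineConfig,
    seed_id: int,
    centroid: tuple[int, int] | None = None,
) -> tuple[ComponentMasks, tuple[int, int]]:
    """Fit the coat Gaussian at a centroid patch and classify the mask.

    When ``centroid`` is None the mask's own centroid is used (coarse
    stage); the fine stage passes the coat centroid from the coarse stage.
    """
    if centroid is None:
        centroid = colorclass.mask_centroid(seed_mask)
    feats = colorclass.sample_patch_features(image, centroid, config.patch_size)
    model = colorclass.fit_gaussian(feats, ridge_floor=config.ridge_floor)
    comp = colorclass.classify_mask(image, seed_mask, model,
                                    threshold=config.threshold, seed_id=seed_id)
    if config.denoise_radicle:
        coat, radicle = _denoise_components(comp.coat, comp.radicle)
        comp = ComponentMasks(coat=coat, radicle=radicle, seed_id=seed_id)
    return comp, centroid


def measure_image_detailed(
    image: SeedImage,
    detections: list[Detection],
    backend: SegmenterContract,
    config: PipelineConfig | None = None,
    scale: CalibrationScale | None = None,
) -> list[SeedResult]:
    """Run the full pipeline, keeping intermediate masks for inspection."""
    config = config or PipelineConfig()
    coarse = coarse_segment(image, detections, backend)

    results: list[SeedResult] = []
    fine_prompts: list[tuple[int, tuple[int, int] | None, tuple[int, int] | None]] = []
    coat_centroids: dict[int, tuple[int, int]] = {}
    for det, cmask in zip(detections, coarse):
        rec = SeedRecord(image_id=image.image_id, seed_id=cmask.seed_id,
                         cls=det.cls, box=det.box, flags=set(cmask.flags))
        res = SeedResult(record=rec, coarse_mask=cmask)
        results.append(res)
        if det.cls is SeedClass.NON_GERMINATED:
            rec.flags.add(SeedFlag.NO_RADICLE)
            continue
        if not cmask.mask.any():
            rec.flags.add(SeedFlag.SEGMENTATION_EMPTY)
            continue
        comp, _ = _classify_stage(image, cmask.mask, config, cmask.seed_id)
        res.coarse_components = comp
        try:
            coat_c = colorclass.mask_centroid(comp.coat)
        except ValueError:
            rec.flags.add(SeedFlag.SKELETON_DISCONNECTED)
            continue
        rad_c = None
        if comp.radicle.any():
            rad_c = colorclass.mask_centroid(comp.radicle)
        coat_centroids[cmask.seed_id] = coat_c
        fine_prompts.append((cmask.seed_id, coat_c, rad_c))

    fine = {m.seed_id: m for m in fine_segment(image, fine_prompts, backend)}
    for res in results:
        rec = res.record
        fmask = fine.get(rec.seed_id)
        if fmask is None:
            if rec.cls is SeedClass.GERMINATED and res.coarse_components is None:
                rec.pixel_length = 0.0
            continue
        res.fine_mask = fmask
        rec.flags |= fmask.flags
        if not fmask.mask.any():
            continue
        comp, _ = _classify_stage(image, fmask.mask, config, rec.seed_id,
                                  centroid=coat_centroids.get(rec.seed_id))
        res.fine_components = comp
        if not comp.coat.any():
            rec.flags.add(SeedFlag.SEGMENTATION_EMPTY)
            continue
        meas = skeletometry.radicle_pixel_length(
            comp.coat, comp.radicle, diagonal_weight=config.diagonal_weight)
        res.measurement = meas
        rec.pixel_length = meas.pixel_length
        rec.flags |= set(meas.flags)
        if scale is not None:
            rec.ratio = scale.R
            rec.true_length_mm = to_true_length(meas.pixel_length, scale)
        logger.info("seed %d: flags=%s l_p=%.2f", rec.seed_id,
                    sorted(f.value for f in rec.flags), rec.pixel_length)
    return results


def _denoise_components(coat: np.ndarray, radicle: np.ndarray):
    """Morphological cleanup after each classification stage.

    Classification leaves salt noise: whenever the 9-sample patch fit lands
    on a low-variance patch, an inflated fraction of coat pixels falls
    below the threshold and lands in the radicle mask, and specks attached
    to the radicle extend its skeleton into the coat and bias the junction
    inward. The radicle mask is opened (3x3 erosion+dilation) and the
    removed pixels returned to the coat — the coat/radicle partition of the
    seed mask is preserved. If opening would erase the radicle entirely
    (very thin radicles) the masks are left untouched.
    """
    from scipy.ndimage import binary_opening
    opened = binary_opening(radicle, structure=np.ones((3, 3), bool))
    if not opened.any():
        return coat, radicle
    return coat | (radicle & ~opened), opened


def measure_image(
    image: SeedImage,
    detections: list[Detection],
    backend: SegmenterContract,
    config: PipelineConfig | None = None,
    scale: CalibrationScale | None = None,
) -> list[SeedRecord]:
    """Measure every detected seed in an image; records in detection order."""
    return [r.record for r in
            measure_image_detailed(image, detections, backend, config, scale)]


def run_threshold_sweep(scenes, thresholds, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Classification-quality sweep over the coat-probability threshold T.

    For each T, every scene's ground-truth seed masks are classified with a
    Gaussian fitted at the coat-centroid patch. Because T only repartitions
    a fixed seed mask between coat and radicle, Dice / IoU / PA are scored
    on the radicle class (the region the threshold controls), averaged over
    scenes; ``iou_rd`` repeats the IoU under its component name. Returns
    one row per threshold.
    """
    config = config or PipelineConfig()
    rows = []
    for t in thresholds:
        scores = []
        for scene in scenes:
            pred = np.zeros(scene.image.shape, dtype=np.uint8)
            gt = np.zeros(scene.image.shape, dtype=np.uint8)
            for seed in scene.seeds:
                gt[seed.radicle_mask] = 2
                union = seed.union
                if not union.any():
                    continue
                cfg = PipelineConfig(threshold=t, patch_size=config.patch_size,
                                     ridge_floor=config.ridge_floor)
                comp, _ = _classify_stage(scene.image, union, cfg, seed.seed_id)
                pred[comp.radicle] = 2
            s = segmentation_scores(MaskPair(pred=pred, gt=gt))
            scores.append(s)
        rows.append({
            "T": t,
            "dice": np.mean([s.dice for s in scores if s.dice is not None]),
            "iou": np.mean([s.iou for s in scores if s.iou is not None]),
            "pa": np.mean([s.pa for s in scores if s.pa is not None]),
            "iou_rd": np.mean([s.iou_rd for s in scores if s.iou_rd is not None]),
        })
    return pd.DataFrame(rows)
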