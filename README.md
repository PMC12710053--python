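# lenruler

Automated radicle-length measurement for germinating seeds from RGB images.

Seed-vigour assays score germination by how far the radicle (the embryonic
root) has grown. Measuring hundreds of seedlings by hand with a ruler is
slow and subjective; `lenruler` automates the measurement from a photograph
of seeds on a dark background plus per-seed detector boxes, and reports each
radicle's length in pixels and — given a calibration object of known
physical size — in millimetres.

## Method

For every detected seed the pipeline runs five steps:

1. **Coarse segmentation** — the detector box is used as a prompt to a
   promptable segmenter (any model satisfying the `SegmenterContract`; a
   ground-truth oracle backend ships for testing). The returned mask is
   clipped to the box, so a long radicle leaving the box is truncated.
2. **Coarse classification** — each pixel of the seed mask is reduced to the
   brightness-invariant chromaticity feature *f* = (R−B, G−B). A Gaussian
   coat model *G* = (*m*, *C*) is fitted on the 3×3 patch at the mask
   centroid (which lies on the seed coat) and every pixel is scored with

   *p*(*f*) = exp[−½ (*f*−*m*)ᵀ *C*⁻¹ (*f*−*m*)].

   Pixels with *p* > *T* (default *T* = 0.006) are coat, the rest radicle.
3. **Fine segmentation** — the coat and radicle centroids are sent as
   foreground point prompts; the returned mask is not clipped, recovering
   the radicle parts outside the box.
4. **Fine classification** — the Gaussian is re-fitted at the coat centroid
   and the fine mask is re-partitioned.
5. **Length measurement** — both masks are thinned (Zhang–Suen) and viewed
   as weighted graphs: vertices are skeleton pixels, 8-neighbour edges weigh
   1 (orthogonal) or 2 (diagonal; √2 available). The radicle length *l*ₚ is
   the geodesic distance between the radicle endpoint farthest from the coat
   skeleton (the tip) and the junction nearest to it.

Calibration: a quadrilateral of known area *S*ᵣ (default one sixty-fourth
of an A4 sheet, 974.53125 mm²) is detected by morphology + Canny + largest
closed contour; its shoelace pixel area *S*ₚ gives the ratio
*R* = √(*S*ₚ/*S*ᵣ) px/mm and *l*ᵣ = *l*ₚ/*R*.

A seeded synthetic-scene generator (`lenruler.synthgen`) renders elliptical
seed coats with Gaussian chromaticity, curved radicles of known arc length,
and the calibration square, with exact ground truth — so the whole pipeline
is testable without any pretrained model.

## Worked example

```bash
printf 'calibration_side_px: 80\ncalibration_side_mm: 20.0\nradicle_mode: straight_axis_aligned\nshape: [320, 480]\n' > scene_cfg.yaml
lenruler synth --seed 3 --config scene_cfg.yaml --out scene/
lenruler calibrate --image scene/scene.png --true-area-mm2 400 --out scale.json
lenruler measure --image scene/scene.png --detections scene/detections.json \
    --backend oracle --scene-dir scene --scale scale.json --out results.csv
```

prints

```
wrote scene with 6 seeds to scene
S_p=6162.5 px^2, R=3.9251 px/mm -> scale.json
measured 6 seeds (6 flagged) -> results.csv
```

and `results.csv` contains one row per seed, e.g.

```
image_id,seed_id,class,x_min,y_min,x_max,y_max,pixel_length,ratio,true_length_mm,flags
scene,0,germinated,192,143,227,168,23.0000,3.9251,5.8598,no_intersection_fallback
scene,1,germinated,376,105,415,132,44.0000,3.9251,11.2100,no_intersection_fallback
```

Seed 0's radicle measures 23 px ≈ 5.86 mm against a generated arc length of
23.75 px (see `scene/ground_truth.csv`); the detected ratio 3.93 px/mm is
within 2 % of the rendered 4.0 px/mm. The `no_intersection_fallback` flag
records that the radicle skeleton was unbranched, so the junction fell back
to the skeleton vertex nearest the coat — the normal case for clean,
unbranched radicles.

`lenruler eval` scores predicted label masks (0 = background, 1 = coat,
2 = radicle) against ground truth with Dice, IoU, pixel accuracy, FPR, the
component IoUs and mIoU; `lenruler sweep` runs the threshold-sensitivity
analysis over *T*.

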