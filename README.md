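# stereotrap

A toolkit for stereo camera-trap image analysis, covering the full desk-scale
chain from rectified stereo pairs to wildlife detection-probability
estimates:

* **`stereo_core`** — sum-of-squared-differences cost volumes over candidate
  disparities, winner-take-all disparity readout (optional sub-pixel
  parabola), and disparity ↔ metric depth conversion via `z = b·f/d`.
* **`quality_metrics`** — RMSE and endpoint error of disparity maps against
  pointwise rangefinder ground truth (both in disparity space), a
  flow-compensated temporal-stability score for disparity sequences, and an
  integer block-matching fallback flow estimator.
* **`frame_sampler`** — fixed-rate frame selection, plus adaptive selection
  driven by a per-pixel Gaussian-mixture background model: the per-frame
  foreground-pixel ratio is accumulated and a frame is emitted each time the
  running sum crosses a threshold (default 0.10).
* **`observation_distance`** — fusion of animal detections (instance masks
  or MegaDetector-style bounding boxes) with depth maps into per-animal
  camera distances; median under masks, lower-half median (robust 25th
  percentile) inside boxes.
* **`ctds`** — camera-trap distance sampling: binning of observation
  distances between left/right truncation (defaults 3 m / 11 m, 7 bins),
  binned multinomial maximum-likelihood fitting of a detection function
  (uniform key with cosine adjustments, or half-normal) under point-transect
  geometry, with AIC, chi-square GOF, and the average detection probability.
* **`synthetic_fixtures`** — seeded generators for textured stereo scenes
  with piecewise-constant ground-truth disparity, motion videos, and
  night-degradation holes; used throughout the test suite.
* **`cli_io`** — PFM/PNG/YAML/CSV/JSON I/O and the end-to-end pipeline.

## Conventions

* Pixel coordinates are `(i, j) = (column, row)`, 0-based. Matching
  searches the right image leftward: the cost at disparity `d` compares
  left column `i` against right column `i − d`.
* The default matching patch is the 1-px-wide, `2c+1`-tall column of the
  SSD definition; `--square-window` switches to a `(2c+1)²` window.
* Invalid pixels (no valid match, zero disparity, out-of-bounds warp) are
  NaN everywhere — in memory and in PFM files (little-endian Middlebury
  dialect).
* Cosine adjustments use the scaled distance
  `r_s = (r − w_l)/(w_r − w_l)`, so `g(w_l) = 1` under left truncation.
* CSVs are UTF-8, comma-separated, with a header row.

## CLI

```sh
stereotrap match --left L.png --right R.png --max-disparity 64 \
    --patch-half-height 1 -o disp.pfm
stereotrap depth --disparity disp.pfm --calib calib.yaml -o depth.pfm
stereotrap eval --pred disp.pfm --calib calib.yaml --gt points.csv
stereotrap eval-temporal --frames 'disp_*.pfm' --fallback-flow --block 16 --range 8
stereotrap sample --frames 'f_*.png' --mode adaptive --threshold 0.10 --burn-in 50
stereotrap distances --detections md.json --depth 'depth_*.pfm' \
    --min-confidence 0.2 -o obs.csv
stereotrap ctds --distances obs.csv --left-trunc 3 --right-trunc 11 --bins 7 \
    --key uniform --cosine-orders 1 --plot fit.png
stereotrap simulate-scene --config scene.yaml -o outdir/
stereotrap run --config pipeline.yaml
```

Calibration YAML needs `baseline_m`, `focal_px`, `image_width`,
`image_height`, and optionally `rectify_left`/`rectify_right` remap-grid
PFM path pairs.

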