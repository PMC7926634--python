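# thermovitals

Contactless vital-sign extraction from radiometric infrared-thermography
video of ICU-style scenes. Given a sequence of per-pixel temperature
frames (°C) and per-frame bounding boxes for `{patient, chest, head,
clinician}`, the package estimates:

- **Respiratory rate** — temporal filtering of chest crops, dense
  optical flow by local polynomial expansion, spatial averaging,
  zero-phase Butterworth bandpass (0.15–0.44 Hz), autocorrelation peak
  picking with parabolic lag refinement and quality/exclusion flags.
- **Body-surface temperature trend** — per-point mean of the per-frame
  head-ROI maximum, with camera/room drift compensated by subtracting a
  corner-ROI ambient estimate before differencing against the first
  measurement point. Only deviations are reported, never absolute
  temperatures.
- **Clinician attendance** — binary presence per frame and a pooled
  percent-present profile over the day with circular interpolation of
  empty bins.

It also ships detector-evaluation metrics (IoU, greedy matching at
IoU 0.5, per-class AP / mAP with all-point interpolation, micro F1,
detection coverage), Bland–Altman / grouped-MAE agreement statistics,
and a seeded synthetic thermal-scene generator with exact ground truth
so the whole stack is testable without clinical data.

## Layout

| module | contents |
| --- | --- |
| `thermovitals.irt_io` | sequence dialects (16-bit multi-page TIFF with scale/offset metadata, CSV stack + JSON sidecar), darknet label parsing, normalization, cropping |
| `thermovitals.detection_eval` | IoU, matching, AP/mAP/F1, coverage |
| `thermovitals.optflow` | polynomial-expansion dense flow (pure numpy/scipy) |
| `thermovitals.respiration` | chest-motion RR pipeline |
| `thermovitals.temperature` | head-temperature trend + regression diagnostics |
| `thermovitals.attendance` | presence series and daily profile |
| `thermovitals.synthetic` | scene generator + detector-output fixtures |
| `thermovitals.agreement` | Bland–Altman, grouped MAE |
| `thermovitals.cli` | `thermovitals` command-line front end |

## CLI

```sh
# render a synthetic scene (sequence + darknet truth labels + truth.json)
thermovitals simulate --config scene.yaml --seed 1 --out scene/ --dialect tiff16

# respiratory rate per analysis window
thermovitals extract-rr --seq scene/sequence.tiff --labels scene/labels --out rr.csv

# head-temperature trend
thermovitals extract-temp --seq scene/sequence.tiff --labels scene/labels --out trend.csv

# clinician attendance profile
thermovitals attendance --seq scene/sequence.tiff --labels scene/labels --out attendance.csv

# detection metrics against ground truth
thermovitals eval-detections --truth scene/labels --pred preds.csv \
    --width 382 --height 288 --out metrics.csv

# agreement of paired estimate/reference CSVs
thermovitals agree --estimates est.csv --reference ref.csv --out agree.json
```

`scene.yaml` mirrors `synthetic.SceneConfig`, e.g.

```yaml
width: 382
height: 288
fps: 4.0
duration: 240.0
noise_sigma: 0.04
chest: {rr_bpm: 15.0, amplitude_px: 1.0}
clinician_events:
  - {start_s: 60.0, end_s: 90.0, overlap_chest: true}
```

## Conventions

Pixel coordinates are 0-based, top-left origin, `y` down; boxes are
half-open `[x_min, x_max) × [y_min, y_max)`. Darknet label class ids
map `{0: patient, 1: chest, 2: head, 3: clinician}`. All randomness
flows through `numpy.random.default_rng` seeds.
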