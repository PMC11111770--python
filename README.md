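# cytoscreen

Slide-level cervical cytology grading from patch-level detections.

`cytoscreen` is a reusable library for building and evaluating a
whole-slide cytology screening pipeline: patch detections (from a
pluggable detector, or the bundled statistically parameterized
simulator) are aggregated into per-slide confidence statistics and
classified into the five TBS 2014 report categories (NILM, ASC-US,
LSIL, HSIL+, AGC) with a random forest. The package also provides the
supporting machinery such a pipeline needs end to end:

- **core** — patch/slide grade vocabularies, the patch→slide grouping
  map (ASC-H/HSIL/SCC → HSIL+), and the nested risk strata
  (ASC-US+ ⊃ LSIL+ ⊃ HSIL+, plus all-abnormal) used for screening calls.
- **tiling** — sliding-window decomposition of a slide with clamped
  final windows and patch→slide coordinate mapping.
- **stain** — stain-density-absorbance (optical density) transform,
  Macenko SVD/percentile stain-matrix estimation, per-image H/E
  component distribution fitting, and bounded uniform stain
  perturbation for color augmentation.
- **detection** — the detector plug-in contract, a simulated detector
  driven by grade-conditioned Poisson rates / class-confusion /
  Beta-confidence profiles, IoU-deduplicating slide-level aggregation,
  and top-k per-class selection for review.
- **classify** — per-class confidence statistics (max/mean/SD +
  confidence-bin proportions, optional counts and glandular fraction)
  and the random-forest slide classifier with severity-aware
  tie-breaking and stratum scores.
- **quality** — thumbnail standardization (short edge 1000 px) and a
  heuristic acceptable/problematic quality report (blur, incomplete
  scan, low cellularity) behind a pluggable contract.
- **evaluation** — per-stratum confusion tables,
  sensitivity/specificity/accuracy/PPV/NPV with Clopper–Pearson exact
  95% CIs, rank-based ROC AUC with stratified-bootstrap CIs, two-sided
  χ² arm comparisons, and prevalence-weighting identities.
- **synthetic** — seeded generators for detection cohorts, two-stain
  Beer–Lambert images with known ground truth, and simulated
  reader / AI-assisted-reader arms.

## Test

```sh
python -m pytest -q tests/
```

## CLI

```sh
cytoscreen simulate --out-dir runs/sim --n-slides 200 --seed 3
cytoscreen features runs/sim/detections.csv --out runs/features.csv
cytoscreen train runs/features.csv runs/sim/manifest.csv --out runs/model.joblib
cytoscreen predict runs/features.csv runs/model.joblib --out runs/preds.csv
cytoscreen evaluate runs/preds.csv runs/sim/manifest.csv --out runs/report.json
cytoscreen qc thumbnail.png
cytoscreen augment img1.png img2.png --out-dir runs/aug --n-augmentations 4 --seed 5
cytoscreen run --out-dir runs/full --n-slides 1000 --seed 17   # end-to-end
```

`run` executes the whole pipeline (simulate → features → 4:1 split →
train → predict → evaluate) and writes a deterministic artifact set
(features CSV, model, predictions CSV, per-stratum report JSON, and a
provenance log with seeds, config hash and library versions). Exit
codes are 0 on success, 2 for configuration errors, and a distinct
nonzero code per stage family.

Detection tables from a real detector can be ingested unchanged as CSV
with columns `slide_id, grade, confidence, x0, y0, x1, y1,
epithelium_score` (or equivalent JSON).

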