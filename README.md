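# milct

Weakly supervised detection of a small tumor inside a small organ from 3D
volumetric images, using multi-instance learning (MIL). The package implements
the full second stage of a two-stage segment-then-classify architecture: it
consumes a volume plus an organ segmentation mask (produced externally, e.g.
by nnU-Net, or taken from phantom ground truth) and produces a patient-level
cancer probability with confusion metrics and a DeLong AUC confidence
interval.

## Pipeline

1. **phantom** — seeded synthetic cohorts: anisotropic-spacing volumes with an
   organ ellipsoid occupying a minority of axial slices and, for cases, a
   smaller high-contrast spherical lesion inside it. NIfTI I/O round trip.
2. **preprocess** — series screening (incomplete series, inconsistent
   spacing/orientation, segmentation-error QA flag; first-failing-reason
   priority), resampling to homogeneous spacing (cubic spline for images,
   nearest-neighbor for masks, output shape `round(shape·old/new)`), and
   global `(x − mean)/sd` intensity normalization with statistics frozen on
   the training cohort.
3. **roi** — organ bounding box with a millimeter margin, organ-bearing axial
   slice detection, and one 2D instance per organ slice (shared in-plane
   crop, bilinear rescale to a common size).
4. **mil** — bags (one per patient, bag label = patient label), pluggable
   feature extractors, K-means pseudo-labeling inside positive bags (the
   cluster farther from the negative-bag instance centroid is labeled 1;
   negative bags bypass clustering), and an instance classifier with an
   average-pool(4×4) → dense(256, ReLU) → dropout(0.3) → dense(2, softmax)
   head trained on the pseudo-labels.
5. **aggregate** — per-bag instance probabilities are summarized into a
   normalized 10-bin histogram (permutation- and duplication-invariant) and
   mapped to a patient probability by a one-hidden-layer (18-unit) network
   with a logistic output; model selection is frozen on the validation split.
6. **metrics** — sensitivity/specificity/accuracy at a threshold,
   Mann–Whitney ROC AUC (ties count ½), DeLong variance with 95% normal CIs,
   and the dice overlap utility (both-empty = 1).
7. **pipeline** — seeded end-to-end orchestration with patient-level
   stratified train/val/test splits; reruns with the same config are
   byte-identical.

Neural components are small seeded NumPy networks (no GPU framework
required); K-means uses scikit-learn, with tiny k=2 problems solved exactly
by partition enumeration.

## CLI

```bash
milct simulate   --config phantom.yaml --out cohort/        # NIfTI studies + labels.csv
milct preprocess --in cohort/ --out resampled/ --spacing 1.0,1.0,1.0
milct run        --config run.yaml --out report.json        # full pipeline
milct evaluate   --pred pred.csv --labels labels.csv        # metrics from CSVs
```

A minimal `run.yaml`:

```yaml
phantom: {n_cases: 30, n_controls: 30, noise_sd: 15.0, seed: 7}
seed: 7
threshold: 0.5
split_fractions: [0.6, 0.2, 0.2]
```

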