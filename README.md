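# bmdetect

Lesion-level detection of brain metastases on contrast-enhanced
black-blood (BB) 3D MRI, evaluated the way radiologists care about:
per lesion, not per slice.

Brain metastases appear as small enhancing foci on contrast MRI. On BB
sequences the signal of flowing blood is suppressed, so enhancing lesions
stand out against dark vessels — but incompletely suppressed vessel
segments remain the dominant false-positive source for automated
detectors. A practical detection framework therefore needs more than a
per-slice detector: 2D detections must be merged into 3D lesions, tiny
single-slice findings must be filtered out, and performance must be scored
per lesion with a false-positive rate per scan, including on a lesion-free
normal cohort.

`bmdetect` implements that full framework:

- **`phantom`** — seeded generator of synthetic BB-like volumes
  (ellipsoidal brain, bright skull rim, spherical enhancing lesions
  ≥ 5 mm, partially suppressed vessel-like tubes, Gaussian noise) with
  exact per-slice ground-truth boxes;
- **`preprocess`** — morphological brain extraction and per-slice min-max
  intensity normalization of brain voxels to [0, 1];
- **`detect`** — a pluggable per-slice detector interface with a
  deterministic reference implementation (threshold, connected components,
  area and circularity gates), plus augmentation transforms and anchor-box
  estimation (k-means under the 1 − IoU distance, 7 anchors);
- **`link`** — the core linking algorithm: boxes on adjacent slices with
  IoU > 0.3 are the same lesion (union-find connected components);
  components confined to a single slice are discarded, because a > 5 mm
  lesion must be visible on ≥ 2 slices at 3 mm slice thickness;
- **`evaluate`** — greedy one-to-one lesion matching (a lesion counts as
  detected if any one of its slices is hit with IoU > 0.5) and the metric
  suite

  ```
  Sensitivity (TPR) = TP / (TP + FN)
  Precision   (PPV) = TP / (TP + FP)
  F1                = 2·TP / (2·TP + FN + FP)
  FP_avg            = FP / N
  ```

  per fold and pooled, with the normal-cohort FP_avg and a reading-time
  reduction summary;
- **`pipeline`** — k-fold cross-validation (default 5): the detector is
  calibrated by grid search on the training folds only, applied to the
  held-out fold, and every calibrated model is applied to the normal
  cohort with the results averaged.

## Worked example

```python
import bmdetect as bd

# 6 lesion-bearing scans (3 lesions each) + 2 normals, moderate noise
cfg = bd.PhantomConfig(n_lesions=3, noise_sigma=0.05, seed=11)
manifest = bd.generate_cohort(6, 2, cfg)
report = bd.run_crossval(manifest, k=2, seed=1)
print({k: report[k] for k in ("sensitivity", "precision", "f1",
                              "fp_avg", "fp_avg_normal")})
```

prints

```
{'sensitivity': 100.0, 'precision': 81.82, 'f1': 90.0,
 'fp_avg': 0.67, 'fp_avg_normal': 0.0}
```

All 18 planted lesions were recovered (sensitivity 100 %); 4 predicted
lesions matched no ground truth (precision 81.82 %, i.e. 0.67 false
positives per scan), and the calibrated models produced no false positives
on the two normal scans. Reports are byte-identical across reruns with the
same manifest and seed.

The same pipeline is scriptable from the shell:

```
bmdetect phantom --n-scans 6 --n-normals 2 --preset bb --seed 11 --out cohort/
bmdetect crossval --manifest cohort/manifest.yaml -k 2 --seed 1 --out results/
```

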