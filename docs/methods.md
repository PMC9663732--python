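# Methods

## The detection problem and the unit of evaluation

Brain metastases are enhancing foci on contrast-enhanced T1-weighted MRI.
Object detectors operate per slice, but the clinical unit is the 3D
lesion: a finding is useful if any part of the lesion is flagged. The
framework therefore separates three concerns — per-slice detection,
2D-to-3D lesion formation, and lesion-level scoring — and treats the
per-slice detector as a pluggable interface so that a learned model can
replace the built-in reference detector without touching anything else.

## Geometry conventions

Boxes are half-open real rectangles `[x, x+w) × [y, y+h)` in 0-based pixel
coordinates (`x` = column, `y` = row), so area is exactly `w·h` and IoU is
computed on continuous rectangles. All thresholds are strict as stated:
linking requires IoU > 0.3, matching requires IoU > 0.5. Volumes are
`(slice, row, col)` arrays with in-plane pixel size and slice thickness in
millimetres; slice order along the third NIfTI axis carries no anatomical
interpretation. Label rectangles are stored in pixel units.

## Phantom generator

Each scan is drawn from a single `numpy` Generator seeded by the
configuration, so identical configurations give bit-identical volumes.
Cohorts derive one independent stream per scan from
`SeedSequence([master_seed, scan_index])`, making generation
order-independent.

The anatomy is deliberately minimal: a smooth ellipsoidal brain of uniform
tissue intensity 1.0 (semi-axes 40 % / 36 % / 40 % of the grid extent), a
bright elliptical shell (intensity 2.0) standing in for the skull,
separated from the brain by a dark gap. Lesions are balls with diameters
uniform on [5, 25] mm (the floor matches the clinical inclusion rule that
lesions smaller than 5 mm are excluded; no distributional claim is made
beyond the floor), rendered at 3.0× tissue intensity. Vessels are
random-walk tubes (radius 0.6–1.6 mm) at 2.8× tissue; under the
black-blood preset 85 % of each tube's length is suppressed to tissue
intensity in random contiguous windows, leaving residual bright segments —
the characteristic false-positive substrate; the "gre" preset leaves the
tubes fully bright, qualitatively mimicking gradient-echo contrast.
Noise is additive Gaussian (default σ = 0.05 relative to tissue 1.0),
added last. This is a simplification of MR physics (noise in magnitude
images is Rician, there are no partial-volume or bias-field effects, and
no anatomy beyond the ellipsoid); the phantom exercises the detection,
linking and evaluation logic, not image realism, so passing tests
demonstrate algorithmic correctness — not clinical performance.

Ground-truth boxes are the exact bounding boxes of each ball's rasterised
cross-section (voxel centres strictly inside the sphere, evaluated at the
slice-centre z), computed before noise. A 5 mm ball centred on a slice
centre can intersect only one 3 mm slice, so lesion centres are
rejection-sampled until the raster covers at least two slices with at
least 4 voxels each — the generator's reading of "observable over two or
more slices". Lesions are pairwise separated by at least 2 mm and placed
so the ball fits inside the brain; exhausting 400 retries per lesion
raises a placement error.

Default grid 256×256×40 at 0.9 mm pixels / 3 mm slices: a half-resolution
version of a 512×512 / 0.45 mm axial reconstruction over the same 230 mm
field of view, chosen to keep a 30-scan cohort run in minutes on one CPU
while preserving every size relation that the algorithms depend on
(`PhantomConfig.paper_geometry()` restores full resolution).

## Preprocessing

Brain extraction is a morphological stand-in for a full brain-extraction
tool, sufficient because the phantom supplies an analytic reference mask:
Otsu threshold → binary opening (3D cross structuring element) → largest
3D connected component → hole filling. Opening is idempotent and the
subsequent steps are fixed points on its output, so extraction of an
already-stripped volume reproduces the same mask. A constant (e.g.
all-zero) volume is an error, not an empty mask.

Normalization maps each slice's *brain* voxels linearly to [0, 1];
background stays 0. Restricting the min/max to brain voxels avoids the
background zeros pinning the minimum and trivialising the map. Slices with
constant brain intensity map to 0 rather than NaN. The map is invariant to
per-slice affine rescaling `a·x + b` (a > 0) of the input. Note the known
side effect of per-slice normalization: on lesion-free scans the brightest
normal structure is stretched to 1.0, which inflates normal-cohort false
positives; this behaviour is reported by the metrics, not corrected.

## Reference detector

Per slice: threshold the normalized intensity (default 0.6) inside the
brain mask, label 8-connected components, gate by area and circularity,
and emit each survivor's tight bounding box with score
`mean intensity × circularity`. Circularity is `4π·area/perimeter²`
(clamped to 1; a component with zero measured perimeter counts as 1) and
rejects elongated vessel residues — a transparent geometric stand-in for
what a trained network learns about vessel morphology. Area gates default
to `[4, 800]` px: the lower gate is the raster area of roughly a 2 mm disc
at 0.9 mm pixels (the visibility floor used by the phantom, so the small
off-equator chord of a 5 mm lesion still passes), the upper bounds the
equatorial disc of the largest generated lesions. The detector refuses
inputs outside [0, 1] rather than silently rescaling.

Calibration replaces network training inside the cross-validation harness:
an exhaustive grid (default thresholds {0.55, 0.65, 0.75} × circularity
gates {0.3, 0.45}) is scored by pooled lesion-level F1 on the training
scans, ties broken by lower FP per scan, then lower threshold. Component
labelling is cached per threshold so the gate dimensions of the grid are
free. The search is deterministic.

Support utilities follow single-shot-detector practice: augmentation is
the 8-element group of axis rotations (0/90/180/270°) and left-right flip,
applied identically to image and boxes (rotation first, then flip); anchor
estimation is Lloyd's k-means on (w, h) under the `1 − IoU` distance of
centred boxes (k = 7 by default), with a seeded farthest-point
initialisation so two-cluster inputs are recovered exactly, centroids as
arithmetic means, and anchors sorted by area. Rotation/flip sampling
probabilities and the anchor algorithm are this package's choices; only
the transform set and the anchor count are inherited from the protocol it
mirrors.

## Linking

Boxes on slices whose indices differ by exactly 1 (no gap tolerance) are
connected when their 2D IoU exceeds 0.3; lesions are the connected
components, computed by union-find and verified in tests against an
explicit-graph oracle. A box may link to several boxes on a neighbouring
slice; all are merged (no one-to-one restriction). Lesion ids are assigned
1..K in order of each component's minimum `(slice, y, x)` key, making the
output invariant to input order. Components spanning fewer than 2 distinct
slices are discarded — for predictions as well as labels, on the argument
that the same visibility rule defines a lesion on both sides; `min_slices`
is exposed for sensitivity analyses. Where source descriptions disagree
("two or more" vs "more than two" slices), the methods-level rule —
two or more — is implemented.

## Matching and metrics

A (ground-truth, predicted) lesion pair is compatible if on some slice a
box of each overlaps with IoU > 0.5. With `one_slice_tp=True` (default)
the pair score is the best single-slice IoU — one hit slice certifies the
lesion; with `False` every ground-truth slice must be hit and the score is
the worst slice. Matching is greedy one-to-one by descending score with
deterministic tie-breaks; one prediction cannot certify two lesions.
Greedy is not guaranteed to equal maximum-cardinality matching on
adversarial inputs, but on geometry where ground-truth lesions are
disjoint a prediction cannot exceed IoU 0.5 with two different lesions on
one slice, and the brute-force oracle test confirms equality on such
instances.

TP/FN/FP are integer counts per scan (TP + FN = number of ground-truth
lesions, always); rates are exact rationals internally and are rounded to
two decimals only when a report is rendered. Undefined rates (zero
denominator) raise rather than returning 0, and cross-validation reports
mark such folds invalid. Pooling sums counts across scans and folds. The
F1 reported is the standard harmonic-mean form `2TP/(2TP+FN+FP)`; a halved
variant `TPR·PPV/(TPR+PPV)` is also emitted, explicitly labelled
`f1_tablestyle`, because some published tables tabulate that quantity
under the F1 heading. Normal-cohort scans have no labels, so every
predicted lesion is a false positive and only FP per scan is reported.
The reading-time utilities (per-rater percent reduction of mean reading
time, their mean, and the two-sided paired t-test) are reporting
conveniences, not contributions.

## Cross-validation harness

Scans are shuffled with a seeded permutation and assigned round-robin to k
folds (sizes differ by at most one; 113 scans at k = 5 give 23/23/23/22/22).
Assignment is random, not stratified by lesion count; stratification would
be a straightforward extension. Per fold, calibration sees only the k−1
training folds; the held-out fold is scored with the calibrated
configuration; all k calibrated models are applied to the normal cohort
and their FP rates averaged. Preprocessing is computed once per scan and
shared across folds (it is scan-local and involves no fitting, so no
information leaks). Reports are byte-identical across reruns for identical
inputs; wall-clock timings go to a separate provenance log so they cannot
perturb report bytes.

## Problem sizes and regression bands

The test suite runs mostly on 96×96×20 phantoms (all size-dependent
invariants are preserved at that scale). End-to-end checks use the default
256×256×40 geometry: a 10-scan noise-free cohort must reach pooled
sensitivity 100 % (every planted lesion recovered), and a 30-scan cohort
at σ = 0.05 must stay within the operating band sensitivity ≥ 85 % and
FP_avg ≤ 20 — a regression guard on the synthetic analogue of the
clinical operating point, not a claim of reproducing clinical performance.
The acceptance script uses 8-scan (noise-free) and 15 + 5-scan (noisy)
cohorts, sizes chosen so the whole script completes in a few minutes on
one CPU.

## Known limitations

- The phantom's simplifications (Gaussian noise, binary-intensity
  anatomy, no partial volume) make detection easier than on clinical
  data; absolute phantom metrics are not comparable to clinical ones.
- The reference detector is a transparent rule, not a learned model; the
  framework's claims concern the linking/evaluation protocol around it.
  An optional learned detector can be plugged in behind the same
  interface.
- Brain extraction assumes a bright rim geometrically separated from the
  brain, as the phantom provides; it is not a clinical skull-stripper.
- Greedy matching is exact only under the disjoint-lesion geometry argued
  above; an optimal-assignment matcher would be the safe generalisation
  if overlapping ground-truth lesions were ever in scope.
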