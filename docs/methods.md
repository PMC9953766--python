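# Methods

## Problem setting

Binary benign-vs-melanoma classification of dermoscopy images, driven by the
irregular pigment network: a reticular pattern whose presence, density and
morphology carry diagnostic weight. The package assumes three aligned inputs
per image: the RGB image, a binary lesion mask (produced upstream; treated
as given), and a binary irregular-network mask (usually predicted by a
segmenter). Cohort metadata carries a `lesion_ID`: several images may show
the same physical lesion, and all data discipline is grouped on it.

## Tiled inference with dihedral TTA

Patch segmenters operate on fixed 448×448 windows. Whole-image prediction
plans patch origins at stride `patch − overlap` = 398 px per axis, clamping
the last origin to `dim − patch` so the final patch abuts the border; images
smaller than a patch are reflect-padded up to 448 and the output cropped
back. Each patch is predicted under all 8 elements of the dihedral group
(horizontal flip × quarter turns), each output passed through the exact
inverse, and the 8 maps averaged. Stitching weights are uniform: a pixel
covered by k patches receives the mean of the k patch values. Windowed
(cosine/Gaussian) weighting was considered and rejected as the default
because uniform averaging is order-independent and lossless on {0,1}
outputs, which makes the oracle-closure property exactly testable.
Thresholding is strict exceedance (`p > 0.5`), so a uniform 0.5 map is
all-negative — ties break toward the benign/background decision everywhere
in the package.

## Segmentation evaluation

TP/FP/TN/FN are pixel counts accumulated over all test images, so images
weigh by pixel count; metrics (precision, recall, F1, specificity,
IoU = TP/(TP+FN+FP), accuracy) are computed once from the accumulated
counts. The false-negative count uses the condition `p=0 ∧ g=1`; a
denominator of zero yields a 0.0 sentinel plus an explicit flag in the
report rather than NaN. Per-image IoU defines empty-vs-empty as 1.0
(identical empties); this convention only affects the per-image mean, never
the dataset-level counts.

## Hand-crafted features (36 values, fixed order)

Objects are 8-connected components of the network mask.

* **Color (18)**: pooled per-pixel mean and population (÷n) SD per CIELAB
  plane (sRGB, D65 white point) over three regions: pixels of objects
  assigned inside the lesion, pixels of objects assigned outside, and skin
  (complement of lesion ∪ network). Pooling over all object pixels (rather
  than averaging per-object means) keeps the statistic well defined when
  object counts vary; this is a deliberate choice where the alternative was
  equally plausible.
* **Counts (4)**: total objects, objects inside, objects outside, objects
  surviving erosion by a discrete disk of radius 3 (a thick-structure
  count: lines thinner than 7 px vanish).
* **Shape aggregates (12)**: mean/SD/max of object area, eccentricity
  (inertia-ellipse definition, 0 for isotropic shapes), length (major axis
  of the inertia-equivalent ellipse — chosen over skeleton path length for
  determinism and consistency with the eccentricity machinery), and width
  (maximum inscribed-disk diameter: 2 × max Euclidean distance to the
  object's complement; an isolated pixel has width 2 by the distance-1
  convention).
* **Densities (2)**: network pixels inside (outside) the lesion ÷ lesion
  area, computed on raw pixel intersections.

Object inside/outside assignment is a pixel-majority vote, since objects may
straddle the lesion border. Empty regions and empty object sets produce 0.0
sentinels so classifier rows stay finite. Features are computed at native
resolution; no rescaling. An empty lesion mask is an error (densities
undefined), not a sentinel.

## Cascade generalization

* **Split**: 30% lesion-grouped hold-out; remaining pool into 5
  lesion-grouped folds. Achieved fractions drift by group-size granularity
  (a ±3 pp drift is normal and mirrored by the tests' tolerance bands).
* **Level-0**: for fold f, a fresh level-0 model is fitted on folds ≠ f and
  scores fold f, giving strictly out-of-fold probabilities for every pool
  record. The default desk-scale level-0 is a logistic regression on 8×8
  downsampled grayscale intensities; real CNN classifiers attach through
  the same `fit/predict_proba` contract.
* **Level-1**: rows are the 36 features plus the level-0 probability (last
  column, length 37). Each fold's rows get a grouped 80/20 inner split; the
  model fits on the 80% with library-default hyperparameters (no tuning);
  the 20% is scored for diagnostics only. SVMs and the neural network are
  preceded by a z-score standardizer fitted on their own training split;
  tree kinds consume raw features.
* **Test time**: the fold-f level-0 model's probabilities feed the fold-f
  level-1 model (pairing preserved from training); the five outputs are
  averaged. A `shared` variant (single averaged level-0 probability fed to
  all five) is available as a config switch. Kinds may be ensemble-averaged
  on top. Decisions use the constant strict-0.5 threshold.

## Classification evaluation

ROC is built over unique score thresholds; AUC by trapezoid. The restricted
AUC for FPR > 0.40 is the raw trapezoidal area of TPR over FPR on
[0.4, 1] with linear interpolation at the cutoff — not McClish-normalized,
so a perfect classifier scores 0.6 and the chance diagonal 0.42; the cutoff
is configurable. Permutation importance is the mean decrease in accuracy
over seeded column permutations (default 10 repeats), evaluated on each
fold's inner validation rows and averaged across folds and classifier kinds;
evaluation on the hold-out test set is available as an option.

## Synthetic data: what it emulates, what it does not

The generator states a world and keeps it fixed:

* **Lesion**: a connected blob (polar radius 1 + smooth ±12% perturbation),
  radius 40–60 px on a 160×160 canvas by default (448+ px canvases for
  inference tests), on a skin-toned background with Gaussian color noise
  (SD 6).
* **Network**: jittered polygonal grid edges (spacing 8–13 px, per-edge
  width 1–3 px) clipped to the lesion dilated by 2 px, added in random
  order until a target coverage fraction of the lesion area is reached —
  realized coverage lands within one edge's area of the target. The spacing
  range is chosen so coverages up to ≈0.35 are realizable. Because grid
  edges touch, the rendered network is typically one large connected
  component — realistic for a reticular pattern, and it means object-count
  features carry less class signal than density features in this world.
* **Class signal**: benign coverage ~ N(0.15, 0.05), melanoma shifted by
  `class_effect` (default +0.10), clipped to [0.02, 0.75].
* **Duplicates**: a configurable fraction of records re-render an earlier
  same-class lesion (identical geometry seed and coverage, fresh color
  noise) under the same `lesion_ID`.
* **Mock level-0**: scores are sigmoid(z + d′·(y − ½)) with z ~ N(0,1)
  keyed deterministically on (seed, image_id) and d′ = √2·Φ⁻¹(AUC), so the
  empirical AUC converges to the target by the binormal identity
  AUC = Φ(d′/√2). The symmetric ±d′/2 placement makes the 0.5 threshold the
  unbiased operating point, emulating a calibrated classifier. Keying z on
  (seed, image_id) makes same-seed fold models perfectly correlated, as real
  fold models of one architecture nearly are; independent fold draws would
  let plain averaging wash out all score noise and overstate the level-0
  ensemble. The mock reads the record's stored label and ignores pixels —
  it is test plumbing for the cascade contract, not a model of images.
* **Mock segmenters**: constant-c; a ground-truth oracle (uses an optional
  location-aware protocol because a patch alone does not identify its crop
  origin); and a darkness-contrast heuristic (local-mean minus pixel
  intensity, min-max rescaled per patch).

Not emulated: hair/ruler artifacts, multi-resolution acquisition, lesion
substructure (globules, streaks), unannotated network mimics, and any
calibrated correspondence to real dermoscopy geometry. A green test on this
world establishes the machinery (contracts, leakage discipline, metric
arithmetic, signal recovery), not clinical performance.

## Numerical conventions

* 8-connectivity for components; population (÷n) SD; sRGB→CIELAB under D65.
* All ties at 0.5 break negative (strict `>`), for both pixels and records.
* Empty-set statistics are 0.0 sentinels; zero metric denominators are 0.0
  with a flag.
* Every randomized stage derives its seed from (master seed, stage label)
  via a CRC-keyed SeedSequence, so pipelines are reproducible end to end
  and stages are independently stable.

## Known limitations

* The feature schema covers every feature named in the source material's
  main tables but an extended appendix list may differ; the schema is fixed
  and versioned by order.
* The default level-0 stand-in (logistic on 8×8 grayscale) is intentionally
  weak; conclusions about cascade gains on synthetic cohorts use the
  controlled-AUC mock instead.
* Desk-scale cohorts (hundreds of 160² images) keep the test suite fast;
  nothing in the implementation depends on that scale.
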