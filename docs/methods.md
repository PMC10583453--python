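# Methods

`gliocam` implements an interpretability pipeline for overall-survival (OS)
classification of glioma patients from volumetric multimodal MRI. This note
documents the models, the parameters that matter, the synthetic data the
package is validated on, and the numerical choices made where the design was
genuinely open.

## Problem and pipeline

Each subject contributes a 4-channel volume (T1, T1-contrast, T2, FLAIR)
co-registered to an anatomical template, a tumor segmentation mask
(necrosis / edema / enhancing tumor), and survival in days. Survival is
converted to months at 30.44 days/month (mean Gregorian month; no conversion
factor is standard in the field) and binned into three ordered classes:
short (< 10 months), medium ([10, 15) months) and long (>= 15 months). The
half-open intervals make the binning total on (0, inf); boundary survivals
fall into the longer class.

The pipeline stages are:

1. **Preprocessing** — tumor masking (all non-tumor voxels zeroed) and
   slice cropping. The full-scale preset crops to a 90-slice working window
   of the 155-slice template (40 inferior slices and 25 superior slices
   removed); the desk-scale default crops a 24-slice grid to 18 slices
   (4 inferior, 2 superior). The retained window is recorded so saliency
   maps can be re-indexed back onto the template.
2. **Classifier** — a small 3D CNN: three blocks of
   convolution (3x3x3, stride 1, "same") -> batch norm -> ReLU ->
   dropout (0.2) -> 2x2x2 max-pool, with 6, 16 and 32 filters, then one
   fully connected layer and a softmax over the three classes. Training is
   SGD with momentum 0.9, mini-batch 16, learning rate 3e-4, with random
   rigid augmentation (in-plane rotation up to +-10 degrees, integer
   translation up to +-5 voxels, zero fill). Loss is cross-entropy. No
   early stopping: the final-epoch model is returned with its loss history.
3. **3D Grad-CAM** — for a target class `c`, the gradient of the
   pre-softmax class score `y^c` with respect to the activations `A^k` of
   the final block's ReLU is globally average-pooled into channel weights
   `alpha_k = (1/Z) sum_ijk dy^c/dA^k_ijk` (`Z` = voxels per feature map);
   the raw map is `H' = max(sum_k alpha_k A^k, 0)`. The map is trilinearly
   resampled (corner-aligned) onto the working grid, averaged over all
   subjects of each class (H_S, H_M, H_L), re-indexed to the template slice
   positions, and masked by the per-slice brain silhouette (template > 0
   with in-plane hole filling). Every stage preserves nonnegativity.
4. **Probability maps** — each class map is min-max rescaled to [0, 1]
   and divided by the equal-weight sum `L_H = H_S + H_M + H_L`, giving
   voxel-wise class-evidence maps with `D_S + D_M + D_L = 1` on the
   support.
5. **Region attribution** — rescaled maps are binarized at thresholds
   {0.1, ..., 0.6} (strict `> th`), overlaid on the parcellation atlas, and
   label-presence sets are combined: regions common to all classes
   (`B = P_S n P_M n P_L`) and unique to each (`B_S = P_S - P_M - P_L`,
   cyclically).
6. **OS prediction** — a new subject's Grad-CAM map (for the CNN-predicted
   class) is rescaled to [0, 1] and matched to each `D_c` by continuous
   Dice, `2 sum min(A,B) / (sum A + sum B)`; the class Dice scores are read
   as per-class probabilities of the event-of-interest and the argmax is
   the predicted class. The thresholded patient map overlaid on the atlas
   yields the textual region-contribution report.
7. **Evaluation** — a threshold sweep reporting the Dice-predictor accuracy
   and, per class, the Spearman correlation between relative tumor volume
   and the binary Dice of tumor mask vs thresholded class map, plus tidy
   per-subject scatter data.

## Synthetic cohort

No public cohort ships with the package; the generator provides a fully
synthetic stand-in whose defaults are the study conditions:

* class sizes 42 / 30 / 46 (short / medium / long) at full scale; the
  default desk-scale pipeline halves them to 21 / 15 / 24 (n = 60),
* survival drawn per class from a truncated normal (floor 1 day) with
  means 157, 369, 761 days and SDs 79, 41, 346; draws falling outside the
  class's month window are redrawn (cap 100) so labels recomputed from
  days always match the requested class. A truncated normal is used
  because the conditions are stated as mean +- SD; the within-class shape
  is otherwise unspecified,
* a brain-silhouette atlas: an axis-aligned ellipsoid partitioned into
  contiguous Voronoi parcels of random interior seeds (12 parcels on the
  default 48x48x24 grid; 56 on the 240x240x155 preset),
* tumors as three concentric axis-aligned ellipsoid shells (necrotic core,
  enhancing rim at 0.7x, edema halo at 1x the edema radius), centered in a
  class-preferred parcel and clipped to the silhouette. Channel intensities
  are class-typical offsets over independent Gaussian noise (sd 0.05):
  FLAIR/T2 bright in edema, T1c bright in the enhancing rim, T1 dark in
  necrosis,
* a planted monotone coupling between tumor volume and survival: the edema
  radius scales as `exp(-coupling * z)^(1/3)` with `z` the within-class
  survival z-score (clipped at +-2.5) and multiplicative log-normal jitter
  (sd 0.10). With the default coupling of 1, larger tumors mean shorter
  survival within every class — the structure the evaluation stage must
  recover; coupling 0 decouples them.

What the generator does **not** emulate: MRI physics and texture, lesion
infiltration patterns, multifocal tumors, anatomically realistic parcel
shapes, class imbalance beyond the given counts, and scanner or site
effects. Passing tests therefore demonstrate that the pipeline's math and
plumbing are correct and that it recovers planted volume/location structure;
they do not certify classifier performance on clinical data.

## Numerical and design choices

* **No autodiff dependency.** The CNN layers carry hand-written backward
  passes (shift-and-matmul convolution adjoints, analytic batch-norm
  gradient, argmax max-pool routing). Correctness is pinned by central
  finite-difference tests at 1e-3 relative tolerance (and observed at
  ~1e-10 in float64).
* **Grad-CAM class score** is the pre-softmax logit (the standard choice;
  gradients of the probability saturate) with a `use_probability` switch.
* **Training-map CAMs** are computed with respect to each subject's true
  class and averaged over *all* subjects of the class, not only correctly
  classified ones; at inference the CAM uses the CNN-predicted class.
* **Resampling** is corner-aligned trilinear interpolation, clamped at 0.
* **Probability-map support**: `L_H` vanishes where all class maps are
  zero; those voxels get `D_c = 0` (not 1/3) under an epsilon of 1e-8 —
  background carries no class evidence. A constant saliency map rescales
  to zeros with a warning.
* **Binarization** is strict (`> th`), so `th = 0` keeps exactly the
  positive-saliency voxels.
* **Set operations** act on label-presence sets (minimum presence: 1
  suprathreshold voxel, configurable), making the subtraction order in the
  unique-region definitions immaterial.
* **Dice** is the continuous min-form on rescaled maps; a binarized
  variant is available (`binarized_dice`). Ties in the class argmax break
  toward the worse prognosis (short > medium > long) and are flagged.
* **Threshold sweep**: the threshold is applied uniformly — class maps and
  the patient map are zeroed below `th` before probability-map
  construction and Dice matching. The `th = 0` row is a no-threshold
  control in which the binary class map is the full brain silhouette `W`;
  since tumors lie inside the brain, Dice = `2V/(V+W)` is strictly
  increasing in tumor volume `V` and the volume-Dice Spearman correlation
  is exactly 1 whenever volumes are distinct. `spearman` short-circuits
  perfect (anti)concordant rank vectors to exactly +-1 so floating-point
  rank summation cannot blur the anchor, uses average ranks for ties, and
  raises on constant input rather than returning a silent 0.
* **Determinism**: every stage seed derives from one master seed via seed
  sequences; training shuffling, dropout masks and augmentation draws all
  flow from the training seed. JSON is written with sorted keys and CSVs
  with a fixed float format, so a rerun with the same configuration is
  byte-identical.
* **Problem sizes**: the default configuration runs the whole pipeline on
  a 48x48x24 grid with 60 subjects and 40 training epochs (a few minutes
  on one CPU); `PipelineConfig.full_scale()` carries the full-scale
  geometry (240x240x155, 118 subjects, crop 40/25, 100 epochs). All
  dimensions, counts and hyperparameters are configurable.

## Known limitations

* The desk-scale CNN sees strongly planted, noise-light signal; accuracy
  numbers on synthetic cohorts say nothing about clinical accuracy.
* A slice-count inconsistency exists in the full-scale crop convention
  (40 + 30 slices removed from 155 leaves 85, yet all downstream shapes
  assume 90); the preset uses (40, 25) to produce the 90-slice working
  grid and both knobs are configurable.
* The atlas stand-in has generic parcel names; region-level findings on
  synthetic data are positional, not anatomical.
* Batch-norm statistics come from small desk-scale batches; inference is
  strictly deterministic but running statistics are noisy for very small
  cohorts.
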