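# Methods

## Problem and scope

The pipeline models a three-way morphological classification of monocytic
cells (monocyte, promonocyte, blast) from single-cell blood-smear patches
with per-cell background/cytoplasm/nucleus masks, ground-truthed by the
consensus of a five-expert review panel. Because clinical images of this
kind are not redistributable, the package ships a synthetic generator that
reproduces the *statistical structure* the analysis depends on; all
quantitative claims made by the test suite therefore concern that synthetic
regime (see "What the synthetic data does and does not show").

## Synthetic cell model

A cell is a mildly eccentric ellipse (axis ratio ∈ [0.85, 1], random
orientation) of nominal radius 70–78 px in a 200×200 patch. The nucleus
boundary is the closed curve r(θ) = r₀(1 + A sin(kθ + φ)) with k ∈ {2..5}
folds; r₀ is solved from the enclosed-area identity
area = π r₀²(1 + A²/2) so the nucleus-to-cell area ratio hits its target,
then the nucleus is clipped to the 2-px-eroded cell so a cytoplasmic rim
always survives. Chromatin is band-limited noise (Gaussian-smoothed white
noise) modulating the nucleus colour; the texture length scale and contrast
are class presets. Class presets are maturity-ordered:

| parameter                  | monocyte | promonocyte | blast |
|----------------------------|----------|-------------|-------|
| nucleus area fraction      | 0.45     | 0.62        | 0.80  |
| boundary folding amplitude | 0.30     | 0.18        | 0.06  |
| chromatin texture scale px | 4.0      | 2.5         | 1.5   |
| chromatin contrast         | 0.35     | 0.22        | 0.12  |

mirroring the morphological criteria used at the microscope: immature cells
have larger, rounder nuclei with finer chromatin. Every jittered parameter
is multiplied by 1 + U(−2j, 2j) where j is the `jitter`
coefficient-of-variation. The bounded support makes separability provable:
at j ≤ 0.05 the three area-fraction supports are disjoint
([0.405, 0.495] / [0.558, 0.682] / [0.72, 0.88]); at large j they overlap,
giving a tunable-difficulty task. Patients contribute small RGB and
brightness offsets (σ ≈ 5 and 4 grey levels) so patient-grouped splitting
is meaningful. Class counts follow largest-remainder apportionment of the
requested proportions, with remainder ties broken toward the larger
proportion. Default proportions are 0.45/0.30/0.25 — monocyte-majority
with minority precursors, the imbalance regime the weighted loss exists
for; no per-class census of the original cohort is available, so this is a
package choice. All generation is a pure function of (parameters, seed).

Reviewer panels are simulated per reviewer from a row-stochastic confusion
matrix P(assigned | true); the designated repeat reviewer's second pass
copies the first label with probability `repeat_consistency` (default 0.9)
and is otherwise redrawn from the same confusion row. Under this model the
first/repeat Pearson correlation has the closed form
r = c + (1−c)·Var_T(E[X|T])/Var(X), which the tests use as an oracle.

## Preprocessing

Configurations 1, 2, 4 mask to the whole cell, 5 to the nucleus, 3 keeps
the raw patch. Decisions that were genuinely open:

- **z-score statistics over foreground pixels only.** Including the zeroed
  background would make the mean/SD depend on cell size, defeating
  standardisation.
- **Geometry before z-scoring (configs 2, 5).** Interpolating z-scored
  values would break the zero-mean/unit-SD contract; centring and resizing
  first lets the contract hold exactly (|mean| < 1e-6, |SD−1| < 1e-6) on
  the delivered pixels.
- **Config 1 renormalises after resizing.** Bilinear interpolation at the
  foreground edge mixes in zero background; re-applying the (idempotent)
  RGB-fraction map restores channel-sum-to-one everywhere.
- Population (n) SD for z-scoring — the standard-score convention.
- Bilinear interpolation for images, nearest-neighbour for masks and
  foreground grids (preserves the label set); after any geometric
  transform, pixels outside the transformed foreground are re-zeroed.
- Raw-pixel configurations rescale 8-bit values to [0, 1].

Centring uses the foreground bounding box (not the intensity centroid);
the crop is scaled isotropically so its longer side fits the target and is
zero-padded to square.

## Classifier

The loss is weighted categorical cross-entropy with w_j = max_k n_k / n_j
applied to each sample's true class — the only reading under which every
class has equal total impact (Σ over class j of n_j w_j is constant).
Probabilities are clipped at 1e-7 before the log. Training uses Adam.

The reference backbone is a from-scratch numpy CNN: a bilinear downsampling
stem to 32×32×3, three blocks of (3×3 same-padding conv → ReLU → 2×2 max
pool) with 8/16/32 channels, global average pooling (the 32-dim feature
vector exposed by `extract_features`), and a softmax head initialised at
small scale so untrained predictions start near-uniform. Max-pool gradient
is split evenly across ties. All randomness (init, batch order) flows from
the spec seed, so loss trajectories are bit-reproducible. The default
learning rate in `TrainingSpec` is 1e-4 — appropriate for fine-tuning large
pretrained backbones; the desk-scale experiments use 1e-3 with 30 epochs
and batch 32, because a 3-block network trained from random initialisation
for a few hundred gradient steps needs the larger step size. Named
published backbones (InceptionV3, ResNet50, Inception-ResNet, VGG16,
DenseNet121) are registered for interface completeness but require a deep
learning framework and raise `BackboneUnavailableError` when selected.

## Evaluation

The 70/10/20 split apportions each class to the three sets by largest
remainder after a seeded shuffle, guaranteeing per-class proportions within
one cell of the targets. Stratified k-fold delegates to scikit-learn's
`StratifiedKFold` (per-class fold counts within 1). Splitting is at cell
level by default, as the class labels are the stratification variable; an
optional patient-grouped mode deals whole patients greedily to the set
furthest below target, trading exact stratification for leakage control.

Precision/recall/F1 are macro-averaged (equal class weight — the natural
convention when the minority classes are the clinically important ones);
a class never predicted contributes precision 0. Summaries are mean ±
sample SD (n−1), reported at 2 decimals. t-SNE uses perplexity
min(30, (n−1)/3) with PCA initialisation and a fixed seed.

Cross-validation trains one model per fold (fold index added to the seed so
folds are independent but reproducible); the 2-class scheme merges labels
*before* training. For already-trained 3-class models,
`merge_predictions` sums promonocyte and blast probabilities instead.
Collapsing truth and prediction simultaneously can only preserve or gain
correct predictions, so 2-class accuracy ≥ 3-class accuracy whenever the
comparison is made on the same predictions — the structural reason the
merged task scores higher.

## Agreement

Consensus is the plurality label; ties go to the least mature tied class
(blast over promonocyte over monocyte — the conservative direction for
blast-equivalent counting) and are flagged so analyses can drop them.
Pearson correlations are computed on the maturity-ordered numeric encoding
0/1/2 (the three classes form an ordinal maturation scale; the encoding is
an explicit, swappable parameter). The correlation matrix includes the
repeat-pass column and optionally the consensus reference; constant columns
yield NaN with a warning rather than an arbitrary value.

## Problem sizes and numerical choices

The shipped experiments use 300 cells / 5 folds / 30 epochs for the
cross-validation study and 935 cells for panel simulations — sizes chosen
so a full run completes in minutes on a single CPU while keeping ≥ 45
cells of the rarest class in every training fold. Degenerate inputs are
guarded explicitly: empty mask regions, < 2 foreground pixels for
z-scoring, constant channels (map to zero), classes absent from training
labels, constant label columns in correlations.

## What the synthetic data does and does not show

Passing tests demonstrate that the *pipeline* is correct: losses match
independent oracles, preprocessing contracts hold, splits stratify,
training recovers classes that are separable by construction, and the
2-class ≥ 3-class ordering emerges as predicted. They do not show that the
reference CNN would reach any particular accuracy on real smears: real
monocytic cells differ by stain variability, overlapping morphology
(particularly promonocytes), debris and neighbouring cells, focus
variation, and inter-patient heterogeneity far beyond the colour offsets
modelled here. Synthetic class overlap is controlled by one scalar
(`jitter`), which is a caricature of real ambiguity. Accordingly, published
full-scale accuracies are out of scope; the acceptance layer instead checks
in-table aggregate reproduction, oracle equivalences, invariants, and
synthetic recovery.

## Known limitations

- Only the reference backbone is trainable in this distribution; published
  ImageNet backbones need an external framework.
- The generator renders one cell per patch; no multi-cell fields, no
  red-cell background clutter (config 3 therefore differs from configs 1–4
  less than it would on real data).
- Reviewer noise is conditionally independent given the true class;
  real experts disagree in correlated, cell-specific ways.
- Pearson on ordinal labels is encoding-dependent; chance-corrected
  statistics (Cohen's/Fleiss' κ) are not implemented.
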