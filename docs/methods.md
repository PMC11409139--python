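# Methods

## Problem setting

Semantic segmentation of ovarian-tumor ultrasound assigns every pixel one of
nine classes: eight tumor/ovary annotation classes — chocolate cyst (CC),
serous cystadenoma (SC), teratoma (T), theca cell tumor (TCT), simple cyst
(SCH), normal ovary (NO), mucinous cystadenoma (MC), high-grade serous
cystadenoma (HGSC) — plus the ultrasound background (B). Several trained
networks typically disagree pixel-by-pixel, and each has distinct per-class
strengths (one segments HGSC comparatively well, another MC and SCH). The
package implements a principled way to (a) combine several predictors' hard
label masks into one, and (b) select which subset of predictors to combine.

## Decision fusion

Each predictor i carries a per-class quality weight `w(i, j)` — by default
its per-class IoU (Jaccard index, `TP / (TP + FP + FN)`) measured on a
weight-fitting split. For an input pixel where predictor i voted class
`v_i`, the fused score of class j is

```
score(j) = Σ_i  w(i, j) · [v_i = j]
```

and the fused label is `argmax_j score(j)` — soft voting over hard
decisions, where a vote counts for exactly what its caster has demonstrated
on that class. The weight metric is pluggable (any per-class metric table
can be adopted as the weight matrix); IoU is the default.

Two degenerate cases are undefined by the argmax alone and are resolved by
explicit deterministic policy:

* **Ties** (several classes share the maximal score): the lowest class id
  wins by default; a full precedence order over classes can be configured
  instead (`precedence:NAME,NAME,...`). Determinism and reproducibility are
  prioritised over any heuristic.
* **All-zero scores** (every voter has weight 0 for its voted class): fall
  back to plurality over the raw votes, then the same tie policy. This only
  arises with degenerate weight matrices, but leaving it undefined would
  make fusion partial.

The contract is pixelwise; the implementation is vectorised but required —
and tested — to be bit-identical to the per-pixel definition. Useful
consequences, asserted as properties: the fused mask is invariant to
predictor permutation and to positive rescaling of the weight matrix;
raising `w(i, j)` never flips a pixel away from j where predictor i voted j;
a predictor whose weight row strictly dominates the sum of all other rows
reproduces its own decision mask.

One algebraic nuance: when all predictors share an *identical* weight row,
`score(j) = w_j · n_votes(j)`, which equals raw plurality voting only if the
shared row is also flat across classes — a non-constant shared row still
modulates the argmax (two votes on a 0.1-weight class lose to one vote on a
0.9-weight class). The test suite checks plurality equivalence with flat
shared rows and checks non-flat shared rows against the weighted pixelwise
oracle.

Percent-valued weight tables are divided by 100 on ingestion; fractions in
[0, 1] are the single internal convention (the argmax is scale-invariant, so
this is cosmetic but avoids mixed units). Undefined (NaN) metric cells become
weight 0: a predictor never evaluated on a class gets no say in it.

## Metrics

All metrics are computed from one pooled K×K pixel confusion matrix per
predictor (dataset-wide, not per-image averaged — one number per predictor
per class). `IoU = TP/(TP+FP+FN)`, `F1 = 2TP/(2TP+FP+FN)`,
`PREC = TP/(TP+FP)`, `RECALL = TP/(TP+FN)`. A 0/0 metric is *undefined*,
carried as NaN, reported as missing, and excluded from aggregates — never
coerced to 0 or 1, which would silently bias weighted means. The
"correctly-identified-pixels" percentage is defined as the recall-style
diagonal-over-row-sum (the definitions coincide algebraically).

Ensembles are ranked by **weighted IoU**: the per-class IoU averaged with
ground-truth pixel-frequency weights from the evaluation split. Lesion
classes occupy a small fraction of pixels relative to background, and the
frequency weighting matches the aggregate's stated purpose — compensating
class imbalance at the pixel level. Which split supplies the frequencies is
a config choice; the evaluation split is the default.

## Ensemble subset search

With n predictors there are `2^n − 1 − n` subsets of size ≥ 2 (26 for
n = 5). The search is exhaustive: every subset is fused image-by-image with
its members' weight rows, confusion is pooled over the whole split, and
subsets are ranked by weighted IoU, descending, with ties preferring the
smaller subset and then lexicographic member order (cheaper ensembles first;
fully deterministic reports). Individual predictors can be appended to the
ranking for reference but are never selected as "best". No pruning heuristic
is applied — at realistic n the enumeration is trivially cheap.

The weight matrix is estimated once on a weight-fitting split and reused
(row-restricted) for every subset. By default the evaluation split doubles
as the weight-fitting split, which is convenient but optimistically biased;
`DecisionFusionEnsemble` accepts a separate weight split for honest
selection, and the API documents the leakage.

## Data handling

* Masks are single-channel 8-bit PNGs whose pixel values are class ids —
  lossless and catalog-independent; display colors live only in the catalog.
* Raw binary {0, 1} lesion masks are lifted into the 9-class space using the
  per-image metadata class (0 → background id, 1 → that class).
* Resizing of label masks is nearest-neighbor only, implemented by floor
  index mapping (`src_idx = tgt_idx · src_size // tgt_size`): deterministic
  and incapable of inventing labels, which any averaging interpolation would
  do. The conventional adapted frame is 900 × 600 (width × height,
  configurable).
* Train/val/test splitting is stratified per lesion class: within each
  class, ids are seed-shuffled and allocated by largest-remainder rounding,
  so each split's per-class count is within 1 of fraction × class-total.
  Rounding ties go to the earlier split (train, then val, then test).

## Synthetic studies

The simulator stands in for trained networks so the entire pipeline runs in
seconds with no GPUs or clinical data.

* **Ground truth**: 300 × 200 frames (the 3:2 aspect of 900 × 600 adapted
  scans at a ninth of the pixel count — chosen to keep full studies at
  desk-scale runtimes), one elliptical lesion per image by default with
  semi-axes 20–60 px, lesion class drawn from a configurable mix (uniform
  over the 8 tumor classes by default). One lesion per image mirrors the
  structure of single-tumor annotated scans.
* **Predictors**: a profile is a K×K row-stochastic confusion matrix Q
  (row = true class, column = emitted class) plus a boundary-jitter radius.
  Per image, lesion regions are first grown/shrunk by a seeded amount up to
  the radius (contour disagreement), then every pixel's emitted label is
  drawn independently from the Q row of its jittered true label.
  `specialist_profile` builds the archetypal error structure: high diagonal
  on designated strong classes, low elsewhere, with missed lesion mass going
  to background and a small uniform false-lesion rate from background.
* **Calibration**: by construction the empirical confusion of a simulated
  predictor converges to its Q; at ≥ 10⁵ pixels per class the per-entry
  deviation is below 0.01 (binomial concentration), which the tests measure.
* **Determinism**: all draws derive from one root seed with fixed per-stream
  keys (ground truth / jitter / labels, keyed by image index; predictor
  streams keyed by predictor index), so adding a predictor never perturbs
  existing masks.

What the model does *not* emulate: spatially correlated errors, ultrasound
texture, multi-lesion interactions, or the specific encoder architectures.
Per-pixel independent noise was chosen deliberately — it admits closed-form
expectations and makes every fusion/search contract testable. Passing tests
therefore demonstrate the correctness of the fusion and selection machinery,
not the clinical performance of any particular network ensemble.

The bundled demo study (two disjoint-class specialists plus a mediocre
generalist) is a designed recovery experiment: the exhaustive search should
select an ensemble containing both specialists and beat every individual
predictor's weighted IoU — the qualitative signature that motivates fusion,
where a weaker-overall predictor still improves the ensemble through its
per-class strengths.

## Reference benchmark data

`segfuse.published` embeds, as input data, the published per-class IoU table
of five DeepLabV3+ variants (ResNet-18/50, InceptionResNet-V2, MobileNet-V2,
Xception) trained on the MMOTU 2-D ovarian-ultrasound dataset, and the
published weighted-IoU ranking of the top fusion ensembles (best ensemble
91.18 %, best individual 84.58 %). These figures drive worked examples and
consistency checks (ranking gaps, counts of ensembles beating the best
individual); reproducing them from scratch would require the clinical
dataset and GPU training, which is out of scope. One documented discrepancy:
the published subset-count prose states 27 experiments for five networks,
while the counting formula `2^5 − 1 − 5` (and explicit enumeration) gives
26; the package follows the formula.

## Numerical and degenerate-input choices

* Metric denominators of zero ⇒ NaN, handled as above; weighted IoU raises
  if a positive-weight class has undefined IoU (cannot happen when weights
  come from the evaluation split's own frequencies).
* Score ties are exact floating-point equality ties; with measured IoU
  weights these essentially occur only at all-zero scores or duplicated
  weight rows, both covered by policy.
* Empty studies, misaligned image-id sets, dimension mismatches, foreign
  pixel values (with value and location), and non-row-stochastic profiles
  all fail fast with named offenders.

## Problem sizes used in the checks

Unit and property tests run on 8×8 to 16×16 masks with up to 5 predictors;
the end-to-end recovery study uses 200 images at 300×200 with 3 predictors;
simulator calibration uses 1.2 × 10⁵ pixels per class. These sizes give
sub-minute suites while keeping every statistical margin (binomial
concentration at 10⁵ pixels, coverage at 200 images) comfortably sharp.

## Known limitations

* Fusion operates on hard decisions only; per-pixel confidence/softmax
  fusion and learned fusion weights are out of scope.
* The default weight-fitting split equals the evaluation split (documented
  leakage); pass separate splits for unbiased selection.
* Exhaustive search scales as 2^n; no preselection heuristic is provided.
* No boundary-distance metrics (e.g. Hausdorff), per-image metric
  distributions, or significance tests between predictors.
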