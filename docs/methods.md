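# Methods

`mesograph` scores every detected cell of a tissue-microarray (TMA) core
on an epithelioid ↔ sarcomatoid axis using only core-level subtype
labels. This note documents the model, the synthetic data the package is
validated on, and the numerical and design choices a maintainer should
know about.

## Problem formulation

A core is a *bag* B = {X_1, …, X_{n_B}} of cells; each cell carries a
feature vector X_i. Training labels exist only at core level:
epithelioid (E), biphasic (B), sarcomatoid (S). Because biphasic tumours
contain both components, the label is treated as *ordinal* along the
sarcomatoid axis: E = 0, B = 1, S = 2 for the sarcomatoid-positive task,
and symmetrically S = 0, B = 1, E = 2 for the epithelioid-positive task
(the two task labels always sum to 2). This is multiple-instance
learning with ordinal bag labels rather than the classical binary
formulation.

## Cell graphs and features

Cells become nodes; two cells are joined when their centroids are within
30 µm (boundary inclusive — the choice is arbitrary at a set of measure
zero but fixed for reproducibility). Coordinates are physical (µm);
image resolution enters only once, through the microns-per-pixel of the
rendering, so the 30 µm graph radius and 50 µm smoothing kernel are
resolution independent.

The canonical per-cell schema has 129 features:

| group | count | content |
|---|---|---|
| shape | 10 | area, perimeter, circularity 4πA/P², max/min caliper diameter, for nucleus and whole cell |
| intensity | 18 | mean / median / population SD of the hematoxylin and eosin OD channels over nucleus, cytoplasm, whole cell |
| smoothed | 29 | shape+intensity smoothed over nearby cells with a Gaussian kernel (support diameter 50 µm, σ = 12.5 µm, truncated at 25 µm, self included), plus the nearby-detection count |
| delaunay | 33 | Delaunay neighbour count, edge-length mean/median/min/max, neighbourhood means of shape+intensity over {v} ∪ N(v) |
| haralick | 39 | 13 classical GLCM statistics × {H, E, total-OD} channels on a 15 µm-radius disc around the centroid |

An optional `deep` group appends a 512-dimensional embedding of the
72×72 RGB patch centred on each cell. The default backbone is a
deterministic seeded random-projection embedder (a stable, fast stand-in
with the standard 512-wide interface); any callable mapping a (72, 72, 3)
patch to a vector — e.g. a pretrained CNN — can be plugged in. The deep
group is off by default and the recovery experiments below do not use it.

Stain separation uses the fixed Ruifrok–Johnston H&E optical-density
matrix: OD = −log10((I+1)/256), concentrations by pseudo-inverse
projection, negatives clipped at 0. Haralick configuration: 32 grey
levels scaled per-region min–max, distance 1 px, 4 directions, symmetric
normalised GLCM; correlation (and the information measures) are defined
as 0 for zero-variance regions. Feature columns are z-scored with
statistics fitted on training cores only.

## Network

With h_v^(0) = X_v (width d₀ = 129 by default):

* layer 1 is purely local: h_v^(1) = f_Θ1(X_v);
* layers k = 2…K are EdgeConv updates
  h_v^(k) = (1/|N_v|) Σ_{u∈N_v} f_Θk([h_v^(k−1) ‖ h_v^(k−1) − h_u^(k−1)]);
* the per-cell representation is the jumping-knowledge concatenation
  [h_v^(1) ‖ … ‖ h_v^(K)].

Defaults: K = 5 layers of width 10 (JK width 50). Every f_Θ is an MLP
with one hidden layer of the output width, ReLU hidden activation,
linear output. Isolated nodes aggregate over the self pair (difference
zero) so every cell is scored. Biases are initialised with small random
values (σ = 0.01) so no ReLU unit starts exactly on its kink; weights
use He initialisation.

Two sigmoid branches score each cell:
z_v^(s) = σ(α_s · f_Θs(JK_v) + β_s), and symmetrically z_v^(e). The
scalars α and β are produced per core by small MLPs (one hidden layer,
width 16) from the core-level feature mean X̄, letting the model
calibrate each core; α-networks are initialised near 1 and β-networks
near 0 so training starts from the unmodulated branch. The gain is
constrained positive, α = softplus(f_α(X̄)): left unconstrained, the
gain network can act as a bag-level shortcut classifier (strongly
negative α on epithelioid cores, positive on sarcomatoid, near zero on
biphasic), which leaves within-bag cell polarity unidentified exactly
where cell-level resolution matters — some trained folds then score
sarcomatoid cells *below* epithelioid ones inside biphasic cores while
still ranking bags perfectly. Restricting calibration to positive
rescaling removes this unidentifiability without reducing the
expressiveness needed for bag ranking (β is unconstrained). The bag score is
Z = mean_v (z_v^(s) − z_v^(e)) ∈ (−1, 1); negative is
epithelioid-like, positive sarcomatoid-like. The per-cell difference
z_v^(s) − z_v^(e) is the exported cell score.

## Training

The pairwise ranking hinge
L = Σ_i Σ_j max(0, 1 − (Y_i − Y_j)(Z_i − Z_j)) is summed over ordered
pairs within a batch whose labels differ (equal-label pairs contribute a
constant 1 with zero gradient and are omitted from the reported loss).
Each head is ranked on its own bag score (Z_s for the S task, Z_e for
the E task); the combined Z is used only for prediction. Note the loss
has a positive floor: per-head bag scores are means of sigmoids and live
in (0, 1), so adjacent-class pairs can never fully clear the margin of
1 — the loss approaches its floor while the induced ranking becomes
perfect.

Optimisation: Adam (β₁ = 0.9, β₂ = 0.999), decaying triangular cyclic
learning rate from 2×10⁻⁵ up to a per-cycle peak and back, cycle length
50 epochs, first peak 1×10⁻⁴, peak decaying by 0.8 per cycle; up to 500
epochs (300 in the recovery experiments) with early stopping. Batches
hold 8 bags; ranking pairs are formed within a batch.

Cores available for training are split 75/25 into train and validation,
stratified by subtype so both splits see every class (an unstratified
split of a small cohort can leave the validation AUROC undefined). The
checkpoint with the best validation AUROC (B+S vs E on Z) is kept;
AUROC ties — common once the ranking saturates on easy synthetic data —
are broken by the validation ranking loss so score margins keep
improving. Early-stopping patience is 50 epochs.

The network and its gradients run on a small in-package reverse-mode
autodiff over NumPy (`mesograph.autodiff`); analytic gradients are
property-tested against central finite differences on toy graphs.

## Evaluation protocol

Hold-one-slide-out cross-validation: each fold's test set is every core
of one slide; cores of patients represented on the held-out slide are
excluded from that fold's training pool entirely, so no patient ever
straddles train/val and test. Bag metrics (AUROC, average precision,
sensitivity/specificity at Z > 0) treat B and S cores as positive
against E. On synthetic cohorts the instance-recovery AUROC compares the
per-cell score with the planted class, pooled over the cells of biphasic
bags only — biphasic bags are where instance resolution matters and
where the bag label alone cannot explain a correct answer.

## Synthetic cohorts

No public mesothelioma TMA data ships with the package; a generator
emulates the study conditions end to end. A core is a hard-core
(minimum-spacing) point pattern inside a disc (default 500 µm diameter,
150–300 cells), each cell an ellipse rendered in a Beer–Lambert H&E
colour model with seeded multiplicative chromatin texture, so stain
deconvolution and texture features are exercised honestly. Phenotype
defaults (free parameters of the generator, fixed once):

* epithelioid — nucleus area 40 ± 8 µm², eccentricity 0.35 ± 0.12,
  H-stain 0.55 ± 0.06, texture contrast 0.06;
* sarcomatoid — nucleus area 60 ± 15 µm², eccentricity 0.85 ± 0.07,
  H-stain 0.75 ± 0.08, texture contrast 0.14, and 1.1× the minimum
  centroid spacing (a more dispersed pattern).

These encode the qualitative differences that define the subtypes —
sarcomatoid nuclei larger, more elongated, denser chromatin — without
claiming quantitative fidelity to any measured distribution.

Biphasic cores place their sarcomatoid component in a circular segment
covering a ρ fraction of the core area (ρ drawn uniformly from
[0.3, 0.7] per B core), because biphasic mesothelioma presents
regionally separated components rather than salt-and-pepper mixtures of
single cells; a `mixed` arrangement remains available in `CoreSpec` for
stress-testing. E cores draw ρ from [0, 0.05] and S cores from
[0.9, 1]. Cores are assigned round-robin to slides and grouped into
two-core patients within a slide.

What the generator does *not* emulate: realistic chromatin/tissue
appearance, touching or overlapping nuclei, segmentation errors,
stromal and immune cells, staining batch effects across slides, or
class-imbalanced cohorts. Passing the recovery experiment therefore
shows that the architecture, loss and protocol can recover bag- and
cell-level structure from bag labels under clean conditions — not that
the pipeline reaches any particular accuracy on clinical material.

## Recovery experiment (the package's core validation)

Simulate 90 bags (30 E / 30 B / 30 S, 150–300 cells, 3 slides, fixed
seed), extract the 129-feature schema (no deep group), run the full
3-fold hold-one-slide-out protocol with default model and training
configuration capped at 300 epochs. Expected behaviour, all computed by
`scripts/acceptance.py` and asserted in the test suite: pooled held-out
bag AUROC ≥ 0.95, pooled instance AUROC within biphasic bags ≥ 0.85, and
strict ordering of mean bag scores S > B > E. The run takes roughly 6
minutes on one CPU; problem sizes were chosen so the whole validation
suite stays desk-scale.

## Eigen-cell morphology analysis

To characterise what a trained model rewards, the top-scoring decile of
cells from S cores and bottom decile from E cores (ties at the boundary
broken toward the lowest index) are cropped to 72×72, rotated so the
nucleus major axis (from exact polygon second moments) is vertical,
masked to the cell polygon dilated by 2 µm, reduced to the hematoxylin
channel, and decomposed by PCA. Components are orthonormal with
nonincreasing explained variance and are sign-fixed so each component's
largest-magnitude pixel is positive. Images are rotated with bicubic
interpolation and masks with bilinear interpolation thresholded at 0.5,
which keeps the aligned output stable to ~10⁻³ mean absolute intensity
under re-orientation of a symmetric cell. The 180° ambiguity of an axis
is resolved by reducing angles modulo π; flipped copies are not added.

## Known limitations

* The published feature total (157) is under-determined by its group
  descriptions; the canonical 129-column enumeration here is documented
  and counted in code but makes no claim to match the original
  enumeration exactly.
* The default deep backbone is a random projection, not a pretrained
  CNN; it preserves interface and determinism, not ImageNet semantics.
* Training is single-CPU NumPy; fine for ~100-bag cohorts, not for
  whole-slide-scale graphs.
* Evaluation is per-core; no aggregation of multiple cores per patient
  is attempted.
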