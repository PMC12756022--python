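# Methods

## Problem setting

`habmil` classifies a subject from three co-registered structural MRI
volumes (T1w, T2w, FLAIR) using only a subject-level binary label — the
weakly supervised, multiple-instance-learning (MIL) formulation used for
imaging-genomic problems such as predicting IDH mutation status in glioma,
where voxel-level lesion annotations are expensive and the diagnostic
signal is carried by a small part of the volume.

A subject's volume is a *bag*; the spatial cells of the encoder's final
feature grid are its *instances* x₁…x_N with hidden labels yᵢ. The bag
label follows the standard MIL assumption

    Y = 0  if Σᵢ yᵢ = 0,   else 1,

and training minimizes the empirical bag-level risk
(1/m) Σᵢ l(h_f(Xᵢ), Yᵢ) with l = binary cross-entropy (the natural choice
for a sigmoid bag head; any per-bag loss would fit the same frame).
Instance labels are never used for fitting — only for evaluating
localization on synthetic data, where they are known by construction.

## Model

The pipeline per subject is

    volume (3, X, Y, Z)
      → 3D CNN instance encoder → N×D instance features + N×3 coordinates
      → positional encoding + fusion (CLE)    [optional]
      → MIL pooling (DGA or a baseline)       → bag embedding z
      → affine + sigmoid                      → bag probability

Everything after the encoder treats the bag as a set, so the bag
probability is permutation-invariant by construction; position enters only
through the explicit coordinate channel.

### Instance encoder

Each stage is 3×3×3 convolution (stride 1, zero "same" padding) → batch
normalization → ReLU → 2× max pooling → dropout. The full-scale
configuration uses stage channels (32, 64, 64) and a final 1×1×1
projection to D = 64; on a 240×240×155 input the grid after three pooled
stages is 30×30×19, and an adaptive max pooling lands exactly on the
2×2×2 instance grid, giving the published 2×2×2×64 feature-map geometry.
Adaptive pooling is required because 155 is not a power-of-two multiple
of the target; its bins are the floor partition
edge(i) = ⌊i·size/bins⌋, with remainder voxels absorbed into the last
bin so the receptive cells tile the input without overlap or gap. Each
instance's coordinate is the normalized center of its receptive cell.

The desk-scale preset — stage channels (4, 8, 16), D = 32, 4×4×4 grid on
48×48×32 volumes — keeps a single training run in the tens of seconds on
one CPU core while preserving the architecture's structure. Stage count
and channel growth beyond the first stage (32) are free design choices;
we use the shallowest progression consistent with the printed geometry.
Dropout defaults to 0.25 at full scale and 0.1 at desk scale (the small
phantom networks underfit with heavier dropout). Parameter counts are not
matched to any published total, since the backbone beyond these
constraints is under-determined.

### Collateral location encoding (CLE)

Coordinates p ∈ [0,1]³ are encoded by a learnable two-layer GELU network

    F̂(p) = a₂ · GELU(a₁ · p + b₁) + b₂        (d_pos = 16, hidden 32)

GELU rather than ReLU because coordinates are continuous and the encoding
should be smooth in them. The instance features F and the encoding F̂ are
each standardized per feature across the bag's instances (zero mean, unit
variance, ε = 1e-6) and concatenated row-wise, H′ = [Norm(F) ‖ Norm(F̂)];
the normalization makes the wide appearance block and the narrow location
block scale-commensurate, which is the point of normalizing before
concatenation. CLE then applies an adaptive importance weighting

    A = softmax(W H′ + b)   (one scalar score per instance,
                             softmax over the instance axis, ΣA = 1)
    O = H′ ⊗ A

Two open details are resolved as follows: the softmax axis is the
instance axis (weights that "sum to 1" are only meaningful across
instances), and W maps each fused row to a single scalar (a vector-valued
score would make A a matrix whose rows no longer sum to one across
instances; the scalar variant is the minimal consistent reading, and the
module keeps the vector variant available through its `score` layer
width).

Comparators: `spe` concatenates fixed sin/cos features at dyadic
frequencies (2^k, k < 3, 18 dims); `npe` is the GELU network without the
importance weighting; `none` feeds raw features to the pooling. These
isolate, respectively, the value of learnability and of the weighting
stage.

### Learnable SVD (LSVD)

The gate of the dynamic pooling is built on a low-rank reconstruction of
an instance-affinity matrix:

    α = softmax_rows(X W_a + b_a)   (one shared projection, W_a ∈ R^{d×r})
    Â = α · diag(σ) · αᵀ            (σ ∈ R^r trainable, initialized to 1)

Softmax is applied row-wise so each instance carries a normalized mixture
over r latent components; r defaults to 4 and must satisfy r ≤ min(N, d).
Because the same projection produces both factors, Â is symmetric — an
instance-affinity matrix, which is why the layer reconstructs an N×N
object rather than an N×d one. Two caveats are deliberate:

* Softmax factors cannot be orthogonal, so the construction is
  SVD-*inspired* — a learnable low-rank re-weighting — rather than an
  exact SVD; the classical decomposition motivates the parameterization
  but is not enforced.
* The Eckart–Young theorem still bounds it: no rank-r reconstruction can
  have smaller Frobenius error than the truncated exact SVD. The test
  harness asserts this bound on every fit.

`fit_to_matrix` exists purely as a test harness: it gradient-trains
(W_a, b_a, σ) with Adam to reconstruct a given matrix from X = target.
For oracle-gap tests the targets are random Gaussian-kernel affinity
matrices of points in the unit cube (bandwidth 0.3) — symmetric,
nonnegative, and of the affinity type the layer is designed to model; on
these the fit lands within a few percent to ~16% of the Eckart–Young
optimum. On unstructured symmetric matrices (e.g. symmetrized uniform
noise) the *representational floor* of the simplex-constrained symmetric
class is itself 1.3–2× the unconstrained optimum — we verified this by
direct multi-restart L-BFGS over free factor logits — so gaps on such
targets measure the constraint class, not optimization quality.

### Dynamic gated attention (DGA)

Two per-instance signals are combined:

* **Tanh branch**: affine → tanh → dropout (0.25) → affine-to-scalar →
  tanh, giving a signed score a_tanh ∈ (−1, 1). The final tanh keeps the
  branch's output in the signed activation range that motivates using
  tanh here (both positive and negative attention evidence); without it
  the closing affine map would be unbounded.
* **LSVD gate**: Â's row i summarizes instance i's total affinity mass;
  the row mean passed through a sigmoid gives a smooth switch
  a_lsvd ∈ (0, 1). The row mean (rather than sum) keeps the gate's scale
  independent of bag size.

The final weights and bag embedding are

    aₙ = softmax(Linear(a_lsvd ⊙ a_tanh)),    z = Σₙ aₙ yₙ,

with `Linear` a scalar→scalar affine map applied per instance before the
softmax. The plain-attention baseline is exactly this scoring path
without the gate, so clamping a_lsvd ≡ 1 reduces DGA to the baseline as
a numerical identity — a property the tests assert to 1e-12. Max and
mean pooling complete the baseline set; max reports pseudo-weights (the
frequency with which each instance supplies the coordinatewise maximum)
since true attribution weights do not exist for it.

## Numerical core

No GPU tensor framework is used: the package carries a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`habmil.autodiff`), with 3D convolution implemented as im2col + GEMM in
memory-bounded chunks (≤150 MB column buffers, so a full-scale
240×240×155 forward pass stays under ~5 GB), dedicated
batch-normalization and pooling kernels, and numeric-gradient tests for
every structured operation. Convolution-heavy stages run in float32; the
MIL head (CLE, LSVD, DGA, bag head) runs in float64, which is what makes
the 1e-6-relative permutation-invariance contract hold at realistic bag
sizes. Adam follows the standard update with classic L2 weight decay on
gradients.

## Training protocol

Defaults mirror the published protocol: Adam, learning rate 1e-4, weight
decay 1e-5, batch size 2, 100 epochs, subject-level 60/20/20 split with
five-fold cross-validation available inside the training partition, and
best-checkpoint selection on validation AUC. Metrics are AUC (trapezoidal
ROC, via scikit-learn), accuracy, sensitivity and specificity at a fixed
0.5 threshold (never tuned on test). All RNG streams — splits,
initialization, shuffling, dropout, augmentation — derive from explicit
seeds; a rerun with the same configuration reproduces identical numbers.
A single-class evaluation set yields AUC = NaN with a logged flag, and
checkpoint selection then falls back to training loss.

The desk-scale experiment presets (`desk_train_config`) use learning
rate 1e-3 and 8–30 epochs: the phantom tasks are low-dimensional and the
small networks converge within a few epochs at that rate, so longer
schedules would only add runtime. Class-imbalance weighting
(inverse-prevalence) is available but off by default.

Augmentation (scipy.ndimage-based) offers flips, small affine warps
(≤10°, ≤3 voxels, one geometric draw shared by all modalities),
intensity scaling, brightness/contrast jitter (the single-channel reading
of "color jitter"), and whole-modality dropout — the
missing-sequence-robustness scheme of zeroing T1/T2/FLAIR during
training. The desk experiments run without augmentation: the phantom
tasks are already solvable within a few epochs, and geometric
augmentation would corrupt the octant task's label (a flip moves the
lesion to a different octant).

## Synthetic phantom cohorts

The generator emulates the *statistical structure* of a skull-stripped,
co-registered multi-parametric cohort, not MRI physics: constant base
intensity 1.0, white Gaussian noise (sd 0.1) per modality, and
axis-aligned ellipsoidal lesions with Gaussian-smoothed (σ = 1) edges and
per-axis radii drawn as 9–16% of the axis length. Tumor-like lesions use
the contrast signature (−0.4, +0.8, +1.0) on (T1w, T2w, FLAIR) — T1-hypo,
T2/FLAIR-hyper, the qualitative pattern of glial tumors — while
background-like distractors are isointense (+0.8 everywhere), so
discriminating them requires the cross-modal pattern rather than "any
bright blob". These values were fixed once as the package's study
conditions. Under the presence rule negative bags carry distractors by
default; under the octant rule every subject has one lesion and the label
is whether its center lies in the all-upper-half octant.

### Absolute position leaks through zero padding

A finding that shaped the octant benchmark: a zero-padded CNN is not
translation-invariant near volume boundaries, and with three pooled
stages the ~22-voxel receptive field couples lesion appearance to the
nearest corner strongly enough that a position-blind backbone can reach
AUC ≈ 0.85–1.0 on the octant task through boundary artifacts alone. The
octant cohort therefore (a) keeps every lesion surface ≥ 5 voxels from
every face and (b) is paired with a two-stage encoder (receptive field
≈ 9 voxels), after which the backbone sits at chance (median AUC ≈ 0.6
on 12-subject test sets) and any lift must come from the positional
encoding. This mirrors the known result that convolutional padding
encodes absolute position, and it is why "position is the only signal"
needs to be engineered, not assumed.

### What the synthetic results do and do not show

Passing the synthetic benchmarks shows that the implementation can learn
the MIL decision rule end-to-end, that attention concentrates on truly
positive instances, and that positional encoding adds exactly the
information it should on a position-only task. It does not show clinical
performance: phantoms lack anatomy, bias fields, partial-volume effects,
registration error and intensity non-stationarity, and the lesion/label
association is noiseless by construction. Published cohort-level numbers
are not reproducible from this repository and are not claimed.

## Experiment sizes used by tests and the acceptance script

Presence recovery: 40 + 40 subjects at 48×48×32, split 48/16/16, 8
epochs, five seeds (median held-out AUC is the reported statistic).
Octant ablation: 30 + 30 subjects at 32×32×32, 30 epochs, full model vs
backbone over paired seeds. LSVD oracle: five 8×8 affinity targets, rank
4, 2000 Adam steps. These sizes keep the complete suite in the
~15-minute range on a single core while leaving each conclusion's margin
wide (presence AUC typically 1.0; octant full ≈ 0.9 vs backbone ≈ 0.6).

## Interpretability

### Attention localization is bimodal across seeds

On the presence task the trained model's final attention either tracks
the lesion (most seeds: top-1 key patch overlaps the lesion in ~all
positive test bags) or converges to a bag-independent pattern peaked on
one fixed cell while still classifying perfectly — the bag head can read
the diffuse remainder of the weights, so nothing forces the attention to
localize once the loss is satisfied. Diagnostics attribute the fixed-cell
mode to the dynamic gate's training dynamics: with the gate removed
(plain attention + CLE) localization was reliable in every run we
examined, and neither longer training nor a smaller initial σ changes an
already-locked run. Pooled over the five seeded runs of the test suite
the top-1 localization rate is 80%; single runs range from ~0.2 (a
locked seed) to 1.0, which is why both the tests and the acceptance
script report the rate aggregated over five seeds rather than one run.
Attention-map instability of this kind is a recognized property of
attention-based MIL; consumers of key patches should inspect more than
one seed.

Key patches are the top-k instances by final attention weight mapped
back through the pooling geometry to voxel boxes (ties broken by
instance index). Grad-CAM backpropagates the bag probability to a chosen
encoder stage (default: the last stage before flattening), weights each
channel by the spatial mean of its gradient, rectifies the weighted sum,
trilinearly upsamples to the input grid and min–max scales to [0, 1]; a
flat map is returned as all-zeros rather than dividing by a ~0 range.
Report panels show the lesion-center axial slice when a mask is
available, otherwise the mid-slice.

## Known limitations

* Batch normalization statistics with batch size 2 are noisy; running
  statistics (momentum 0.1) stabilize evaluation but very short runs
  evaluate with partially warmed statistics.
* Max pooling's gradient routes to the first argmax on ties (measure
  zero for continuous data, but relevant for constant inputs).
* The LSVD reconstruction is symmetric by construction (shared
  projection); asymmetric affinity structure is out of its class.
* The engine is single-threaded numpy + BLAS; full-scale (240×240×155)
  training is out of desk-scale scope — only the forward geometry is
  exercised at that size.
* `standardize` resampling uses trilinear interpolation for images and
  nearest-neighbour for masks; extreme anisotropic resampling ratios can
  shift thin masks by a voxel.
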