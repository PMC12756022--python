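# habmil

Weakly supervised classification of multi-modal 3D brain MRI with
hierarchical attention-based multiple instance learning.

`habmil` is for researchers who have subject-level labels (e.g. a
genotype such as IDH-mutant vs IDH-wild established from pathology) and
routine structural MRI (T1w, T2w, FLAIR), but no voxel-level lesion
annotations. It treats each subject's volume as a *bag* of spatial
*instances* and learns the bag label end-to-end, so no manual tumor
delineation is ever needed. Because real clinical cohorts cannot be
redistributed, the package ships a synthetic phantom-cohort generator
with exact lesion ground truth, on which every claim the code makes is
tested.

## The model

For a bag X = {x₁,…,x_N} with hidden instance labels yᵢ, the label obeys
the MIL rule Y = 1{Σᵢ yᵢ > 0}, and the classifier is Y ≈ g(h(f(x₁),…,f(x_N))):

* **f — 3D instance encoder.** Stages of 3×3×3 convolution → batch norm →
  ReLU → 2× max pool → dropout, then adaptive pooling onto a fixed
  H*×W*×S* instance grid and a 1×1×1 projection to D dims. At full scale
  a 240×240×155 volume yields a 2×2×2×64 feature grid; the desk-scale
  preset yields 4×4×4×32 from 48×48×32 volumes.
* **CLE — collateral location encoding.** Instance coordinates p ∈ [0,1]³
  pass through a learnable GELU network F̂(p) = a₂·GELU(a₁p + b₁) + b₂;
  features and encodings are per-bag standardized, concatenated, and
  re-weighted by an importance softmax A = softmax(WH′ + b), O = H′ ⊗ A.
  Sinusoidal (SPE) and unweighted neural (NPE) encodings are included as
  comparators.
* **LSVD — learnable singular value decomposition.** A low-rank affinity
  reconstruction Â = α·diag(σ)·αᵀ with α = softmax_rows(XW_a + b_a) from
  one shared projection and trainable σ. Its Frobenius error is bounded
  below by the Eckart–Young truncated-SVD optimum, which the tests
  assert on every fit.
* **DGA — dynamic gated attention pooling.** A signed Tanh attention
  branch a_tanh ∈ (−1,1) is gated by a_lsvd = sigmoid(rowmean(Â)) ∈ (0,1);
  the bag weights are aₙ = softmax(Linear(a_lsvd·a_tanh)) and
  z = Σₙ aₙ yₙ. Clamping the gate to 1 reduces DGA exactly to plain
  attention MIL; max and mean pooling complete the baselines.

Training uses mean binary cross-entropy over bags, Adam, subject-level
60/20/20 splits with optional 5-fold CV inside training, and best
checkpoint on validation AUC. Everything is seeded and reproducible.

The package runs on plain numpy: it includes a small reverse-mode
autodiff engine (`habmil.autodiff`) with chunked im2col 3D convolution,
so no GPU framework is required. Interpretability comes as top-k
attention key patches mapped back to voxel boxes and 3D Grad-CAM
saliency volumes.

## Worked example

Train the full model on 20 positive / 20 negative desk-scale phantoms
(positives carry tumor-like lesions with a T1-hypo / FLAIR-hyper
signature; negatives carry isointense distractor blobs):

```bash
python examples/02_train_presence.py
```

```
epoch 0: loss 0.694 val AUC 0.600
epoch 1: loss 0.694 val AUC 1.000
...
epoch 5: loss 0.615 val AUC 1.000
held-out: AUC 1.000 ACC 1.000 SEN 1.000 SPE 1.000 (n=8)
```

The held-out AUC of 1.000 means the model recovered the presence rule
from bag labels alone: it separates subjects with a tumor-signature
lesion from distractor-only subjects it never saw during training. The
LSVD demo prints the layer's distance from its theoretical floor:

```bash
python examples/04_lsvd_demo.py
```

```
fit error      1.2991
rank-4 optimum 1.1869  (truncated SVD)
ratio          1.095  (1.0 would be the unreachable floor)
```

Other examples: `01_phantom_cohort.py` (generator + instance ground
truth), `03_octant_ablation.py` (a task where lesion *position* is the
only signal — the positional encoding lifts AUC from chance to ~0.9),
`05_interpret.py` (key patches land on lesion cells; Grad-CAM saliency
is enriched in the lesion).

A thin CLI wraps the same library calls:

```bash
habmil synth --n-pos 20 --n-neg 20 --grid 48x48x32 --rule presence --seed 7 --out cohort/
habmil train --config run.yaml --pooling dga --pos-encoding cle
habmil explain --model runs/latest/model.npz --manifest cohort/manifest.tsv \
               --subject sub-0003 --k 3 --out panels/
```

## Scope

Phantom cohorts emulate the statistical structure of skull-stripped,
co-registered MRI — not anatomy or MRI physics — so results here
demonstrate correctness of the method, not clinical performance.
Upstream steps (DICOM handling, skull stripping, registration) are
assumed done; input is NIfTI.
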