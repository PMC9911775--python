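# Methods

## Problem setting

Given `N` subjects, each observed once in every one of `M` modalities
(strong pairing) and labelled with one of `C` classes, the task is to learn
per-modality hash functions into a common `K`-bit Hamming space such that
(i) codes of same-class samples are close across modalities, (ii) codes of
different classes are far, and (iii) same-class codes are *not* all
identical — the continuous within-class similarity structure of the data
should survive in code space.  Retrieval quality is measured by mean average
precision (mAP) over all returned results, in both cross-modal directions.

## Similarity model

Codes of one modality are compared with cosine similarity (homogeneous
similarity `S_I`).  Codes of different modalities are compared with a heat
kernel over a label-aware modified distance:

    d(a,b)   = ‖a − b‖₂
    D(a,b)   = √(1 − e^(−d))   if labels agree
             = √(e^(−d))       otherwise
    S_H(a,b) = exp(−D²/τ)

so same-label pairs have similarity 1 at `d = 0` decaying to `e^(−1/τ)`,
and different-label pairs start at `e^(−1/τ)`.  The `M·N × M·N` block
matrix with `S_I` blocks on the diagonal and `S_H` blocks off it is the
multi-manifold similarity `S_M`.  `τ` (heat-kernel constant) defaults to
1.0; it is not prescribed by the method and is exposed in every API.

Two printed-form subtleties are implemented literally and exposed as flags
rather than silently changed:

* the different-label branch of `D` makes `S_H` *increase* with distance
  (its monotonicity is inverted relative to what a similarity usually
  does); `swap_distance_branches` (default off) exchanges the two branch
  assignments for experimentation.  At the gentle fine-tuning rate used
  here both conventions give near-identical results.
* self-pairs (`m = n, i = j`) are included in the loss sums exactly as the
  summation limits state; they contribute a constant and can be excluded
  with `include_self_pairs=False` for reporting.

## Objective

`J = α·J1 + β·J2 + R` with

* `J1` (multi-semantic consistency): for every modality and subject, the
  Euclidean norms `‖y−ℓ‖ + ‖r−ℓ‖ + ‖y−r‖` between the two branch
  predictions and the one-hot label.  Predictions are softmax-normalized —
  comparing against one-hot targets presupposes comparable scale.
* `J2` (multi-manifold similarity preservation):
  `Σ log(1+e^s) − I·s` over all entries `s` of `S_M`, `I` the same-label
  indicator.  Every per-pair term is non-negative.  At
  `s* = ln((1+√5)/2)` — the root of `log(1+e^s) = 2s`, equivalently of
  `u² − u − 1 = 0` with `u = e^s` — the term matches a Laplacian-eigenmaps
  objective `½·S·‖H_i − H_j‖²` on row-normalized codes;
  `laplacian_embedding_loss` computes that reference quantity for
  numerical probing.
* `R` (quantization): the printed form is the ℓ1 distance of every relaxed
  code to the all-ones vector, summed over all `(m,n,i,j)` pairs — each
  code counted `2MN` times.  Because driving *all* bits toward +1
  conflicts with a `{−1,+1}` code space, the package also provides the
  common magnitude form `‖|h| − 1‖₁`.  The loss API defaults to the
  literal form; the desk-scale training default uses the magnitude form.

**Reductions.**  `sum` reproduces the printed equations.  `mean` divides
each loss by its number of scalar summands (`J1` by `M·N`, `J2` by
`(MN)²`, `R` by `2(MN)²·K`), so the regularizer's weight does not grow
with the code length and the printed multiplicity cancels; this is the
desk-scale default for optimizer balance.  The reduction in force is
recorded in the training log.

## Architecture

* **Encoders** (one per modality, unshared — pseudo-Siamese for every
  `M ≥ 2`, the safe general reading for heterogeneous modalities): a
  2-layer MLP `Z → 64 → D` for flat input, or a small conv stack
  (`tiny_cnn`: 3 convolutions; `alexnet_like`: 5 convolutions + 2 fc) for
  2-D slices.  The feature layer is **tanh-bounded**: with an unbounded
  feature layer, classification pre-training grows feature norms without
  limit (softmax margins), which parks the decoder's tanh in saturation
  and freezes the codes before the similarity losses can act.  Bounding
  the features lets classifier confidence grow in the head weights
  instead.  `D < Z` is validated (the encoder compresses).
* **Decoder** (shared across modalities): a single affine map `D → K`
  into tanh, producing relaxed codes in `(−1,1)`.  The encoder has
  strictly more parameters than the decoder (asymmetry, asserted in
  tests).
* **Attention branches**: linear multi-layer heads (two stacked affine
  maps, softmax output) on features (`SPAB_E`) and codes (`SPAB_D`).  No
  spatial attention map is constructed because none is specified beyond
  "linear multi-layer perceptron".
* **Binarization**: `sign` with `sign(0) = +1`, idempotent.  For ±1 codes
  of equal length, cosine ranking and Hamming ranking coincide
  (`cos = (K − 2·Ham)/K`); evaluation binarizes by default (`--no-binarize`
  evaluates relaxed codes).

All gradients come from a small reverse-mode autodiff engine
(`dcpha.autodiff`) over NumPy arrays; the test suite checks its gradients
of `J2` and `R` against central finite differences to 1e−4 relative error,
and convolution backward through the im2col lowering is exercised by the
gradient-flow tests.

## Training schedule

Three stages, each with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8):

1. **Pre-train encoders** + `SPAB_E` on the `‖y−ℓ‖` term (decoder
   untouched).
2. **Pre-train decoder** + `SPAB_D` on `‖r−ℓ‖` + quantization, encoders
   frozen.
3. **Fine-tune** everything on the full objective.

The per-stage objectives are the minimal reading of the three-step
description and are config-overridable.  Batches contain the same subject
indices in every modality, drawn without replacement per epoch from a
seeded generator; fixed seed ⇒ bit-identical histories and parameters on
one CPU thread.

**Learning rates.**  Desk-scale pre-training uses 1e−3 (tiny backbones at
the published 1e−6 do not move measurably).  Fine-tuning defaults to
1/100 of the pre-training rate (desk: 1e−5).  This mirrors the method's
own regime — the published setting tunes at 1e−6 — and is load-bearing:
at aggressive fine-tuning rates the fixed-weight quantization term drives
every class to a single consensus code (shared-parameter dynamics push
each bit to the cluster-majority sign), destroying exactly the
within-class code diversity the method is designed to preserve.  Stage
budgets (50 / 50 / 100 iterations) are sized to the measured loss
plateaus of each stage on the default recipe.

Presets: `desk` (the defaults above), `adni2` (batch 20, 500 iterations,
lr 1e−6, α = 0.3, β = 1.0, sum reduction, literal regularizer) and
`oasis3` (same with α = 0.1) carry the published hyper-parameters.

## Synthetic data generator

Each class `c` owns a latent centre `μ_c ∈ R^q` (q = 4); centres are
rescaled so the minimum pairwise distance equals `class_separation`
(default 4.0).  Subject `i` of class `c` draws a latent
`z_i = μ_c + 1.0·N(0, I_q)` — the within-class spread (a quarter of the
centre separation, 10× the sensor noise) gives each class patch genuine
extent; a near-point cluster would carry no within-class structure to
preserve.  Modality `m` renders the *shared* latent through its own fixed
random nonlinear map `T_m(z) = W_m·[z; sin(Ω_m z + φ_m)] + b_m` plus
`N(0, noise_sd²)` noise (default 0.1), so modalities live on different
curved sub-manifolds while sharing subject identity and label.  Splitting
is subject-level, stratified by class, default 8/2.

What the generator does **not** emulate: MRI/PET physics, intensity
distributions, anatomy, registration error, missing modalities or label
noise.  Passing tests therefore show that the pipeline recovers planted
cross-modal class structure under realistic separability — not that it
reaches any particular accuracy on clinical data.

## Numerical choices

* ε = 1e−12 inside square roots on the differentiable path (pairwise
  distances, per-sample norms) so gradients stay finite at zero distance;
  the plain-NumPy evaluation path is exact.
* Cosine ranking computes the dot product first and normalizes after, so
  single-query and batched rankings tie-break identically for ±1 codes;
  ties break by ascending gallery index (stable sort).
* Queries whose class is absent from the gallery score AP = 0 and are
  counted, with a logged warning.
* `sign(0) = +1`, fixed.
* Duplicate codes between distinct samples are legal inputs everywhere.

## Known limitations

* The desk-scale backbones are deliberately small; no pre-trained weights,
  no GPU path.
* Within-class binarized-code diversity is a transient property under the
  printed objective: with unlimited aggressive joint training the
  quantization term always wins and collapses each class to one code per
  modality.  The gentle fine-tuning default keeps the model in the regime
  the method's published setting occupies.
* Real-data ingestion is limited to single-slice NIfTI extraction with a
  minimal, documented convention (middle slice, min-max normalization,
  spline resize); clinical preprocessing (registration, skull-stripping)
  is out of scope.
* Multi-label data is rejected: the similarity definitions compare one-hot
  labels for exact equality.
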