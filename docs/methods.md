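# Methods

This note documents the model, the algorithmic and numerical choices made
where the design was genuinely open, what the synthetic data do and do not
emulate, and the package's known limitations.

## Problem setting and model

Subject-level diagnosis from 3D volumes is cast as multi-instance learning
(MIL): a subject is a bag of `k` cubic patches with a single binary bag
label; a positive bag is assumed to contain at least one label-activating
instance. The bag probability factorises as `Θ(X) = g(φ(f(X)))` with a
shared instance transform `f` (PatchNet), an attention MIL pooling `φ`
(A-MIDL) and a global classifier `g`.

### Patch location proposal

Volumes are assumed skull-stripped and co-registered upstream (the canonical
template space is 181×217×181 voxels; any shape is accepted). Partitioning
uses 0-based coordinates and half-open cubes `[o, o+W)`; trailing voxels
that do not fill a cube are dropped rather than padded, so a location grid
has `∏ floor(dim/W)` cubes and no artificial boundary patterns. Axis order
is taken as stored in the file — within-study consistency is what the group
comparison requires, not a canonical anatomical frame.

The per-location test is a two-sided Welch t-test on the per-subject **patch
mean** intensity. The patch-mean summary reflects group evaluation of
patch-level structure and is the default; a voxel-wise variant (per-voxel
t-tests, location scored by the mean voxel p-value) is available via
`patch_proposal.statistic: voxelwise` since the field's practice varies.
Welch (unequal variances) is used because group variances are not assumed
equal. If both groups have zero variance at a location the p-value is
defined as 1 (with a logged warning). No multiple-testing correction is
applied: selection is rank-based on min–max-normalised p-values, and any
monotone correction leaves ranks unchanged. When all raw p-values coincide,
normalised scores are defined as 0. Ties in selection break by
lexicographic coordinate order, making the bag layout independent of map
insertion order.

### PatchNet

Four 3×3×3 conv layers (padding 1), channel plan `c1-c2-c3-c4` (default
32-64-128-128; the desk-scale pipeline default is 4-8-8-8), with a 2×2×2
max-pool between conv2 and conv3, so a `W³` patch yields `c4 × (W//2)³`
maps. Layer order is conv → batch-norm → ReLU; putting BN before the
nonlinearity keeps the pre-activation distribution controlled and is the
common convention. The spatial attention block pools the conv4 maps across
channels (max and average), concatenates the two `w³` maps, applies one
2-in/1-out 3×3×3 convolution and a sigmoid, and rescales every channel
voxel-wise; it is applied once, to conv4's output. The effect-score branch
is global average pooling over the attended maps followed by a linear map to
one scalar; "two branches" constrains little, and GAP+linear is the smallest
head that sees the whole attended representation.

### A-MIDL pooling

Each patch's channels are averaged to a single `w³` map; the stacked maps
form the bag-level global feature (one map per patch, in bag order). Global
average and global max pooling reduce each map to a scalar; a shared
two-layer per-patch MLP (1 → hidden → 1, hidden default 4) maps the GAP and
GMP descriptors to the pre-sigmoid vectors `A_average` and `A_max`. Sharing
the MLP between the two descriptor paths follows the established shared-MLP
channel-attention design; `amidl.shared_descriptor_mlp: false` unshares
them. Both descriptors are computed from the same compressed global feature.
Because the MLP acts on each patch independently, the pooling is permutation
-equivariant: permuting bag order permutes weights and weighted maps
identically. The fused attention is `A_patch = σ(A_average + A_max + a)`
with the effect vector entering unscaled and the three terms equally
weighted, as the fusion is defined; the weighted global feature is the
patch-wise product.

### Global classifier and loss

The `k` weighted maps are treated as input channels to two 3×3×3 conv
layers (k → 16 → 8 by default, BN + ReLU), flattened and mapped to two
logits with softmax. The primary objective is mean bag-level cross-entropy.
Training uses Adam (lr 1e-3, batch 8 by default) with early stopping on
validation loss and restoration of the best-validation parameters.

### Training dynamics (design choices)

Four choices matter for whether the attention map becomes meaningful, and
all were driven by observed failure modes on the synthetic task:

* **Subject-batched normalisation.** A minibatch of bags is pushed through
  one joint forward pass: all `B·k` patches share the PatchNet normalisation
  batch, and the global classifier normalises across the `B` subjects. With
  per-subject forwards (batch of one), the classifier's batch-norm cancels
  exactly the between-subject channel-mean differences — the very signal a
  mean-shift pathology produces — and the model can only memorise.
* **Neutral gate initialisation.** The output layers of the descriptor MLP
  and the effect head start at zero, so every patch gate begins at exactly
  σ(0) = 0.5 and the *training signal*, not initialisation noise, decides
  the attention ordering.
* **Effect-score supervision.** The bag cross-entropy alone does not
  identify the intended attention polarity: multiplicative gates can help
  classification equally well by up-weighting *or* by zeroing-out the
  informative patch, and empirically either basin is reached. The effect
  score is therefore given its literal meaning — capacity to activate the
  bag label — through a weak auxiliary term
  `λ · BCE(σ(max_i a_i), Y)` (default λ = 1,
  `classifier.effect_supervision`; 0 restores the pure bag objective).
  Under the MIL assumption the bag label is a valid weak label for the
  largest instance score; only the truly informative patch can keep a high
  score in positive bags while all patches stay low in negative bags, so the
  equilibrium places the top effect — and hence the top attention weight —
  on the discriminative patch.
* **Optimiser.** Adam with optional decoupled weight decay (skipped for
  biases and normalisation affines) and an optional learning-rate
  multiplier for the attention branch; both default to neutral (0 and 1) —
  aggressive attention learning rates were observed to destabilise the bag
  loss when combined with neutral gate initialisation.

### FSSA

The printed description of the optimiser is corrupted in several places;
the implementation uses the following concrete forms, each switchable where
a credible alternative exists:

* Initialisation `lb + U(0,1)·(ub − lb)` (sign-corrected).
* Exploration phase (first half of the run): three encircling moves around
  the best-known position with `A = 2·a·r1 − a`, `C = 2·r2` and `a`
  decaying linearly 2 → 0 over the whole run; the candidate is their mean,
  followed by a fuzzy step `x ← x + α(x_best − x)` with
  `α = GFM(f(candidate); c = mean population fitness, s = fitness SD
  (floored at 1e-12), m = 2)` — candidates of near-average quality take the
  largest steps toward the best.
* Exploitation phase (second half): the classical leader/follower chain —
  leader `F ± c1·((ub−lb)·C2 + lb)` with the branch on `C3 ≥ 0.5`, followers
  moving to the midpoint of themselves and their (already updated)
  predecessor, sequentially in array order (`sort_chain: true` re-sorts by
  fitness first). The exploitation-phase `c1` decays linearly from 0.95 to
  0.05 (`c1_schedule: adaptive`); the canonical `2·exp(−(4t/T)²)` decay is
  available as `c1_schedule: classic`.
* Greedy selection everywhere (strict improvement; ties keep the incumbent),
  which makes the best-so-far trace non-increasing by construction.
* Population size shrinks linearly from `n_max` to `n_min`, discarding the
  worst salps while preserving chain order among survivors.
* All positions are clamped to the box after every update. Minimisation
  convention; maximisation is handled by negating the fitness.

Classifier refinement flattens the global classifier's final linear layer
into the decision vector, bounds the search at the current values ± 0.5
(configurable), and minimises `−accuracy + 1e-6·min(CE, 1e3)` on the
validation bags — the cross-entropy term only breaks accuracy ties, since
accuracy moves in steps of `1/n_val`. The incoming parameters seed the
first salp, so the refined model's validation accuracy is never below the
input's. Penultimate-layer activations are cached once, making each fitness
evaluation a single dense-layer pass.

### Metrics and splits

ACC/SEN/SPE are exact ratios of the 2×2 confusion table at a 0.5
probability threshold (the operating point is configurable; nothing fixes a
tuned one). Undefined denominators give NaN with a warning. AUC is the
trapezoidal ROC area (equal to the Mann–Whitney probability with ties at
one half), computed via scikit-learn and cross-checked in the tests against
a brute-force pair count. Hold-out and k-fold splits are stratified by
label — important at cohort sizes where a random split can unbalance
classes.

## Synthetic data

`generate_cohort` emulates only the *group-contrast structure* of a
registered, skull-stripped cohort: one shared smooth base field (Gaussian
-blurred white noise, σ = 6 voxels, rescaled to unit SD) as an anatomy
proxy, i.i.d. unit-SD voxel noise per subject, and a mean shift of
`effect_size · noise_sd` (default d = 1.5, negative sign — atrophy-like
signal loss) inside each lesion cube for the disease group. Defaults are
48³ volumes, one 12³ lesion aligned to the patch grid, 60 subjects per
group. It does **not** model anatomical boundaries, bias fields,
registration error, partial-volume effects, or lesions that straddle patch
boundaries; passing tests therefore demonstrate the pipeline's mechanics
and its localisation behaviour under a known contrast, not clinical
performance. Because a patch-mean shift of d·noise_sd against patch-mean
noise of `noise_sd/√(W³)` is a very large subject-level separation, perfect
hold-out metrics on the default cohort are expected, and the informative
checks are calibration under the null (uniform p-values), lesion recovery
rate, and attention localisation.

## Numerical choices

* Default training dtype is float32 (configurable); gradient checks run in
  float64 and agree with finite differences to ~1e-6 relative.
* Sigmoid outputs and the Gaussian fuzzy membership are clipped into the
  open interval their mathematical forms map to, guarding against float
  saturation/underflow at extreme arguments.
* Batch-norm eval mode uses running moments (momentum 0.1, eps 1e-5), so
  inference is deterministic; all randomness flows from explicit seeds
  through `numpy.random.default_rng`, and reports are written with sorted
  keys and no timestamps, so reruns are byte-identical.
* Max-pool ties resolve to the first occurrence; partition remainders are
  dropped, never padded.

## Problem sizes

The reference configuration (48³ cohort, n = 60/group, k = 8, W = 12,
channels 4-8-8-8, ≤ 40 epochs) trains in about two minutes on one CPU; the
full-width 32-64-128-128 PatchNet with W = 25 is supported and
shape-checked in the tests but is not the default, as its compute scale
belongs on accelerated hardware.

## Known limitations

* Patch size is uniform and fixed; lesions off the patch grid dilute into
  neighbouring patches.
* The proposal stage is decoupled from the network: bag locations are fixed
  before training and never revisited.
* Binary classification only; no multi-class staging or longitudinal
  modelling.
* FSSA refinement targets only the final linear layer; refining deeper
  layers would require bounding a much higher-dimensional box and many more
  fitness evaluations.
* The effect-supervision term assumes the standard MIL premise (at least
  one informative instance per positive bag); with diffuse pathology spread
  over many patches its localisation pressure weakens.
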