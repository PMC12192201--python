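# foamidl

Weakly-supervised classification of 3D volumetric images (e.g. structural
brain MRI) with attention-based multi-instance deep learning, plus a fuzzy
salp swarm algorithm (FSSA) that refines the trained classifier's final
layer. The package is aimed at researchers who have subject-level labels
(disease vs control) but no voxel- or region-level annotations, and who want
both a classifier and an interpretable map of *which* image regions drove
each decision.

## The method

A subject's scan is treated as a **bag** `X = {I_1, …, I_k}` of cubic
patches (`I_i ∈ R^{W×W×W}`) with one bag label `Y ∈ {0, 1}`. The positive
class probability decomposes as

```
Θ(X) = g(φ(f(X)))
```

with four stages:

1. **Patch location proposal.** The co-registered training volumes are
   partitioned into non-overlapping `W³` cubes; at each location a Welch
   two-sample t-test compares the groups on the per-subject patch mean.
   P-values are min–max normalised, `(p − MIN)/(MAX − MIN)`, and the `k`
   lowest-scoring locations define every subject's bag.
2. **PatchNet** `f` — a shared per-patch 3D CNN (four 3×3×3 conv layers,
   BN + ReLU, one 2×2×2 max-pool) with a **spatial attention block**
   (`A_spatial = σ(Conv([F_max; F_avg]))`, applied voxel-wise to the Conv4
   maps) and a scalar **effect score** per patch — its capacity to activate
   the bag label.
3. **A-MIDL pooling** `φ` — each patch's channels are average-compressed to
   one map; global average/max descriptors pass through a shared two-layer
   MLP, and the patch attention map is fused as
   `A_patch = σ(A_average + A_max + a)`, then multiplied onto the maps.
   `A_patch` is also the interpretability output: high-weight patches mark
   candidate pathological sites.
4. **Attention-aware global classifier** `g` — two 3D conv layers over the
   patch axis, then a softmax head; trained end-to-end with cross-entropy
   `L(W) = −(1/N) Σ log P(Y_n | X_n; W)`.

After gradient training, the **FSSA** — a leader/follower salp-chain
optimiser with Gaussian-fuzzy step sizes, adaptive control parameter and
linear population shrinkage — searches a box around the global classifier's
final-layer weights for higher validation accuracy. The incoming parameters
seed the first salp and selection is greedy, so refinement can never reduce
validation accuracy.

Evaluation reports ACC, SEN, SPE (confusion-matrix ratios) and ROC AUC.

## Worked example

The built-in generator emulates a two-group cohort of smooth 48³ volumes in
which the disease group has its intensity reduced by 1.5 noise-SD inside one
12³ "lesion" cube (an atrophy-like focal contrast). Running the full
workflow:

```bash
foamidl run --seed 1 --out run/
```

prints the held-out metrics (60 subjects per group, 80/20 hold-out):

```json
{"acc": 1.0, "auc": 1.0, "counts": {"fn": 0, "fp": 0, "tn": 12, "tp": 12},
 "n": 24, "sen": 1.0, "spe": 1.0, "threshold": 0.5}
```

All 24 held-out subjects are classified correctly (the synthetic contrast is
strong at patch scale). `run/bag_spec.csv` shows the proposal ranked the
true lesion cube first, and `run/attention/sub-*.csv` contain the per-patch
attention weights: in 10 of the 12 positive held-out bags of this run the
lesion patch carries the largest weight, so the attention map recovers the
known discriminative region without any location-level supervision.
`run/report.json` stores the same numbers plus the localisation summary;
`run/history.csv` has the per-epoch training curve, and `run/fssa_trace.csv`
the refinement trace (`iter,best_fitness,pop_size,c1`).

Other entry points: `foamidl simulate` (write a NIfTI cohort + manifest),
`foamidl propose-patches`, `foamidl train`, `foamidl refine`,
`foamidl evaluate`, and `foamidl optimize-fssa --fn sphere --dim 10` for
optimiser benchmarks. Every command is driven by a strict YAML config
(unknown keys rejected); `patch_proposal.width` and `patch_proposal.k` are
mandatory. The library functions behind each command are importable from
`foamidl` directly.

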