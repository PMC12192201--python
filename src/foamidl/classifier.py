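"""Attention-aware global classifier and the end-to-end bag model.

The bag probability decomposes as Theta(X) = g(phi(f(X))): f is the shared
PatchNet instance transform, phi the attention MIL pooling, and g a small
3D conv head that treats the k weighted patch maps as input channels,
squeezes them down and emits two-class softmax probabilities.  Training
minimises mean cross-entropy of the bag labels with Adam; ablation flags
reproduce the reduced variants (no CNN extractor / no attention / no
swarm refinement).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _engine as eng
from ._engine import Tensor
from .amidl import AMIDLPooling, PatchAttentionMap
from .patch_proposal import PatchBag
from .patchnet import PatchNet
from .volio import ValidationError

__all__ = [
    "Prediction",
    "GlobalClassifier",
    "FixedPatchEmbedding",
    "BagModel",
    "global_classifier_forward",
    "bag_forward",
    "cross_entropy_loss",
    "train",
    "ablation_variant",
    "TrainingDiverged",
]

VALID_ABLATION_FLAGS = frozenset({"no_patchnet_cnn", "no_attention", "no_fssa"})


class TrainingDiverged(RuntimeError):
    """Loss became NaN/Inf; message names the epoch and batch."""


@dataclass
class Prediction:
    prob_positive: float
    logits: np.ndarray
    attention: PatchAttentionMap | None = None

    @property
    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max()
        e = np.exp(z)
        return e / e.sum()

    @property
    def hard_call(self) -> int:
        return int(self.prob_positive >= 0.5)


class GlobalClassifier(eng.Module):
    """Two 3x3x3 conv layers over the patch axis, then a linear softmax head.

    Input is the pooled global feature with k channels (one per patch);
    conv channels default to k -> 16 -> 8, each followed by batch-norm and
    ReLU, then flatten -> linear -> 2 logits.
    """

    def __init__(
        self,
        k: int,
        feature_width: int,
        conv_channels: tuple[int, int] = (16, 8),
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        h1, h2 = conv_channels
        self.k = k
        self.feature_width = feature_width
        self.conv1 = eng.Conv3d(k, h1, rng=rng, dtype=dtype)
        self.bn1 = eng.BatchNorm3d(h1, dtype=dtype)
        self.conv2 = eng.Conv3d(h1, h2, rng=rng, dtype=dtype)
        self.bn2 = eng.BatchNorm3d(h2, dtype=dtype)
        self.fc = eng.Linear(h2 * feature_width**3, 2, rng=rng, dtype=dtype)

    def __call__(self, G: Tensor) -> Tensor:
        """G: (k, w, w, w) -> logits (2,), or batched (B, k, w, w, w) -> (B, 2)."""
        single = G.ndim == 4
        x = G.reshape(1, *G.shape) if single else G
        if x.shape[1] != self.k:
            raise ValidationError(
                f"global feature has {x.shape[1]} maps but classifier expects k={self.k}"
            )
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        logits = self.fc(h.reshape(x.shape[0], -1))
        return logits.reshape(-1) if single else logits


class FixedPatchEmbedding(eng.Module):
    """Untrained per-patch embedding used by the ``no_patchnet_cnn`` ablation.

    Average-pools each W-cube patch down to a single-channel w-cube (w =
    floor(W/2)) so downstream shapes match PatchNet's output; the effect
    score is the patch mean.  Holds no trainable parameters.
    """

    def __init__(self, patch_width: int):
        super().__init__()
        if patch_width < 2:
            raise ValidationError(f"patch width {patch_width} too small to downsample")
        self.patch_width = patch_width
        self.feature_width = patch_width // 2

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        # average-pool each 2-cube; trailing odd voxels dropped (as in PatchNet)
        w = self.feature_width
        n = x.shape[0]
        xc = Tensor(
            np.ascontiguousarray(x.data[:, :, : 2 * w, : 2 * w, : 2 * w]),
            x.requires_grad,
            (x,),
        )

        def bw(g):
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                gx[:, :, : 2 * w, : 2 * w, : 2 * w] = g
                x._accumulate(gx)

        xc._backward = bw
        feats = xc.reshape(n, 1, w, 2, w, 2, w, 2).mean(axis=(3, 5, 7))
        effect = x.mean(axis=(1, 2, 3, 4))
        return feats, effect


@dataclass
class BagModel:
    """Shared PatchNet + A-MIDL pooling + global classifier, with config."""

    patchnet: eng.Module
    pooling: AMIDLPooling
    classifier: GlobalClassifier
    k: int
    patch_width: int
    ablation_flags: frozenset = field(default_factory=frozenset)

    def modules(self) -> list[eng.Module]:
        return [self.patchnet, self.pooling, self.classifier]

    def parameters(self) -> list:
        return [p for m in self.modules() for p in m.parameters()]

    def train_mode(self):
        for m in self.modules():
            m.train()

    def eval_mode(self):
        for m in self.modules():
            m.eval()

    def state_arrays(self) -> list:
        return [a for m in self.modules() for a in m.state_arrays()]

    def load_state_arrays(self, arrays: list) -> None:
        sizes = [len(m.state_arrays()) for m in self.modules()]
        it = iter(arrays)
        for m, n in zip(self.modules(), sizes):
            m.load_state_arrays([next(it) for _ in range(n)])

    @property
    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float64

    # -- forward ----------------------------------------------------------
    def forward_batch(self, patches: np.ndarray) -> tuple[Tensor, Tensor]:
        """patches: (B, k, W, W, W) -> (logits (B, 2), attention weights (B, k)).

        All B*k instances share one PatchNet pass, so at train time the
        normalisation batch spans every instance of the minibatch; the
        global classifier likewise normalises across the B subjects, which
        preserves between-subject differences in channel means.
        """
        B, k = patches.shape[:2]
        if k != self.k:
            raise ValidationError(
                f"bags have {k} patches but model expects k={self.k}"
            )
        x = Tensor(
            np.ascontiguousarray(patches, dtype=self.dtype).reshape(
                B * k, 1, *patches.shape[2:]
            )
        )
        features, effect = self.patchnet(x)  # (B*k, C, w, w, w), (B*k,)
        w = features.shape[-1]
        G = features.mean(axis=1).reshape(B, k, w, w, w)
        if "no_attention" in self.ablation_flags:
            # identity attention: plain channel-compressed maps, uniform weights
            weighted = G
            weights = Tensor(np.full((B, k), 1.0 / k, dtype=self.dtype))
        else:
            desc = self.pooling.descriptor
            gap = G.mean(axis=(2, 3, 4)).reshape(B * k, 1)
            gmp = G.reshape(B * k, -1).max(axis=1, keepdims=True)
            a_avg = desc._mlp(gap, for_max=False).reshape(B, k)
            a_max = desc._mlp(gmp, for_max=True).reshape(B, k)
            weights = (a_avg + a_max + effect.reshape(B, k)).sigmoid()
            weighted = G * weights.reshape(B, k, 1, 1, 1)
        logits = self.classifier(weighted)
        return logits, weights, effect.reshape(B, k)

    def forward(self, patches: np.ndarray) -> tuple[Tensor, Tensor]:
        """patches: (k, W, W, W) -> (logits (2,), attention weights (k,))."""
        patches = np.asarray(patches)
        logits, weights, _ = self.forward_batch(patches[None])
        return logits.reshape(-1), weights.reshape(-1)

    @classmethod
    def build(
        cls,
        k: int,
        patch_width: int,
        patchnet_channels: tuple[int, int, int, int] = (32, 64, 128, 128),
        attention_hidden: int = 4,
        shared_descriptor_mlp: bool = True,
        classifier_channels: tuple[int, int] = (16, 8),
        ablation_flags: tuple = (),
        seed: int = 0,
        dtype=np.float64,
    ) -> "BagModel":
        flags = frozenset(ablation_flags)
        unknown = flags - VALID_ABLATION_FLAGS
        if unknown:
            raise ValidationError(f"unknown ablation flag(s): {sorted(unknown)}")
        rng = np.random.default_rng(seed)
        if "no_patchnet_cnn" in flags:
            patchnet = FixedPatchEmbedding(patch_width)
        else:
            patchnet = PatchNet(patch_width, channels=patchnet_channels,
                                rng=rng, dtype=dtype)
        pooling = AMIDLPooling(hidden=attention_hidden,
                               shared_descriptor_mlp=shared_descriptor_mlp,
                               rng=rng, dtype=dtype)
        classifier = GlobalClassifier(k, patch_width // 2,
                                      conv_channels=classifier_channels,
                                      rng=rng, dtype=dtype)
        return cls(patchnet, pooling, classifier, k, patch_width, flags)


def global_classifier_forward(G, classifier: GlobalClassifier) -> Prediction:
    """Run the global head on a (k, w, w, w) pooled feature, inference mode."""
    maps = getattr(G, "maps", G)
    was_training = classifier.training
    classifier.eval()
    try:
        logits = classifier(Tensor(np.asarray(maps, dtype=classifier.fc.weight.data.dtype)))
    finally:
        if was_training:
            classifier.train()
    data = logits.data
    probs = np.exp(data - data.max())
    probs = probs / probs.sum()
    return Prediction(prob_positive=float(probs[1]), logits=data.copy())


def bag_forward(bag: PatchBag, model: BagModel) -> Prediction:
    """Full inference pass for one bag; attaches the patch attention map."""
    if bag.k != model.k:
        raise ValidationError(f"bag size {bag.k} != model bag size {model.k}")
    model.eval_mode()
    logits, weights = model.forward(bag.stacked(dtype=model.dtype))
    data = logits.data
    probs = np.exp(data - data.max())
    probs = probs / probs.sum()
    w = np.clip(weights.data.astype(float), 1e-12, 1 - 1e-12)
    return Prediction(
        prob_positive=float(probs[1]),
        logits=data.copy(),
        attention=PatchAttentionMap(w),
    )


def cross_entropy_loss(predictions: list[Prediction], labels: list[int]) -> float:
    """Mean negative log-probability of the true class."""
    if len(predictions) == 0:
        raise ValidationError("empty batch")
    if len(predictions) != len(labels):
        raise ValidationError("predictions and labels differ in length")
    total = 0.0
    for pred, y in zip(predictions, labels):
        if y not in (0, 1):
            raise ValidationError(f"labels must be 0/1, got {y!r}")
        p = pred.probs[y]
        total += -np.log(max(p, 1e-300))
    return float(total / len(predictions))


def _batch_loss(
    model: BagModel,
    bags: list[PatchBag],
    class_weights=None,
    effect_supervision: float = 0.0,
) -> Tensor:
    """Differentiable (weighted) mean bag cross-entropy over labelled bags.

    ``effect_supervision`` > 0 adds the weak instance-level term
    lambda * BCE(sigmoid(max_i effect_i), Y): under the MIL assumption a
    positive bag contains at least one label-activating instance, so the
    bag label supervises the largest effect score.  This trains the effect
    branch to mean what it is defined to mean — each patch's capacity to
    activate the bag label.
    """
    patches = np.stack([b.stacked(dtype=model.dtype) for b in bags])
    logits, _, effect = model.forward_batch(patches)
    logp = eng.log_softmax(logits, axis=1)  # (B, 2)
    sel = np.zeros((len(bags), 2), dtype=model.dtype)
    total_w = 0.0
    for i, bag in enumerate(bags):
        w = 1.0 if class_weights is None else float(class_weights[bag.label])
        sel[i, bag.label] = w
        total_w += w
    loss = -(logp * Tensor(sel)).sum() * (1.0 / total_w)
    if effect_supervision > 0 and "no_attention" not in model.ablation_flags:
        y = np.array([b.label for b in bags], dtype=model.dtype)
        m = effect.max(axis=1)  # (B,) max effect per bag
        # BCE(sigmoid(m), y) = softplus(m) - y*m
        bce = (m.softplus() - m * Tensor(y)).mean()
        loss = loss + bce * effect_supervision
    return loss


def _evaluate_split(model: BagModel, bags: list[PatchBag]) -> tuple[float, float]:
    """(mean CE loss, AUC) on a labelled bag list, inference mode."""
    from .metrics import auc as _auc

    preds = [bag_forward(b, model) for b in bags]
    labels = [b.label for b in bags]
    loss = cross_entropy_loss(preds, labels)
    scores = [p.prob_positive for p in preds]
    try:
        a = _auc(labels, scores)
    except ValidationError:
        a = float("nan")
    return loss, a


def train(
    model: BagModel,
    train_bags: list[PatchBag],
    val_bags: list[PatchBag],
    lr: float = 1e-3,
    epochs: int = 100,
    batch_size: int = 8,
    seed: int = 0,
    patience: int = 15,
    class_weights: dict | None = None,
    weight_decay: float = 0.0,
    attention_lr_mult: float = 1.0,
    effect_supervision: float = 0.0,
) -> tuple[BagModel, list[dict]]:
    """Minimise bag-level cross-entropy with Adam; early-stop on val loss.

    ``weight_decay`` is decoupled (AdamW-style) and skipped for biases and
    normalisation affines; it keeps the over-parameterised classifier from
    memorising small cohorts outright, which would starve the attention
    branch of gradient.  ``attention_lr_mult`` scales the learning rate of
    the attention/effect parameters relative to the rest.

    Returns the model restored to its best-validation-loss parameters and a
    per-epoch history of ``epoch, train_loss, val_loss, val_auc``.  Fully
    seeded: shuffling is the only randomness.  Raises
    :class:`TrainingDiverged` if the loss goes non-finite.
    """
    if not train_bags or not val_bags:
        raise ValidationError("training and validation sets must be non-empty")
    for b in train_bags + val_bags:
        if b.label not in (0, 1):
            raise ValidationError(f"bag {b.subject_id!r} has invalid label {b.label!r}")

    rng = np.random.default_rng(seed)
    attention_params = list(model.pooling.parameters())
    if hasattr(model.patchnet, "attention"):
        attention_params += model.patchnet.attention.parameters()
        attention_params += model.patchnet.effect_head.parameters()
    att_ids = {id(p) for p in attention_params}
    base_params = [p for p in model.parameters() if id(p) not in att_ids]
    no_decay = [p for p in model.parameters() if p.data.ndim == 1]
    opt = eng.Adam(
        [(base_params, 1.0), (attention_params, attention_lr_mult)],
        lr=lr, weight_decay=weight_decay, no_decay=no_decay,
    )
    history: list[dict] = []
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    stale = 0

    for epoch in range(epochs):
        order = rng.permutation(len(train_bags))
        model.train_mode()
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            batch = [train_bags[i] for i in order[start:start + batch_size]]
            for m in model.modules():
                m.zero_grad()
            loss = _batch_loss(model, batch, class_weights,
                               effect_supervision=effect_supervision)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {start // batch_size}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_loss, val_auc = _evaluate_split(model, val_bags)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break

    model.load_state_arrays(best_state)
    return model, history


def ablation_variant(
    k: int,
    patch_width: int,
    flags: tuple = (),
    seed: int = 0,
    **build_kwargs,
) -> BagModel:
    """Build the reduced model for a set of ablation flags.

    ``no_patchnet_cnn`` swaps PatchNet for a fixed average-pool embedding,
    ``no_attention`` bypasses the attention path (uniform weights), and
    ``no_fssa`` is recorded on the model so the pipeline skips refinement.
    """
    return BagModel.build(k, patch_width, ablation_flags=tuple(flags),
                          seed=seed, **build_kwargs)


def clone_model(model: BagModel) -> BagModel:
    """Deep structural copy sharing nothing with the original."""
    return copy.deepcopy(model)
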