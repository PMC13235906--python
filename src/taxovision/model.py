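"""Multi-output hierarchical classifier.

Architecture: a convolutional backbone produces feature maps which are
recalibrated by a Squeeze-and-Excitation block, reduced to a vector by
global max-pooling, and passed through a shared dense embedding (ReLU,
dropout).  Three parallel heads map the embedding to softmax distributions
over families, genera and species.  Four fusion strategies control how a
parent head's logits are injected into the child head's input:

``std``
    each head reads only the shared embedding (no cross-rank wiring);
``concat``
    the genus head reads the embedding concatenated with the family logits,
    the species head the embedding concatenated with the genus logits;
``gated``
    a per-dimension sigmoid gate ``g`` blends the embedding ``e`` with a
    learned transform ``t`` of the parent logits: ``fused = g*e + (1-g)*t``;
``att``
    a small two-layer perceptron with sigmoid output produces a mask in
    (0, 1) per embedding dimension that multiplies the embedding.

The gate and attention perceptrons use a narrow bottleneck hidden layer so
their parameter overhead relative to ``std`` stays well under 1% at
full-size embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autodiff as ad
from .taxonomy import TaxonomyTree, build_taxonomy

FUSION_KINDS = ("std", "concat", "gated", "att")

#: default input resolution (the augmentation pipeline crops to this size)
DEFAULT_INPUT_SIZE = 352


class ConfigError(ValueError):
    pass


@dataclass
class BackboneSpec:
    """Backbone choice. ``small_cnn`` is a compact 3-block CNN for desk-scale
    work; ``resnet50v2`` is the full-size pre-activation residual network.
    Pretrained ImageNet weights are not bundled: ``pretrained=True`` requires
    an explicit ``weights_path``."""

    name: str = "small_cnn"
    pretrained: bool = False
    feature_channels: int = 0  # filled in by the builder
    base_channels: int = 16    # small_cnn width multiplier
    weights_path: str | None = None


@dataclass
class PredictionTriple:
    """Per-sample probability vectors over families, genera and species."""

    p_fam: np.ndarray
    p_gen: np.ndarray
    p_spe: np.ndarray

    def __post_init__(self):
        for name in ("p_fam", "p_gen", "p_spe"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, p)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-5:
                raise ValueError(f"{name} is not a probability vector")

    def argmax_chain(self) -> tuple[int, int, int]:
        return (int(self.p_fam.argmax()), int(self.p_gen.argmax()),
                int(self.p_spe.argmax()))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class SmallCNN(nn.Module):
    """Three conv blocks (conv-ReLU[-maxpool]); ~25k parameters at the
    default width. Output channels: 4 * base_channels."""

    def __init__(self, rng: np.random.Generator, base_channels: int = 16):
        super().__init__()
        c = base_channels
        self.conv1 = nn.Conv2d(3, c, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng, padding=1)
        self.conv3 = nn.Conv2d(2 * c, 4 * c, 3, rng, padding=1)
        self.pool = nn.MaxPool2d(2)
        self.out_channels = 4 * c

    def forward(self, x):
        x = self.pool(ad.relu(self.conv1(x)))
        x = self.pool(ad.relu(self.conv2(x)))
        x = ad.relu(self.conv3(x))
        return x

    def param_layers(self) -> list[nn.Module]:
        """Ordered parameterised layers, input to output (for unfreezing)."""
        return [self.conv1, self.conv2, self.conv3]


class _PreactBottleneck(nn.Module):
    """Pre-activation residual bottleneck (BN-ReLU-conv ordering)."""

    def __init__(self, in_ch: int, filters: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        out_ch = 4 * filters
        self.bn0 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, filters, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(filters)
        self.conv2 = nn.Conv2d(filters, filters, 3, rng, stride=stride,
                               padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(filters)
        self.conv3 = nn.Conv2d(filters, out_ch, 1, rng)
        self.project = (nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride)
                        if (in_ch != out_ch or stride != 1) else None)
        self.out_channels = out_ch

    def forward(self, x):
        pre = ad.relu(self.bn0(x))
        shortcut = self.project(pre) if self.project is not None else x
        y = ad.relu(self.bn1(self.conv1(pre)))
        y = ad.relu(self.bn2(self.conv2(y)))
        y = self.conv3(y)
        return ad.add(y, shortcut)


class ResNet50V2(nn.Module):
    """Pre-activation ResNet-50 (v2): 7x7 stem, bottleneck stages
    [3, 4, 6, 3] at widths 64/128/256/512, final BN+ReLU, 2048 channels."""

    STAGES = ((64, 3), (128, 4), (256, 6), (512, 3))

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = nn.Conv2d(3, 64, 7, rng, stride=2, padding=3)
        self.stem_pool = nn.MaxPool2d(3, stride=2, padding=1)
        blocks: list[nn.Module] = []
        in_ch = 64
        for stage_idx, (filters, n_blocks) in enumerate(self.STAGES):
            for block_idx in range(n_blocks):
                stride = 2 if (stage_idx > 0 and block_idx == 0) else 1
                block = _PreactBottleneck(in_ch, filters, rng, stride=stride)
                blocks.append(block)
                in_ch = block.out_channels
        self.blocks = blocks
        self.post_bn = nn.BatchNorm2d(in_ch)
        self.out_channels = in_ch

    def forward(self, x):
        x = self.stem_pool(self.stem(x))
        for block in self.blocks:
            x = block(x)
        return ad.relu(self.post_bn(x))

    def param_layers(self) -> list[nn.Module]:
        return [self.stem, *self.blocks, self.post_bn]


def _build_backbone(spec: BackboneSpec, rng: np.random.Generator) -> nn.Module:
    if spec.name == "small_cnn":
        backbone = SmallCNN(rng, base_channels=spec.base_channels)
        if spec.pretrained:
            raise ConfigError("small_cnn has no pretrained weights")
    elif spec.name == "resnet50v2":
        backbone = ResNet50V2(rng)
        if spec.pretrained:
            if spec.weights_path is None:
                raise ConfigError(
                    "pretrained resnet50v2 requires weights_path: no weights "
                    "are bundled with the package")
            arrays = np.load(spec.weights_path, allow_pickle=False)
            backbone.load_state_arrays([arrays[k] for k in arrays.files])
    else:
        raise ConfigError(f"unknown backbone {spec.name!r}; "
                          f"expected 'small_cnn' or 'resnet50v2'")
    spec.feature_channels = backbone.out_channels
    return backbone


# ---------------------------------------------------------------------------
# fusion sub-modules
# ---------------------------------------------------------------------------

class _BottleneckMLP(nn.Module):
    """Dense(in -> hidden) + ReLU + Dense(hidden -> out); optionally a final
    sigmoid.  Used for the gated transform/gate and the attention mask."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, sigmoid_out: bool = False):
        super().__init__()
        self.fc1 = nn.Dense(in_dim, hidden, rng)
        self.fc2 = nn.Dense(hidden, out_dim, rng)
        self.sigmoid_out = sigmoid_out

    def forward(self, x):
        h = ad.relu(self.fc1(x))
        out = self.fc2(h)
        return ad.sigmoid(out) if self.sigmoid_out else out


class _GatedFusion(nn.Module):
    """fused = g * e + (1 - g) * t(parent_logits); g = sigmoid MLP on
    the concatenation [e, t]."""

    def __init__(self, parent_dim: int, emb_dim: int, hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.transform = _BottleneckMLP(parent_dim, hidden, emb_dim, rng)
        self.gate = _BottleneckMLP(2 * emb_dim, hidden, emb_dim, rng,
                                   sigmoid_out=True)

    def forward(self, inputs):
        emb, parent_logits = inputs
        t = self.transform(parent_logits)
        g = self.gate(ad.concat([emb, t], axis=1))
        one_minus_g = ad.add(ad.mul(g, -1.0), 1.0)
        return ad.add(ad.mul(g, emb), ad.mul(one_minus_g, t))


class _AttentionFusion(nn.Module):
    """fused = mask * e with mask in (0,1) from a two-layer sigmoid MLP on
    the parent logits."""

    def __init__(self, parent_dim: int, emb_dim: int, hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.mask_mlp = _BottleneckMLP(parent_dim, hidden, emb_dim, rng,
                                       sigmoid_out=True)

    def forward(self, inputs):
        emb, parent_logits = inputs
        return ad.mul(self.mask_mlp(parent_logits), emb)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class HierarchicalClassifier(nn.Module):
    """Backbone -> SE -> global max-pool -> shared embedding -> three heads."""

    def __init__(self, tree: TaxonomyTree, backbone: BackboneSpec | None = None,
                 fusion: str = "std", dropout: float = 0.3,
                 embedding_dim: int = 2048, se_reduction: int = 16,
                 fusion_hidden: int | None = None, seed: int = 0):
        super().__init__()
        if fusion not in FUSION_KINDS:
            raise ConfigError(f"unknown fusion kind {fusion!r}; "
                              f"expected one of {FUSION_KINDS}")
        backbone = backbone or BackboneSpec()
        rng = np.random.default_rng(seed)
        self.tree = tree
        self.fusion = fusion
        self.backbone_spec = backbone
        self.backbone = _build_backbone(backbone, rng)
        c = self.backbone.out_channels
        self.se_reduction = se_reduction
        self.se = nn.SEBlock(c, se_reduction, rng)
        self.embed = nn.Dense(c, embedding_dim, rng)
        self.dropout = nn.Dropout(dropout, np.random.default_rng(seed + 1))
        self.embedding_dim = embedding_dim

        nf, ng, ns = tree.rank_sizes
        hidden = fusion_hidden or max(8, embedding_dim // 256)
        self.fusion_hidden = hidden
        head_in_gen = head_in_spe = embedding_dim
        if fusion == "concat":
            head_in_gen, head_in_spe = embedding_dim + nf, embedding_dim + ng
        elif fusion == "gated":
            self.fuse_gen = _GatedFusion(nf, embedding_dim, hidden, rng)
            self.fuse_spe = _GatedFusion(ng, embedding_dim, hidden, rng)
        elif fusion == "att":
            self.fuse_gen = _AttentionFusion(nf, embedding_dim, hidden, rng)
            self.fuse_spe = _AttentionFusion(ng, embedding_dim, hidden, rng)
        self.head_fam = nn.Dense(embedding_dim, nf, rng, init="head")
        self.head_gen = nn.Dense(head_in_gen, ng, rng, init="head")
        self.head_spe = nn.Dense(head_in_spe, ns, rng, init="head")

    # -- forward --------------------------------------------------------
    def forward(self, x):
        """x: Tensor or array, NCHW. Returns (fam, gen, spe) logit Tensors."""
        x = ad.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW input with 3 channels, "
                             f"got shape {x.shape}")
        feats = self.se(self.backbone(x))
        pooled = ad.global_max_pool2d(feats)
        emb = self.dropout(ad.relu(self.embed(pooled)))
        fam_logits = self.head_fam(emb)
        if self.fusion == "std":
            gen_logits = self.head_gen(emb)
            spe_logits = self.head_spe(emb)
        elif self.fusion == "concat":
            gen_logits = self.head_gen(ad.concat([emb, fam_logits], axis=1))
            spe_logits = self.head_spe(ad.concat([emb, gen_logits], axis=1))
        else:
            gen_logits = self.head_gen(self.fuse_gen((emb, fam_logits)))
            spe_logits = self.head_spe(self.fuse_spe((emb, gen_logits)))
        return fam_logits, gen_logits, spe_logits

    # -- inference ------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 64
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Softmax probabilities for an NHWC float image batch in [0, 1]."""
        was_training = self.training
        self.eval()
        try:
            outs = [[], [], []]
            for start in range(0, len(images), batch_size):
                batch = _to_nchw(images[start:start + batch_size])
                logits = self.forward(ad.Tensor(batch))
                for acc, lg in zip(outs, logits):
                    acc.append(softmax(lg.data))
            return tuple(np.concatenate(o, axis=0) for o in outs)
        finally:
            self.train(was_training)

    def trainable_layer_sequence(self) -> list[nn.Module]:
        if hasattr(self.backbone, "param_layers"):
            return self.backbone.param_layers()
        return [self.backbone]


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    if images.shape[-1] == 3:
        images = images.transpose(0, 3, 1, 2)
    return images


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def se_block(features: np.ndarray, reduction: int,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised SE block to NCHW feature maps (numpy in,
    numpy out). Mostly useful for inspection; inside a model the block is a
    trained layer."""
    rng = rng or np.random.default_rng(0)
    block = nn.SEBlock(features.shape[1], reduction, rng)
    return block(ad.Tensor(np.asarray(features, dtype=np.float64))).data


def build_model(tree: TaxonomyTree, backbone: BackboneSpec | None = None,
                fusion: str = "std", dropout: float = 0.3,
                **kwargs) -> HierarchicalClassifier:
    """Construct a :class:`HierarchicalClassifier` for the given taxonomy."""
    return HierarchicalClassifier(tree, backbone=backbone, fusion=fusion,
                                  dropout=dropout, **kwargs)


def forward(model: HierarchicalClassifier, images: np.ndarray
            ) -> list[PredictionTriple]:
    """Run a batch of NHWC images through the model and wrap each sample's
    softmax outputs in a :class:`PredictionTriple` (order-preserving)."""
    pf, pg, ps = model.predict_proba(images)
    return [PredictionTriple(pf[i], pg[i], ps[i]) for i in range(len(pf))]


def count_parameters(model: nn.Module) -> int:
    """Total trainable parameter count."""
    return int(sum(p.size for p in model.parameters(trainable_only=True)))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: HierarchicalClassifier, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar recording taxonomy+config."""
    path = Path(path)
    arrays = {f"arr_{i:05d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "taxonomy": model.tree.triples(),
        "fusion": model.fusion,
        "backbone": {"name": model.backbone_spec.name,
                     "base_channels": model.backbone_spec.base_channels},
        "embedding_dim": model.embedding_dim,
        "fusion_hidden": model.fusion_hidden,
        "dropout": model.dropout.p,
        "se_reduction": model.se_reduction,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> HierarchicalClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    tree = build_taxonomy([tuple(t) for t in sidecar["taxonomy"]])
    spec = BackboneSpec(name=sidecar["backbone"]["name"],
                        base_channels=sidecar["backbone"]["base_channels"])
    model = HierarchicalClassifier(
        tree, backbone=spec, fusion=sidecar["fusion"],
        dropout=sidecar["dropout"], embedding_dim=sidecar["embedding_dim"],
        se_reduction=sidecar["se_reduction"],
        fusion_hidden=sidecar["fusion_hidden"])
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    model.load_state_arrays([arrays[k] for k in sorted(arrays.files)])
    return model
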