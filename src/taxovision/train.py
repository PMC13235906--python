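"""Two-stage training protocol, experiment harnesses, and the
scikit-learn-style estimator.

Training follows a transfer-learning schedule: stage 1 trains the SE block,
shared embedding and heads with any pretrained backbone layers frozen;
stage 2 additionally unfreezes the top ``unfreeze_top_layers`` backbone
layers at a lower learning rate.  A backbone without pretrained weights
(e.g. ``small_cnn``) has nothing to protect, so by default it trains
end-to-end in both stages; ``freeze_backbone_stage1=True`` forces the
frozen protocol regardless.

The optimizer is Adam (stage-1 lr 1e-3, stage-2 lr 1e-5 by default).  All
randomness — shuffling, dropout, augmentation — derives from the config
seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .augment import AugmentConfig, augment_batch
from .dataqc import stratified_split
from .loss import LossConfig, tfcl_graph
from .metrics import EvalBatch, evaluate, mcnemar, tas
from .model import (BackboneSpec, HierarchicalClassifier, _to_nchw,
                    build_model)
from .nn import Adam
from .nn import autodiff as ad
from .syndata import SyntheticDataset, SyntheticSpec, generate_dataset
from .taxonomy import TaxonomyTree, labels_to_array

logger = logging.getLogger(__name__)

FUSIONS = ("std", "concat", "gated", "att")


@dataclass
class TrainConfig:
    batch_size: int = 32
    stage1_epochs: int = 15
    stage2_epochs: int = 10
    unfreeze_top_layers: int = 75
    input_size: int = 352
    seed: int = 0
    lr_stage1: float = 1e-3
    lr_stage2: float = 1e-5
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig | None = None
    freeze_backbone_stage1: bool | str = "auto"

    def __post_init__(self):
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _as_labels(y) -> np.ndarray:
    if hasattr(y, "__len__") and len(y) and hasattr(y[0], "as_tuple"):
        return labels_to_array(y)
    return np.asarray(y, dtype=np.int64)


def _run_epoch(model: HierarchicalClassifier, X: np.ndarray, y: np.ndarray,
               optimizer: Adam, config: TrainConfig,
               rng: np.random.Generator) -> dict[str, float]:
    order = rng.permutation(len(X))
    sums = np.zeros(4)
    n_batches = 0
    for start in range(0, len(X), config.batch_size):
        idx = order[start:start + config.batch_size]
        batch = X[idx]
        if config.augment is not None and config.augment.enabled:
            batch = augment_batch(batch, config.augment, rng)
        logits = model.forward(ad.Tensor(_to_nchw(batch)))
        l_fam, l_gen, l_spe, l_total = tfcl_graph(
            logits, y[idx], model.tree, config.loss)
        optimizer.zero_grad()
        l_total.backward()
        optimizer.step()
        sums += [float(t.data) for t in (l_fam, l_gen, l_spe, l_total)]
        n_batches += 1
    keys = ("loss_fam", "loss_gen", "loss_spe", "loss_total")
    return dict(zip(keys, sums / max(n_batches, 1)))


def _validate(model: HierarchicalClassifier, X: np.ndarray, y: np.ndarray,
              config: TrainConfig) -> dict[str, float]:
    pf, pg, ps = model.predict_proba(X, batch_size=config.batch_size)
    batch = EvalBatch(pf, pg, ps, y)
    preds = batch.argmax_chains()
    from .loss import tfcl_batch

    comp = tfcl_batch(pf, pg, ps, y, model.tree, config.loss)
    return {
        "val_loss": comp.l_total,
        "val_species_accuracy": float((preds[:, 2] == y[:, 2]).mean()),
        "val_tas": tas(batch, model.tree),
    }


def train_two_stage(model: HierarchicalClassifier, X_train: np.ndarray,
                    y_train, X_val: np.ndarray | None = None,
                    y_val=None, config: TrainConfig | None = None
                    ) -> list[dict]:
    """Train in place; returns the per-epoch history (loss components and,
    when a validation set is given, validation loss/accuracy/TAS)."""
    config = config or TrainConfig()
    y_train = _as_labels(y_train)
    y_val = _as_labels(y_val) if y_val is not None else None
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []

    freeze = config.freeze_backbone_stage1
    if freeze == "auto":
        freeze = model.backbone_spec.pretrained
    model.train()

    # stage 1: backbone frozen (if applicable); embedding/SE/heads learn
    if freeze:
        model.backbone.freeze()
    optimizer = Adam(model.parameters(trainable_only=True), lr=config.lr_stage1)
    for epoch in range(config.stage1_epochs):
        record = {"stage": 1, "epoch": epoch}
        record.update(_run_epoch(model, X_train, y_train, optimizer, config, rng))
        if X_val is not None:
            record.update(_validate(model, X_val, y_val, config))
        history.append(record)

    # stage 2: unfreeze the top layers, fine-tune at a lower rate
    if config.stage2_epochs > 0:
        layers = model.trainable_layer_sequence()
        k = config.unfreeze_top_layers
        if k > len(layers):
            logger.warning("unfreeze_top_layers=%d exceeds backbone depth %d; "
                           "clipping", k, len(layers))
            k = len(layers)
        if freeze:
            for layer in layers[len(layers) - k:]:
                layer.unfreeze()
        optimizer = Adam(model.parameters(trainable_only=True),
                         lr=config.lr_stage2)
        for epoch in range(config.stage2_epochs):
            record = {"stage": 2, "epoch": epoch}
            record.update(_run_epoch(model, X_train, y_train, optimizer,
                                     config, rng))
            if X_val is not None:
                record.update(_validate(model, X_val, y_val, config))
            history.append(record)
    model.eval()
    return history


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class TaxonomicClassifier(ClassifierMixin, BaseEstimator):
    """Hierarchical (family/genus/species) image classifier.

    A scikit-learn-compatible wrapper around the multi-output CNN: ``fit``
    builds the model for the given taxonomy and runs the two-stage protocol
    with the taxonomy-focal cross-loss; ``predict`` returns (N, 3) index
    triples, ``predict_proba`` the three per-rank probability matrices.
    ``score`` is species-level accuracy.

    Parameters mirror the training configuration; pass the
    :class:`~taxovision.taxonomy.TaxonomyTree` as ``taxonomy``.
    """

    def __init__(self, taxonomy: TaxonomyTree | None = None,
                 backbone: str = "small_cnn", base_channels: int = 16,
                 pretrained: bool = False, fusion: str = "std",
                 embedding_dim: int = 256, se_reduction: int = 16,
                 dropout: float = 0.3, alpha: float = 0.25, gamma: float = 2.0,
                 lambda_gen: float = 0.1, lambda_spe: float = 0.1,
                 batch_size: int = 32, stage1_epochs: int = 15,
                 stage2_epochs: int = 10, unfreeze_top_layers: int = 75,
                 lr_stage1: float = 1e-3, lr_stage2: float = 1e-5,
                 augment_config: AugmentConfig | None = None,
                 freeze_backbone_stage1: bool | str = "auto",
                 random_state: int = 0):
        self.taxonomy = taxonomy
        self.backbone = backbone
        self.base_channels = base_channels
        self.pretrained = pretrained
        self.fusion = fusion
        self.embedding_dim = embedding_dim
        self.se_reduction = se_reduction
        self.dropout = dropout
        self.alpha = alpha
        self.gamma = gamma
        self.lambda_gen = lambda_gen
        self.lambda_spe = lambda_spe
        self.batch_size = batch_size
        self.stage1_epochs = stage1_epochs
        self.stage2_epochs = stage2_epochs
        self.unfreeze_top_layers = unfreeze_top_layers
        self.lr_stage1 = lr_stage1
        self.lr_stage2 = lr_stage2
        self.augment_config = augment_config
        self.freeze_backbone_stage1 = freeze_backbone_stage1
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, stage1_epochs=self.stage1_epochs,
            stage2_epochs=self.stage2_epochs,
            unfreeze_top_layers=self.unfreeze_top_layers,
            seed=self.random_state, lr_stage1=self.lr_stage1,
            lr_stage2=self.lr_stage2,
            loss=LossConfig(self.alpha, self.gamma, self.lambda_gen,
                            self.lambda_spe),
            augment=self.augment_config,
            freeze_backbone_stage1=self.freeze_backbone_stage1)

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be an (N, H, W, 3) image stack, "
                             f"got shape {X.shape}")
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValueError("image values must lie in [0, 1]")
        return X

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        if self.taxonomy is None:
            raise ValueError("TaxonomicClassifier requires a taxonomy")
        X = self._check_X(X)
        y = _as_labels(y)
        if len(X) != len(y) or y.shape[1] != 3:
            raise ValueError("y must be (N, 3) label-index triples matching X")
        spec = BackboneSpec(name=self.backbone, pretrained=self.pretrained,
                            base_channels=self.base_channels)
        self.model_ = build_model(
            self.taxonomy, backbone=spec, fusion=self.fusion,
            dropout=self.dropout, embedding_dim=self.embedding_dim,
            se_reduction=self.se_reduction, seed=self.random_state)
        self.history_ = train_two_stage(self.model_, X, y, X_val, y_val,
                                        self._train_config())
        self.classes_ = np.arange(self.taxonomy.n_species)
        self.families_ = self.taxonomy.families
        self.genera_ = self.taxonomy.genera
        self.species_ = self.taxonomy.species
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        self._check_fitted()
        return self.model_.predict_proba(self._check_X(X),
                                         batch_size=self.batch_size)

    def predict(self, X):
        pf, pg, ps = self.predict_proba(X)
        return np.stack([pf.argmax(axis=1), pg.argmax(axis=1),
                         ps.argmax(axis=1)], axis=1)

    def score(self, X, y, sample_weight=None):
        """Species-level accuracy."""
        y = _as_labels(y)
        return float(np.average(self.predict(X)[:, 2] == y[:, 2],
                                weights=sample_weight))

    def evaluate(self, X, y) -> dict:
        """Full metric report (per-rank metrics, TAS, alignment, ECE)."""
        pf, pg, ps = self.predict_proba(X)
        return evaluate(EvalBatch(pf, pg, ps, _as_labels(y)), self.taxonomy)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

def _split_dataset(dataset: SyntheticDataset, seed: int):
    assignment = stratified_split(dataset.manifest, seed=seed)
    subsets = {}
    for name in ("train", "val", "test"):
        ids = set(assignment.subset_ids(name))
        mask = dataset.manifest["path"].isin(ids).to_numpy()
        subsets[name] = (dataset.images[mask], dataset.labels[mask])
    split_hash = hashlib.sha256(
        ",".join(f"{k}:{v}" for k, v in sorted(assignment.assignment.items()))
        .encode()).hexdigest()[:16]
    return subsets, split_hash


def compare_fusions(dataset: SyntheticDataset, base_config: TrainConfig,
                    estimator_kwargs: dict | None = None,
                    fusions: tuple[str, ...] = FUSIONS) -> dict:
    """Train one model per fusion kind under identical conditions and
    report per-fusion metrics plus pairwise McNemar tests on species-level
    correctness.  All rows are evaluated on the identical test split, whose
    hash is recorded."""
    estimator_kwargs = estimator_kwargs or {}
    subsets, split_hash = _split_dataset(dataset, base_config.seed)
    X_test, y_test = subsets["test"]
    rows, species_correct = [], {}
    for fusion in fusions:
        clf = TaxonomicClassifier(
            taxonomy=dataset.tree, fusion=fusion,
            batch_size=base_config.batch_size,
            stage1_epochs=base_config.stage1_epochs,
            stage2_epochs=base_config.stage2_epochs,
            unfreeze_top_layers=base_config.unfreeze_top_layers,
            lr_stage1=base_config.lr_stage1, lr_stage2=base_config.lr_stage2,
            alpha=base_config.loss.alpha, gamma=base_config.loss.gamma,
            lambda_gen=base_config.loss.lambda_gen,
            lambda_spe=base_config.loss.lambda_spe,
            augment_config=base_config.augment,
            freeze_backbone_stage1=base_config.freeze_backbone_stage1,
            random_state=base_config.seed, **estimator_kwargs)
        clf.fit(*subsets["train"], X_val=subsets["val"][0],
                y_val=subsets["val"][1])
        report = clf.evaluate(X_test, y_test)
        species_correct[fusion] = clf.predict(X_test)[:, 2] == y_test[:, 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append({
                "fusion": fusion,
                "species_accuracy": report["per_rank"]["species"]["accuracy"],
                "genus_accuracy": report["per_rank"]["genus"]["accuracy"],
                "family_accuracy": report["per_rank"]["family"]["accuracy"],
                "precision": report["per_rank"]["species"]["precision"],
                "recall": report["per_rank"]["species"]["recall"],
                "tas": report["tas"],
                "ece_species": report["ece"]["species"],
                "alignment_genus": report["alignment_given_miss"]["genus"],
                "alignment_species": report["alignment_given_miss"]["species"],
            })
    pairwise = {}
    for a, b in itertools.combinations(fusions, 2):
        res = mcnemar(species_correct[a], species_correct[b])
        pairwise[(a, b)] = {"statistic": res.statistic, "p_value": res.p_value,
                            "b": res.b, "c": res.c, "exact": res.exact}
    return {"table": pd.DataFrame(rows), "mcnemar": pairwise,
            "split_hash": split_hash}


def compare_data_regimes(spec: SyntheticSpec, config: TrainConfig,
                         estimator_kwargs: dict | None = None) -> dict:
    """Train the same architecture on (a) 100% web-regime images and (b) a
    50:50 lab/web mix of identical size, and report the metric deltas."""
    estimator_kwargs = estimator_kwargs or {}
    web_spec = replace(spec, mode_mix=1.0)
    mixed_spec = replace(spec, mode_mix=0.5)
    results = {}
    counts = {}
    for arm, arm_spec in (("web_only", web_spec), ("mixed", mixed_spec)):
        dataset = generate_dataset(arm_spec)
        counts[arm] = dataset.manifest["species"].value_counts().sort_index()
        subsets, split_hash = _split_dataset(dataset, config.seed)
        clf = TaxonomicClassifier(
            taxonomy=dataset.tree, batch_size=config.batch_size,
            stage1_epochs=config.stage1_epochs,
            stage2_epochs=config.stage2_epochs,
            lr_stage1=config.lr_stage1, lr_stage2=config.lr_stage2,
            augment_config=config.augment,
            freeze_backbone_stage1=config.freeze_backbone_stage1,
            random_state=config.seed, **estimator_kwargs)
        clf.fit(*subsets["train"])
        results[arm] = clf.evaluate(*subsets["test"])
        results[arm]["split_hash"] = split_hash
    if not counts["web_only"].equals(counts["mixed"]):
        raise ValueError("per-species image counts differ between arms")
    deltas = {}
    for rank in ("family", "genus", "species"):
        deltas[f"{rank}_accuracy"] = (
            results["mixed"]["per_rank"][rank]["accuracy"]
            - results["web_only"]["per_rank"][rank]["accuracy"])
    deltas["tas"] = results["mixed"]["tas"] - results["web_only"]["tas"]
    return {"web_only": results["web_only"], "mixed": results["mixed"],
            "delta": deltas}
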