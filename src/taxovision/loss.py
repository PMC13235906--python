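"""Taxonomy-Focal Cross-Loss (TFCL).

Per rank, the loss is focal cross-entropy

    L_focal(p_t) = -alpha * (1 - p_t)^gamma * ln(p_t)

where ``p_t`` is the probability assigned to the true class, ``alpha``
balances positive/negative examples and ``gamma`` focuses learning on hard
(low ``p_t``) examples.  The genus and species losses additionally carry a
soft hierarchical-consistency penalty: the negative log of the probability
mass the *parent* head assigns to the true label's parent taxon,

    L_gen = L_focal(p_gen[y_gen]) + lambda_gen * (-ln p_fam[par_gen(y_gen)])
    L_spe = L_focal(p_spe[y_spe]) + lambda_spe * (-ln p_gen[par_spe(y_spe)])

and the total is the plain sum L_fam + L_gen + L_spe.  Probabilities are
clamped at 1e-7 from below; logs are natural; batch reduction is the mean.

Two routes are provided: a numpy route on probability vectors (evaluation,
worked examples) and a graph route on logits (training), which share the
same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .taxonomy import LabelTriple, TaxonomyTree

EPS = 1e-7
LOG_EPS = float(np.log(EPS))


@dataclass
class LossConfig:
    """alpha in (0,1], gamma >= 0, lambdas >= 0.  Defaults are the canonical
    focal-loss setting (alpha=0.25, gamma=2) with mild consistency weights."""

    alpha: float = 0.25
    gamma: float = 2.0
    lambda_gen: float = 0.1
    lambda_spe: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.lambda_gen < 0 or self.lambda_spe < 0:
            raise ValueError("consistency weights must be >= 0")


@dataclass(frozen=True)
class TfclComponents:
    l_fam: float
    l_gen: float
    l_spe: float

    @property
    def l_total(self) -> float:
        return self.l_fam + self.l_gen + self.l_spe

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.l_fam, self.l_gen, self.l_spe, self.l_total)


def focal_ce(p_t: float | np.ndarray, alpha: float, gamma: float
             ) -> float | np.ndarray:
    """-alpha * (1 - p_t)^gamma * ln(p_t), with p_t clamped at 1e-7."""
    p = np.clip(np.asarray(p_t, dtype=np.float64), EPS, 1.0)
    out = -alpha * (1.0 - p) ** gamma * np.log(p)
    return float(out) if out.ndim == 0 else out


def tfcl(pred, label: LabelTriple, tree: TaxonomyTree,
         config: LossConfig | None = None) -> TfclComponents:
    """Single-sample TFCL components from a PredictionTriple-like object
    (anything with p_fam / p_gen / p_spe probability vectors)."""
    config = config or LossConfig()
    label.validate(tree)
    y_fam, y_gen, y_spe = label.as_tuple()
    p_fam = np.asarray(pred.p_fam, dtype=np.float64)
    p_gen = np.asarray(pred.p_gen, dtype=np.float64)
    p_spe = np.asarray(pred.p_spe, dtype=np.float64)

    l_fam = focal_ce(p_fam[y_fam], config.alpha, config.gamma)
    l_gen = (focal_ce(p_gen[y_gen], config.alpha, config.gamma)
             + config.lambda_gen
             * -np.log(max(p_fam[tree.family_of_genus(y_gen)], EPS)))
    l_spe = (focal_ce(p_spe[y_spe], config.alpha, config.gamma)
             + config.lambda_spe
             * -np.log(max(p_gen[tree.genus_of_species(y_spe)], EPS)))
    return TfclComponents(float(l_fam), float(l_gen), float(l_spe))


def tfcl_batch(p_fam: np.ndarray, p_gen: np.ndarray, p_spe: np.ndarray,
               labels: np.ndarray, tree: TaxonomyTree,
               config: LossConfig | None = None) -> TfclComponents:
    """Mean TFCL components over a batch of probability matrices (N, K_rank)
    and an (N, 3) label-index array."""
    config = config or LossConfig()
    labels = np.asarray(labels)
    y_fam, y_gen, y_spe = labels[:, 0], labels[:, 1], labels[:, 2]
    rows = np.arange(len(labels))
    par_g = tree.parent_of_genus[y_gen]
    par_s = tree.parent_of_species[y_spe]
    l_fam = focal_ce(p_fam[rows, y_fam], config.alpha, config.gamma)
    l_gen = (focal_ce(p_gen[rows, y_gen], config.alpha, config.gamma)
             + config.lambda_gen * -np.log(np.clip(p_fam[rows, par_g], EPS, 1)))
    l_spe = (focal_ce(p_spe[rows, y_spe], config.alpha, config.gamma)
             + config.lambda_spe * -np.log(np.clip(p_gen[rows, par_s], EPS, 1)))
    return TfclComponents(float(l_fam.mean()), float(l_gen.mean()),
                          float(l_spe.mean()))


def _focal_from_logp(logp: Tensor, alpha: float, gamma: float) -> Tensor:
    logp = ad.clip_min(logp, LOG_EPS)
    p = ad.exp(logp)
    one_minus_p = ad.add(ad.mul(p, -1.0), 1.0)
    return ad.mul(ad.mul(ad.pow_const(one_minus_p, gamma), logp), -alpha)


def tfcl_graph(logits: tuple[Tensor, Tensor, Tensor], labels: np.ndarray,
               tree: TaxonomyTree, config: LossConfig | None = None
               ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Differentiable TFCL on head logits; returns (L_fam, L_gen, L_spe,
    L_total) scalar Tensors, each the batch mean."""
    config = config or LossConfig()
    labels = np.asarray(labels)
    fam_logits, gen_logits, spe_logits = logits
    y_fam, y_gen, y_spe = labels[:, 0], labels[:, 1], labels[:, 2]
    # reject labels inconsistent with the tree before building the graph
    if (np.any(tree.parent_of_species[y_spe] != y_gen)
            or np.any(tree.parent_of_genus[y_gen] != y_fam)):
        from .taxonomy import HierarchyViolationError
        raise HierarchyViolationError("label batch contains triples "
                                      "inconsistent with the taxonomy")

    logp_fam = ad.log_softmax(fam_logits, axis=1)
    logp_gen = ad.log_softmax(gen_logits, axis=1)
    logp_spe = ad.log_softmax(spe_logits, axis=1)

    l_fam = ad.tmean(_focal_from_logp(ad.gather_rows(logp_fam, y_fam),
                                      config.alpha, config.gamma))
    pen_gen = ad.mul(ad.clip_min(
        ad.gather_rows(logp_fam, tree.parent_of_genus[y_gen]), LOG_EPS), -1.0)
    l_gen = ad.add(
        ad.tmean(_focal_from_logp(ad.gather_rows(logp_gen, y_gen),
                                  config.alpha, config.gamma)),
        ad.mul(ad.tmean(pen_gen), config.lambda_gen))
    pen_spe = ad.mul(ad.clip_min(
        ad.gather_rows(logp_gen, tree.parent_of_species[y_spe]), LOG_EPS), -1.0)
    l_spe = ad.add(
        ad.tmean(_focal_from_logp(ad.gather_rows(logp_spe, y_spe),
                                  config.alpha, config.gamma)),
        ad.mul(ad.tmean(pen_spe), config.lambda_spe))
    l_total = ad.add(ad.add(l_fam, l_gen), l_spe)
    return l_fam, l_gen, l_spe, l_total
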