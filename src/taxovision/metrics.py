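"""Evaluation suite for hierarchical predictions.

Includes the Taxonomic Alignment Score (TAS) — the fraction of samples
whose argmax (family, genus, species) triple forms a valid parent chain in
the taxonomy, independent of label correctness — alongside per-rank
accuracy/macro-precision/recall/F1, cross-rank partial-credit alignment,
expected calibration error with reliability curves, paired McNemar tests,
per-species error binning, and the error-vs-genus-richness regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .taxonomy import LabelTriple, TaxonomyTree

RANKS = ("family", "genus", "species")


@dataclass
class EvalBatch:
    """Stacked predicted probabilities and true labels for N samples.

    ``p_fam``/``p_gen``/``p_spe`` are (N, K_rank) probability matrices;
    ``labels`` is an (N, 3) integer array of (family, genus, species).
    """

    p_fam: np.ndarray
    p_gen: np.ndarray
    p_spe: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.labels)
        if n < 1:
            raise ValueError("EvalBatch requires at least one sample")
        for name in ("p_fam", "p_gen", "p_spe"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, p)
            if len(p) != n:
                raise ValueError(f"{name} length {len(p)} != labels {n}")

    @classmethod
    def from_triples(cls, predictions, labels) -> "EvalBatch":
        """Build from lists of PredictionTriple and LabelTriple."""
        lab = np.array([t.as_tuple() if isinstance(t, LabelTriple) else tuple(t)
                        for t in labels])
        return cls(np.stack([p.p_fam for p in predictions]),
                   np.stack([p.p_gen for p in predictions]),
                   np.stack([p.p_spe for p in predictions]), lab)

    @property
    def n(self) -> int:
        return len(self.labels)

    def argmax_chains(self) -> np.ndarray:
        """(N, 3) array of predicted (family, genus, species) indices.
        Softmax ties break toward the lowest index (numpy argmax)."""
        return np.stack([self.p_fam.argmax(axis=1), self.p_gen.argmax(axis=1),
                         self.p_spe.argmax(axis=1)], axis=1)


def tas(batch: EvalBatch, tree: TaxonomyTree) -> float:
    """Taxonomic Alignment Score: mean indicator of
    parent(genus_i) = family_i AND parent(species_i) = genus_i over the
    predicted argmax chains.  1.0 means every predicted chain is valid."""
    f, g, s = batch.argmax_chains().T
    ok = (tree.parent_of_genus[g] == f) & (tree.parent_of_species[s] == g)
    return float(ok.mean())


def tas_random_baseline(tree: TaxonomyTree) -> float:
    """Probability that a uniformly random (f, g, s) triple is consistent:
    one valid chain per species out of all index combinations."""
    nf, ng, ns = tree.rank_sizes
    return ns / (nf * ng * ns)


def per_rank_metrics(batch: EvalBatch, tree: TaxonomyTree,
                     average: str = "macro") -> dict[str, dict[str, float]]:
    """Accuracy plus averaged precision/recall/F1 per rank.

    Macro averaging (the default) weights all classes present in the labels
    equally, which matters under the class imbalance typical of taxonomic
    datasets; ``average='micro'`` is available as a switch.
    """
    preds = batch.argmax_chains()
    out = {}
    for r, rank in enumerate(RANKS):
        y_true, y_pred = batch.labels[:, r], preds[:, r]
        present = np.unique(y_true)
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=present, average=average, zero_division=0)
        out[rank] = {
            "accuracy": float((y_true == y_pred).mean()),
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
        }
    return out


def alignment_given_miss(batch: EvalBatch, tree: TaxonomyTree,
                         level: str) -> float:
    """Partial credit on misses: among samples misclassified at ``level``
    ('genus' or 'species'), the fraction whose predicted taxon still lies
    under the true parent (genus -> family, species -> genus).

    Returns NaN (with a warning) when there are no misses at the level.
    """
    preds = batch.argmax_chains()
    if level == "genus":
        true, pred = batch.labels[:, 1], preds[:, 1]
        parent = tree.parent_of_genus
    elif level == "species":
        true, pred = batch.labels[:, 2], preds[:, 2]
        parent = tree.parent_of_species
    else:
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    miss = pred != true
    if not miss.any():
        warnings.warn(f"no misclassifications at {level} level; "
                      f"alignment-given-miss is undefined")
        return float("nan")
    return float((parent[pred[miss]] == parent[true[miss]]).mean())


@dataclass
class CalibrationCurve:
    """Reliability-diagram table over equal-width confidence bins."""

    bin_edges: np.ndarray
    mean_confidence: np.ndarray
    accuracy: np.ndarray
    count: np.ndarray

    def ece(self) -> float:
        n = self.count.sum()
        occupied = self.count > 0
        return float(np.sum(self.count[occupied] / n
                            * np.abs(self.accuracy[occupied]
                                     - self.mean_confidence[occupied])))


def reliability(confidences: np.ndarray, correct_flags: np.ndarray,
                n_bins: int = 10) -> CalibrationCurve:
    """Bin argmax confidences into ``n_bins`` equal-width bins on [0, 1] and
    tabulate per-bin mean confidence and empirical accuracy."""
    conf = np.asarray(confidences, dtype=np.float64)
    correct = np.asarray(correct_flags, dtype=bool)
    if conf.min() < 0 or conf.max() > 1:
        raise ValueError("confidences must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(conf, edges[1:-1]), 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_conf = np.where(count > 0,
                             np.bincount(idx, weights=conf, minlength=n_bins)
                             / np.maximum(count, 1), 0.0)
        acc = np.where(count > 0,
                       np.bincount(idx, weights=correct, minlength=n_bins)
                       / np.maximum(count, 1), 0.0)
    return CalibrationCurve(edges, mean_conf, acc, count)


def ece(confidences: np.ndarray, correct_flags: np.ndarray,
        n_bins: int = 10) -> float:
    """Expected calibration error: sum_b (n_b/N) |acc_b - conf_b|.
    Empty bins contribute 0; invariant to sample order."""
    return reliability(confidences, correct_flags, n_bins).ece()


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    exact: bool
    degenerate: bool = False


def mcnemar(correct_a, correct_b) -> McNemarResult:
    """Paired McNemar test on two correctness-flag vectors.

    Uses the exact two-sided binomial test on the discordant counts when
    b + c < 25, otherwise the chi-squared statistic with continuity
    correction.  b + c = 0 yields p = 1.0 with a degenerate flag.
    """
    a = np.asarray(correct_a, dtype=bool)
    bflags = np.asarray(correct_b, dtype=bool)
    if a.shape != bflags.shape:
        raise ValueError("flag vectors must have equal length")
    b = int(np.sum(a & ~bflags))
    c = int(np.sum(~a & bflags))
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, b, c, exact=True, degenerate=True)
    if n < 25:
        res = stats.binomtest(min(b, c), n, 0.5, alternative="two-sided")
        return McNemarResult(float(min(b, c)), float(min(res.pvalue, 1.0)),
                             b, c, exact=True)
    statistic = (abs(b - c) - 1) ** 2 / n
    return McNemarResult(float(statistic),
                         float(stats.chi2.sf(statistic, df=1)), b, c,
                         exact=False)


# -- per-species analyses ------------------------------------------------

ERROR_BINS = {"low": (0.0, 0.10), "moderate": (0.10, 0.25),
              "high": (0.25, 1.0)}


def species_errors(batch: EvalBatch, tree: TaxonomyTree) -> dict[int, float]:
    """Recall-derived error (1 - recall) per species present in the labels."""
    pred = batch.p_spe.argmax(axis=1)
    true = batch.labels[:, 2]
    out = {}
    for s in np.unique(true):
        mask = true == s
        out[int(s)] = float(1.0 - (pred[mask] == s).mean())
    return out


def per_species_error_bins(batch: EvalBatch, tree: TaxonomyTree
                           ) -> dict[str, list[int]]:
    """Bin species by error rate: low (<=10%), moderate (10-25%], high
    (>25%); boundaries inclusive in the lower bin."""
    errors = species_errors(batch, tree)
    bins: dict[str, list[int]] = {"low": [], "moderate": [], "high": []}
    for s, err in sorted(errors.items()):
        if err <= 0.10:
            bins["low"].append(s)
        elif err <= 0.25:
            bins["moderate"].append(s)
        else:
            bins["high"].append(s)
    return bins


@dataclass
class RichnessTrend:
    slope: float
    intercept: float
    pearson_r: float
    n_species: int


def error_vs_genus_richness(batch: EvalBatch, tree: TaxonomyTree
                            ) -> RichnessTrend:
    """OLS slope and Pearson correlation of species error against genus
    richness (species per genus).  Undefined correlation (zero variance in
    richness) yields r = NaN with a warning."""
    errors = species_errors(batch, tree)
    if len(errors) < 3:
        raise ValueError("need at least 3 species with test samples")
    richness = tree.species_per_genus()
    x = np.array([richness[tree.genus_of_species(s)] for s in errors],
                 dtype=np.float64)
    y = np.array(list(errors.values()), dtype=np.float64)
    if np.ptp(x) == 0:
        warnings.warn("genus richness has zero variance; "
                      "correlation undefined")
        return RichnessTrend(0.0, float(y.mean()), float("nan"), len(y))
    fit = stats.linregress(x, y)
    r = fit.rvalue if np.ptp(y) > 0 else float("nan")
    return RichnessTrend(float(fit.slope), float(fit.intercept), float(r),
                         len(y))


def evaluate(batch: EvalBatch, tree: TaxonomyTree, n_bins: int = 10
             ) -> dict:
    """One-stop evaluation: per-rank metrics, TAS, alignment fractions,
    per-head ECE."""
    preds = batch.argmax_chains()
    report: dict = {"n": batch.n, "per_rank": per_rank_metrics(batch, tree),
                    "tas": tas(batch, tree)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report["alignment_given_miss"] = {
            lvl: alignment_given_miss(batch, tree, lvl)
            for lvl in ("genus", "species")}
    for r, (rank, p) in enumerate(zip(RANKS,
                                      (batch.p_fam, batch.p_gen, batch.p_spe))):
        conf = p.max(axis=1)
        correct = preds[:, r] == batch.labels[:, r]
        report.setdefault("ece", {})[rank] = ece(conf, correct, n_bins)
    return report
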