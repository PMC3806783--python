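"""Evaluation machinery: ROC/AUC, lambda tuning, cutoff selection, MCC,
and the phenotype-randomization control.

Labels follow the candidate-restricted convention: for each evaluated gene
only its *scored* candidates enter the label list — a candidate in the
gene's positive set is a positive, every other candidate a negative.
Phenotypes never inferred for the gene are not added as zero-score
negatives (doing so would rescale the false-positive rate by the arbitrary
size of the phenome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .iodata import AssociationTable, GeneId, PhenotypeId, World
from .scoring import ScoringConfig, combine, normalized_components

__all__ = [
    "RocCurve",
    "ConfusionCounts",
    "LambdaSweepResult",
    "UndefinedAucError",
    "roc_auc",
    "select_top_genes",
    "lambda_sweep",
    "pooled_candidates",
    "pooled_roc",
    "best_cutoff",
    "mcc",
    "randomization_test",
]


class UndefinedAucError(ValueError):
    """Raised when an instance has no positive or no negative label."""


@dataclass
class RocCurve:
    """A ROC curve swept over all distinct score thresholds.

    ``thresholds[i]`` is the score cutoff producing point
    (``fpr[i]``, ``tpr[i]``) under the rule "predict positive when
    score >= threshold"; the first threshold is +inf (point (0, 0)).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion count")


@dataclass
class LambdaSweepResult:
    """Grid of lambda values with the mean per-gene AUC at each."""

    grid: list[float]
    mean_auc: list[float]
    best_lambda: float
    per_gene_auc: dict[GeneId, list[float]]
    n_skipped: int = 0  # genes with undefined AUC, excluded from every mean


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC for one score/label instance.

    Tied scores are grouped: all items sharing a score move across the
    threshold together, which makes the AUC equal to the Mann-Whitney
    statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                    n_pos=n_pos, n_neg=n_neg)


def select_top_genes(assoc: AssociationTable, world: World, n: int) -> list[GeneId]:
    """The evaluation panel: genes with known phenotypes and both kinds of
    evidence (at least one PPI edge and at least one ortholog), ranked by
    known-phenotype count descending, ties by identifier, truncated to n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    qualifying = [
        g for g in assoc.genes()
        if world.net.has_gene(g) and world.orth.has_gene(g)
    ]
    qualifying.sort(key=lambda g: (-len(assoc.phenotypes_of(g)), g))
    return qualifying[:n]


def _labeled_components(gene, world, config, positive_set, exclude_set=None):
    """Candidate components of one gene plus its boolean label vector.

    ``exclude_set`` drops candidates from the evaluation list entirely —
    used when scoring against held-out truth, where the gene's visible
    (training) associations are neither positives nor honest negatives.
    """
    cands = normalized_components(
        gene, world.net, world.orth, world.assoc, world.phenet, config
    )
    if exclude_set is not None:
        dropped = exclude_set.phenotypes_of(gene)
        cands = [c for c in cands if c.phenotype not in dropped]
    positives = positive_set.phenotypes_of(gene)
    labels = np.array([c.phenotype in positives for c in cands], dtype=bool)
    return cands, labels


def lambda_sweep(
    genes,
    world: World,
    grid_step: float = 0.1,
    config: ScoringConfig | None = None,
    positive_set: AssociationTable | None = None,
    exclude_set: AssociationTable | None = None,
) -> LambdaSweepResult:
    """Mean per-gene AUC over a lambda grid from 0 to 1.

    Each gene's candidates are labeled by membership in its positive set
    (its known phenotypes by default); genes whose label vector has no
    positive or no negative have undefined AUC and are skipped from every
    mean (their count is reported). The best lambda is the argmax of the
    mean AUC; exact ties break toward the LARGEST lambda, so a world whose
    orthology channel carries no information reports the pure-PPI weight 1
    rather than an arbitrary interior mixture (and symmetrically the noise
    in an uninformative PPI channel drives the optimum to 0).
    """
    config = config or ScoringConfig()
    positive_set = positive_set if positive_set is not None else world.assoc
    k = round(1.0 / grid_step)
    if abs(k * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid step {grid_step} does not divide 1")
    grid = [round(i * grid_step, 10) for i in range(k + 1)]

    per_gene: dict[GeneId, list[float]] = {}
    n_skipped = 0
    for g in genes:
        cands, labels = _labeled_components(g, world, config, positive_set, exclude_set)
        if not cands or labels.all() or not labels.any():
            n_skipped += 1
            continue
        norm_p = np.array([c.norm_ppi for c in cands])
        norm_o = np.array([c.norm_orth for c in cands])
        aucs = []
        for lam in grid:
            comb = lam * norm_p + (1.0 - lam) * norm_o
            top = comb.max()
            final = comb / top if top > 0 else comb
            aucs.append(roc_auc(final, labels).auc)
        per_gene[g] = aucs
    if not per_gene:
        raise UndefinedAucError("no gene yields a defined AUC")
    mean_auc = [float(np.mean([per_gene[g][i] for g in per_gene]))
                for i in range(len(grid))]
    best_i = max(range(len(grid)), key=lambda i: (mean_auc[i], grid[i]))
    return LambdaSweepResult(grid=grid, mean_auc=mean_auc,
                             best_lambda=grid[best_i], per_gene_auc=per_gene,
                             n_skipped=n_skipped)


def pooled_candidates(
    genes,
    world: World,
    config: ScoringConfig,
    positive_set: AssociationTable | None = None,
    exclude_set: AssociationTable | None = None,
):
    """All genes' scored candidates pooled into one score/label list.

    Returns (records, scores, labels) where records are
    (gene, phenotype, final_score) triples in deterministic order.
    """
    positive_set = positive_set if positive_set is not None else world.assoc
    records = []
    labels = []
    for g in sorted(set(genes)):
        cands, _ = _labeled_components(g, world, config, positive_set, exclude_set)
        combine(cands, config)
        positives = positive_set.phenotypes_of(g)
        for c in sorted(cands, key=lambda c: c.phenotype):
            records.append((g, c.phenotype, c.final_score))
            labels.append(c.phenotype in positives)
    scores = np.array([r[2] for r in records], dtype=float)
    return records, scores, np.array(labels, dtype=bool)


def pooled_roc(
    genes,
    world: World,
    lambda_weight: float,
    config: ScoringConfig | None = None,
    positive_set: AssociationTable | None = None,
    exclude_set: AssociationTable | None = None,
) -> RocCurve:
    """ROC over the pooled candidates of a gene panel at one lambda."""
    base = config or ScoringConfig()
    cfg = ScoringConfig(
        lambda_weight=lambda_weight,
        experimental_ppi_only=base.experimental_ppi_only,
        phenet_aggregation=base.phenet_aggregation,
        final_normalization=base.final_normalization,
        min_combined=base.min_combined,
    )
    _, scores, labels = pooled_candidates(genes, world, cfg, positive_set, exclude_set)
    return roc_auc(scores, labels)


def best_cutoff(curve: RocCurve) -> tuple[float, ConfusionCounts]:
    """Cutoff where the ROC curve meets the descending diagonal.

    Selects the curve point minimizing |TPR - (1 - FPR)| — the point where
    sensitivity equals specificity — taking the earliest threshold on
    ties, and returns that threshold with its confusion counts.
    """
    d = np.abs(curve.tpr - (1.0 - curve.fpr))
    i = int(np.argmin(d))  # argmin returns the first minimum: earliest threshold
    tp = int(round(curve.tpr[i] * curve.n_pos))
    fp = int(round(curve.fpr[i] * curve.n_neg))
    counts = ConfusionCounts(tp=tp, tn=curve.n_neg - fp, fp=fp, fn=curve.n_pos - tp)
    return float(curve.thresholds[i]), counts


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient, 0 when any marginal is empty."""
    tp, tn, fp, fn = (float(counts.tp), float(counts.tn),
                      float(counts.fp), float(counts.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def randomization_test(
    genes,
    world: World,
    lambda_weight: float,
    threshold: float,
    n_rounds: int = 100,
    seed: int = 0,
    config: ScoringConfig | None = None,
    positive_set: AssociationTable | None = None,
    exclude_set: AssociationTable | None = None,
    exclude_true: bool = False,
) -> tuple[float, list[float]]:
    """MCC of the prediction at a fixed cutoff against a phenotype-shuffle null.

    The observed MCC labels pooled candidates by the true positive sets.
    Each randomization round replaces every gene's positive set with a
    uniform sample (without replacement) of equal size drawn from the
    gene's species phenome — true positives are not excluded from the draw
    unless ``exclude_true`` — and recomputes the MCC at the same cutoff.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    config = config or ScoringConfig()
    cfg = ScoringConfig(
        lambda_weight=lambda_weight,
        experimental_ppi_only=config.experimental_ppi_only,
        phenet_aggregation=config.phenet_aggregation,
        final_normalization=config.final_normalization,
        min_combined=config.min_combined,
    )
    positive_set = positive_set if positive_set is not None else world.assoc
    records, scores, labels = pooled_candidates(genes, world, cfg, positive_set, exclude_set)
    observed = mcc(_confusion_at(scores, labels, threshold))

    gene_list = sorted(set(genes))
    phenomes = {sp: world.phenome(sp) for sp in {g.species for g in gene_list}}
    k_true = {
        g: len(positive_set.phenotypes_of(g)) for g in gene_list
    }
    for g, k in k_true.items():
        pool = phenomes[g.species]
        if exclude_true:
            pool = [p for p in pool if p not in positive_set.phenotypes_of(g)]
        if k > len(pool):
            raise ValueError(
                f"phenome of {g.species} ({len(pool)}) smaller than the "
                f"positive set of {g} ({k})"
            )

    rng = np.random.default_rng(seed)
    randomized: list[float] = []
    for _ in range(n_rounds):
        fake_pos: dict[GeneId, set[PhenotypeId]] = {}
        for g in gene_list:
            pool = phenomes[g.species]
            if exclude_true:
                pool = [p for p in pool if p not in positive_set.phenotypes_of(g)]
            k = k_true[g]
            idx = rng.choice(len(pool), size=k, replace=False) if k else []
            fake_pos[g] = {pool[j] for j in idx}
        fake_labels = np.array(
            [ph in fake_pos[g] for g, ph, _ in records], dtype=bool
        )
        randomized.append(mcc(_confusion_at(scores, fake_labels, threshold)))
    return observed, randomized
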