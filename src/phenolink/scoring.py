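"""Gene-phenotype candidate scoring.

A phenotype ``Ph`` is a candidate for a query gene ``G`` when it is
reachable by at least one of two evidence routes:

* **PPI path** (guilt-by-association): an interaction partner ``P_i`` of
  ``G`` is known to be associated with ``Ph``. The raw PPI score is the sum
  of the interaction reliabilities over all such partners,
  ``sum_i s_ppi(G, P_i)`` over ``P_i in interactors(G) ∩ p(Ph)``.

* **Orthology path**: a cross-species ortholog ``O_i`` of ``G`` is known to
  be associated with some phenotype ``Ph'`` of its own species that is
  similar to ``Ph`` in the cross-species phenotype similarity table. The
  raw orthology score is ``sum_i s_orth(G, O_i) * s_phnet(O_i, Ph)`` where
  ``s_orth`` is the domain-composition cosine of the two proteins and
  ``s_phnet`` aggregates (max by default) the similarities of ``O_i``'s
  known phenotypes to ``Ph``.

Each raw component is normalized by its maximum over the gene's candidate
set, the two are blended with the mixing weight ``lambda`` (weight of the
PPI component), and the blend is normalized once more per gene so the top
candidate scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .iodata import (
    AssociationTable,
    DomainProfile,
    GeneId,
    InteractionNetwork,
    OrthologyMap,
    PhenotypeId,
    PhenotypeSimilarityTable,
    World,
)

__all__ = [
    "PathEvidence",
    "ScoredCandidate",
    "ScoringConfig",
    "domain_cosine",
    "raw_ppi_score",
    "raw_orthology_score",
    "normalized_components",
    "score_gene",
    "score_phenotype",
]


@dataclass(frozen=True)
class PathEvidence:
    """One summand of a raw path score.

    ``via`` is the interaction partner (PPI path) or the ortholog
    (orthology path); for orthology paths ``phenotype_link`` records the
    ortholog's known phenotype and its similarity to the query phenotype
    that realized the aggregate.
    """

    kind: str  # "ppi" | "orthology"
    via: GeneId
    contribution: float
    phenotype_link: tuple[PhenotypeId, float] | None = None

    def __post_init__(self) -> None:
        if self.contribution <= 0:
            raise ValueError("evidence contribution must be positive")
        if self.kind == "orthology" and self.phenotype_link is None:
            raise ValueError("orthology evidence requires a phenotype link")

    def token(self) -> str:
        """Compact serialization for the ranked-output TSV."""
        if self.kind == "ppi":
            return f"ppi:{self.via}:{self.contribution:.4g}"
        ph, sim = self.phenotype_link
        return f"orth:{self.via}>{ph}@{sim:.4g}:{self.contribution:.4g}"


@dataclass
class ScoredCandidate:
    """A (gene, phenotype) candidate with all score stages and its evidence."""

    gene: GeneId
    phenotype: PhenotypeId
    raw_ppi: float
    raw_orth: float
    norm_ppi: float = 0.0
    norm_orth: float = 0.0
    combined_raw: float = 0.0
    final_score: float = 0.0
    is_known: bool = False
    evidence: list[PathEvidence] = field(default_factory=list)


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable knobs of the scorer.

    lambda_weight
        Mixing weight of the normalized PPI component against the
        normalized orthology component, in [0, 1].
    experimental_ppi_only
        Restrict PPI paths to edges whose experimental-channel score is
        available and at least ``min_combined``, using that score.
    phenet_aggregation
        How an ortholog's several similar phenotypes collapse into one
        gene-phenotype similarity: ``"max"`` (default) or ``"sum"``.
    final_normalization
        ``"max"`` divides the blend by the gene's maximum (top candidate
        scores 1); ``"sum"`` divides by the sum over the gene's candidates.
        Both are ranking-equivalent.
    """

    lambda_weight: float = 0.8
    experimental_ppi_only: bool = False
    phenet_aggregation: str = "max"
    final_normalization: str = "max"
    min_combined: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError(f"lambda weight {self.lambda_weight} outside [0, 1]")
        if self.phenet_aggregation not in ("max", "sum"):
            raise ValueError("phenet_aggregation must be 'max' or 'sum'")
        if self.final_normalization not in ("max", "sum"):
            raise ValueError("final_normalization must be 'max' or 'sum'")


def domain_cosine(a: DomainProfile, b: DomainProfile) -> float:
    """Cosine similarity of two domain-count vectors over their domain union.

    Returns 0.0 when either protein has no scanned domains.
    """
    if not a.counts or not b.counts:
        return 0.0
    dot = sum(c * b.counts.get(d, 0) for d, c in a.counts.items())
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(c * c for c in a.counts.values()))
    nb = math.sqrt(sum(c * c for c in b.counts.values()))
    return min(1.0, dot / (na * nb))


def _edge_ppi_score(edge, config: ScoringConfig) -> float | None:
    """Usable PPI reliability of an edge under the config, or None."""
    if config.experimental_ppi_only:
        s = edge.experimental_only_score
        if s is None or s < config.min_combined:
            return None
        return s
    return edge.combined_score


def raw_ppi_score(
    g: GeneId,
    ph: PhenotypeId,
    net: InteractionNetwork,
    assoc: AssociationTable,
    config: ScoringConfig | None = None,
) -> tuple[float, list[PathEvidence]]:
    """Sum of interaction scores over partners of ``g`` known for ``ph``.

    ``g``'s own association with ``ph`` is not a PPI path.
    """
    config = config or ScoringConfig()
    if g.species != ph.species:
        raise ValueError(f"species mismatch: {g} vs {ph}")
    total = 0.0
    evidence: list[PathEvidence] = []
    known = assoc.genes_of(ph)
    for partner, edge in net.neighbors(g):
        if partner not in known:
            continue
        s = _edge_ppi_score(edge, config)
        if s is None or s <= 0:
            continue
        total += s
        evidence.append(PathEvidence("ppi", partner, s))
    return total, evidence


def raw_orthology_score(
    g: GeneId,
    ph: PhenotypeId,
    orth: OrthologyMap,
    assoc: AssociationTable,
    phenet: PhenotypeSimilarityTable,
    aggregation: str = "max",
) -> tuple[float, list[PathEvidence]]:
    """Sum over orthologs of ``g`` of domain-cosine x phenotype-similarity.

    For each ortholog ``O`` with at least one known phenotype similar to
    ``ph`` in the filtered similarity table, the per-ortholog similarity is
    the ``aggregation`` (max or sum) over those phenotypes.
    """
    if g.species != ph.species:
        raise ValueError(f"species mismatch: {g} vs {ph}")
    total = 0.0
    evidence: list[PathEvidence] = []
    for ortholog, s_orth in orth.partners(g):
        if s_orth <= 0:
            continue
        links = []
        for ph_o in sorted(assoc.phenotypes_of(ortholog)):
            sim = phenet.similarity(ph_o, ph)
            if sim > 0:
                links.append((ph_o, sim))
        if not links:
            continue
        if aggregation == "max":
            best_ph, best_sim = max(links, key=lambda t: (t[1], t[0]))
            contrib = s_orth * best_sim
            if contrib > 0:
                total += contrib
                evidence.append(PathEvidence("orthology", ortholog, contrib,
                                             phenotype_link=(best_ph, best_sim)))
        else:  # sum: one evidence item per realizing phenotype
            for ph_o, sim in links:
                contrib = s_orth * sim
                if contrib > 0:
                    total += contrib
                    evidence.append(PathEvidence("orthology", ortholog, contrib,
                                                 phenotype_link=(ph_o, sim)))
    return total, evidence


def _candidate_phenotypes(
    g: GeneId,
    net: InteractionNetwork,
    orth: OrthologyMap,
    assoc: AssociationTable,
    phenet: PhenotypeSimilarityTable,
    config: ScoringConfig,
) -> set[PhenotypeId]:
    """Phenotypes of g's species reachable by at least one evidence route."""
    cands: set[PhenotypeId] = set()
    for partner, edge in net.neighbors(g):
        if _edge_ppi_score(edge, config) is None:
            continue
        cands |= assoc.phenotypes_of(partner)
    for ortholog, s_orth in orth.partners(g):
        if s_orth <= 0:
            continue
        for ph_o in assoc.phenotypes_of(ortholog):
            for ph_q, _sim in phenet.neighbors(ph_o):
                if ph_q.species == g.species:
                    cands.add(ph_q)
    return {ph for ph in cands if ph.species == g.species}


def normalized_components(
    g: GeneId,
    net: InteractionNetwork,
    orth: OrthologyMap,
    assoc: AssociationTable,
    phenet: PhenotypeSimilarityTable,
    config: ScoringConfig | None = None,
) -> list[ScoredCandidate]:
    """Candidates of ``g`` with raw and max-normalized path components.

    The blend stages (``combined_raw``, ``final_score``) are left at 0 so a
    caller sweeping lambda can recombine cheaply; :func:`score_gene`
    finishes the job for one lambda.

    A component whose maximum over the candidate set is 0 normalizes to 0
    for every candidate (no 0/0).
    """
    config = config or ScoringConfig()
    known = assoc.phenotypes_of(g)
    out: list[ScoredCandidate] = []
    for ph in sorted(_candidate_phenotypes(g, net, orth, assoc, phenet, config)):
        rp, ev_p = raw_ppi_score(g, ph, net, assoc, config)
        ro, ev_o = raw_orthology_score(g, ph, orth, assoc, phenet,
                                       config.phenet_aggregation)
        if rp <= 0 and ro <= 0:
            continue
        out.append(ScoredCandidate(
            gene=g, phenotype=ph, raw_ppi=rp, raw_orth=ro,
            is_known=ph in known, evidence=ev_p + ev_o,
        ))
    max_p = max((c.raw_ppi for c in out), default=0.0)
    max_o = max((c.raw_orth for c in out), default=0.0)
    for c in out:
        c.norm_ppi = c.raw_ppi / max_p if max_p > 0 else 0.0
        c.norm_orth = c.raw_orth / max_o if max_o > 0 else 0.0
    return out


def combine(candidates: list[ScoredCandidate], config: ScoringConfig) -> list[ScoredCandidate]:
    """Blend normalized components at the config's lambda and re-normalize.

    Mutates the candidates in place; returns them sorted by final score
    descending, ties broken by phenotype identifier ascending.
    """
    lam = config.lambda_weight
    for c in candidates:
        c.combined_raw = lam * c.norm_ppi + (1.0 - lam) * c.norm_orth
    if config.final_normalization == "max":
        denom = max((c.combined_raw for c in candidates), default=0.0)
    else:
        denom = sum(c.combined_raw for c in candidates)
    for c in candidates:
        c.final_score = c.combined_raw / denom if denom > 0 else 0.0
    candidates.sort(key=lambda c: (-c.final_score, c.phenotype))
    return candidates


def score_gene(
    g: GeneId,
    config: ScoringConfig,
    net: InteractionNetwork,
    orth: OrthologyMap,
    assoc: AssociationTable,
    phenet: PhenotypeSimilarityTable,
) -> list[ScoredCandidate]:
    """Rank all candidate phenotypes of one query gene.

    Returns the gene's candidates (phenotypes with a positive raw PPI or
    orthology score) sorted by final score descending; empty when the gene
    has no evidence path at all. Phenotypes already known for the gene are
    retained and flagged ``is_known`` (the evaluation machinery uses them
    as positive labels).
    """
    return combine(normalized_components(g, net, orth, assoc, phenet, config), config)


def score_gene_in_world(g: GeneId, config: ScoringConfig, world: World) -> list[ScoredCandidate]:
    """Convenience wrapper over :func:`score_gene` for a loaded world."""
    return score_gene(g, config, world.net, world.orth, world.assoc, world.phenet)


def score_phenotype(
    ph: PhenotypeId,
    config: ScoringConfig,
    net: InteractionNetwork,
    orth: OrthologyMap,
    assoc: AssociationTable,
    phenet: PhenotypeSimilarityTable,
    gene_universe=None,
) -> list[tuple[GeneId, float]]:
    """Rank candidate genes of one phenotype.

    Every gene's score for ``ph`` is exactly its :func:`score_gene` entry
    (normalization stays per-gene, not per-phenotype), so the two entry
    points agree on every (gene, phenotype) pair. Ranked by final score
    descending, ties by gene identifier.
    """
    if gene_universe is None:
        world = World(net, orth, {}, assoc, phenet)
        gene_universe = world.gene_universe(ph.species)
    out: list[tuple[GeneId, float]] = []
    for g in sorted(set(gene_universe)):
        if g.species != ph.species:
            continue
        for cand in score_gene(g, config, net, orth, assoc, phenet):
            if cand.phenotype == ph:
                out.append((g, cand.final_score))
                break
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
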