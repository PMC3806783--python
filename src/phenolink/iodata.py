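"""Tabular and ontology I/O for gene-phenotype inference.

All external tables are plain TSV with a one-line header, mirroring the
shape of STRING / PfamScan / annotation-database exports without binding to
any particular database snapshot:

* PPI edges: ``protein_a  species_a  protein_b  species_b  combined_score
  [experimental_score]``
* Orthology pairs: ``gene  species  ortholog  ortholog_species``
* Domain hits: ``protein  species  domain`` (one row per PfamScan hit;
  repeated rows increment the count)
* Associations: ``gene  species  phenotype``
* Phenotype similarity: ``term_a  species_a  term_b  species_b  similarity``
* Gene sets: GMT (``name TAB description TAB member ...``)
* Term names: OBO 1.2 (``[Term]`` id/name stanzas only)

Load-time filtering applies the reliability thresholds (combined score and
cross-species phenotype similarity both >= 0.5 by default) so that no
downstream computation ever sees a sub-threshold edge.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Default species registry (short codes used in every table).
DEFAULT_SPECIES: tuple[str, ...] = (
    "fly", "human", "mouse", "worm", "yeast", "zebrafish",
)


class FormatError(ValueError):
    """An input table violates its dialect; message names the offending line."""


# ---------------------------------------------------------------------------
# identifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneId:
    """A gene/protein identifier qualified by its species code."""

    species: str
    identifier: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty gene identifier")
        if not self.species:
            raise ValueError("empty species code")

    def __str__(self) -> str:
        return f"{self.species}:{self.identifier}"


@dataclass(frozen=True, order=True)
class PhenotypeId:
    """An ontology phenotype term qualified by its species code."""

    species: str
    identifier: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty phenotype identifier")

    def __str__(self) -> str:
        return f"{self.species}:{self.identifier}"


def _check_species(code: str, registry: Sequence[str], line: int, path) -> None:
    if code not in registry:
        raise FormatError(
            f"{path}, line {line}: unknown species code {code!r} "
            f"(registry: {', '.join(registry)})"
        )


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PpiEdge:
    """An undirected scored interaction between two same-species proteins.

    ``combined_score`` is the STRING-style reliability after any noisy-OR
    fusion with injected experimental evidence; ``experimental_only_score``
    is the purely experimental channel when known.
    """

    a: GeneId
    b: GeneId
    combined_score: float
    experimental_only_score: float | None = None
    source_tag: str = "string_like"

    def __post_init__(self) -> None:
        if self.a.species != self.b.species:
            raise ValueError(f"cross-species PPI edge {self.a} -- {self.b}")
        if self.a == self.b:
            raise ValueError(f"self-interaction {self.a}")
        if self.a > self.b:  # canonical undirected storage
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined score {self.combined_score} outside [0, 1]")

    def partner(self, g: GeneId) -> GeneId:
        return self.b if g == self.a else self.a


class InteractionNetwork:
    """Per-species filtered PPI edges, queryable by gene."""

    def __init__(self, edges: Iterable[PpiEdge] = ()) -> None:
        self._g = nx.Graph()
        for e in edges:
            self.add(e)

    def add(self, edge: PpiEdge) -> None:
        self._g.add_edge(edge.a, edge.b, edge=edge)

    def neighbors(self, gene: GeneId) -> list[tuple[GeneId, PpiEdge]]:
        if gene not in self._g:
            return []
        return sorted(
            ((n, self._g.edges[gene, n]["edge"]) for n in self._g.neighbors(gene)),
            key=lambda t: t[0],
        )

    def edge(self, a: GeneId, b: GeneId) -> PpiEdge | None:
        if self._g.has_edge(a, b):
            return self._g.edges[a, b]["edge"]
        return None

    def has_gene(self, gene: GeneId) -> bool:
        return gene in self._g

    def genes(self) -> list[GeneId]:
        return sorted(self._g.nodes)

    def edges(self) -> list[PpiEdge]:
        return sorted(
            (d["edge"] for _, _, d in self._g.edges(data=True)),
            key=lambda e: (e.a, e.b),
        )

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __len__(self) -> int:
        return self._g.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.edges() == other.edges()


# ---------------------------------------------------------------------------
# domains and orthology
# ---------------------------------------------------------------------------

@dataclass
class DomainProfile:
    """Multiset of protein-family domains detected on one protein."""

    protein: GeneId
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dom, c in self.counts.items():
            if c < 1:
                raise ValueError(f"non-positive domain count {dom}={c}")

    def __bool__(self) -> bool:
        return bool(self.counts)


@dataclass(frozen=True)
class OrthologPair:
    """A cross-species ortholog pair weighted by domain-composition cosine."""

    gene: GeneId
    ortholog: GeneId
    domain_similarity: float

    def __post_init__(self) -> None:
        if self.gene.species == self.ortholog.species:
            raise ValueError(f"same-species ortholog pair {self.gene} -- {self.ortholog}")
        if self.gene > self.ortholog:
            lo, hi = self.ortholog, self.gene
            object.__setattr__(self, "gene", lo)
            object.__setattr__(self, "ortholog", hi)
        if not 0.0 <= self.domain_similarity <= 1.0:
            raise ValueError(f"domain similarity {self.domain_similarity} outside [0, 1]")


class OrthologyMap:
    """Cross-species ortholog pairs, indexed in both directions."""

    def __init__(self, pairs: Iterable[OrthologPair] = ()) -> None:
        self._pairs: dict[tuple[GeneId, GeneId], OrthologPair] = {}
        self._by_gene: dict[GeneId, list[tuple[GeneId, float]]] = defaultdict(list)
        for p in pairs:
            self.add(p)

    def add(self, pair: OrthologPair) -> None:
        key = (pair.gene, pair.ortholog)
        if key in self._pairs:
            return
        self._pairs[key] = pair
        self._by_gene[pair.gene].append((pair.ortholog, pair.domain_similarity))
        self._by_gene[pair.ortholog].append((pair.gene, pair.domain_similarity))

    def partners(self, gene: GeneId) -> list[tuple[GeneId, float]]:
        """Orthologs of ``gene`` with their domain similarities, sorted."""
        return sorted(self._by_gene.get(gene, []))

    def has_gene(self, gene: GeneId) -> bool:
        return gene in self._by_gene

    def pairs(self) -> list[OrthologPair]:
        return sorted(self._pairs.values(), key=lambda p: (p.gene, p.ortholog))

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyMap):
            return NotImplemented
        return self.pairs() == other.pairs()


# ---------------------------------------------------------------------------
# phenotype similarity
# ---------------------------------------------------------------------------

class PhenotypeSimilarityTable:
    """Cross-species phenotype-phenotype similarities (PhenomeNET surrogate).

    Undirected; stored once per canonical pair, queryable in either
    orientation. Only edges surviving the load-time similarity filter are
    ever present.
    """

    def __init__(self) -> None:
        self._sim: dict[tuple[PhenotypeId, PhenotypeId], float] = {}
        self._by_term: dict[PhenotypeId, list[tuple[PhenotypeId, float]]] = defaultdict(list)

    @staticmethod
    def _key(a: PhenotypeId, b: PhenotypeId) -> tuple[PhenotypeId, PhenotypeId]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: PhenotypeId, b: PhenotypeId, similarity: float) -> None:
        if not 0.0 <= similarity <= 1.0:
            raise ValueError(f"similarity {similarity} outside [0, 1]")
        key = self._key(a, b)
        old = self._sim.get(key)
        if old is not None:
            if similarity > old:  # duplicates collapse to the maximum
                self._sim[key] = similarity
                self._reindex(a, b, similarity)
            return
        self._sim[key] = similarity
        self._by_term[a].append((b, similarity))
        if a != b:
            self._by_term[b].append((a, similarity))

    def _reindex(self, a: PhenotypeId, b: PhenotypeId, sim: float) -> None:
        self._by_term[a] = [(t, sim if t == b else s) for t, s in self._by_term[a]]
        self._by_term[b] = [(t, sim if t == a else s) for t, s in self._by_term[b]]

    def similarity(self, a: PhenotypeId, b: PhenotypeId) -> float:
        """Similarity of the pair in either orientation; 0.0 if absent."""
        return self._sim.get(self._key(a, b), 0.0)

    def neighbors(self, term: PhenotypeId) -> list[tuple[PhenotypeId, float]]:
        return sorted(self._by_term.get(term, []))

    def terms(self) -> list[PhenotypeId]:
        return sorted(self._by_term)

    def edges(self) -> list[tuple[PhenotypeId, PhenotypeId, float]]:
        return sorted((a, b, s) for (a, b), s in self._sim.items())

    def __len__(self) -> int:
        return len(self._sim)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeSimilarityTable):
            return NotImplemented
        return self._sim == other._sim


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

class AssociationTable:
    """Known same-species gene -> phenotype links with both indexes.

    Doubles as the evaluation gold standard: the per-gene index supplies the
    positive labels and the per-phenotype index supplies p(Ph), the genes
    known to be associated with a phenotype.
    """

    def __init__(self, records: Iterable[tuple[GeneId, PhenotypeId]] = ()) -> None:
        self._records: set[tuple[GeneId, PhenotypeId]] = set()
        self._by_gene: dict[GeneId, set[PhenotypeId]] = defaultdict(set)
        self._by_ph: dict[PhenotypeId, set[GeneId]] = defaultdict(set)
        for g, ph in records:
            self.add(g, ph)

    def add(self, gene: GeneId, phenotype: PhenotypeId) -> None:
        if gene.species != phenotype.species:
            raise ValueError(
                f"species mismatch: gene {gene} vs phenotype {phenotype}"
            )
        rec = (gene, phenotype)
        if rec in self._records:
            return
        self._records.add(rec)
        self._by_gene[gene].add(phenotype)
        self._by_ph[phenotype].add(gene)

    def phenotypes_of(self, gene: GeneId) -> set[PhenotypeId]:
        return set(self._by_gene.get(gene, ()))

    def genes_of(self, phenotype: PhenotypeId) -> set[GeneId]:
        """p(Ph): all genes known to be associated with the phenotype."""
        return set(self._by_ph.get(phenotype, ()))

    def genes(self) -> list[GeneId]:
        return sorted(self._by_gene)

    def phenotypes(self, species: str | None = None) -> list[PhenotypeId]:
        phs = self._by_ph.keys()
        if species is not None:
            phs = (p for p in phs if p.species == species)
        return sorted(phs)

    def records(self) -> list[tuple[GeneId, PhenotypeId]]:
        return sorted(self._records)

    def __contains__(self, record: tuple[GeneId, PhenotypeId]) -> bool:
        return record in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return self._records == other._records


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) plus the union universe."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return sorted(self.sets)

    def mean_set_size(self) -> float:
        if not self.sets:
            raise ValueError("empty gene-set collection")
        sizes = [len(m) for _, m in self.sets.values()]
        return sum(sizes) / len(sizes)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# the assembled world
# ---------------------------------------------------------------------------

@dataclass
class World:
    """All loaded tables needed to score gene-phenotype candidates."""

    net: InteractionNetwork
    orth: OrthologyMap
    domains: dict[GeneId, DomainProfile]
    assoc: AssociationTable
    phenet: PhenotypeSimilarityTable

    def phenome(self, species: str) -> list[PhenotypeId]:
        """All phenotype terms of one species seen anywhere in the world."""
        terms = {p for p in self.assoc.phenotypes() if p.species == species}
        terms |= {t for t in self.phenet.terms() if t.species == species}
        return sorted(terms)

    def gene_universe(self, species: str | None = None) -> list[GeneId]:
        genes = set(self.net.genes()) | set(self.assoc.genes())
        genes |= {p.gene for p in self.orth.pairs()} | {p.ortholog for p in self.orth.pairs()}
        if species is not None:
            genes = {g for g in genes if g.species == species}
        return sorted(genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, World):
            return NotImplemented
        return (
            self.net == other.net
            and self.orth == other.orth
            and self.domains == other.domains
            and self.assoc == other.assoc
            and self.phenet == other.phenet
        )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_table(path, columns: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    """Read a headered TSV, checking required columns and field counts."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(columns))
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
    bad = df.index[vals.isna() & (df[col] != "")]
    if len(bad):
        line = int(bad[0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}, line {line}: non-numeric value {df[col][bad[0]]!r} in {col}")
    return vals


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_ppi(
    path,
    min_combined: float = 0.5,
    experimental_injections=None,
    injection_score: float = 0.9,
    species_registry: Sequence[str] = DEFAULT_SPECIES,
) -> InteractionNetwork:
    """Load a scored PPI edge list, filter, and inject experimental pairs.

    Duplicate / reversed rows for the same pair collapse to the maximum
    score before combination. A pair present both in the base table and in
    the injection list receives the noisy-OR combination
    ``1 - (1 - s_base) * (1 - injection_score)``; injection-only pairs carry
    ``injection_score``. Only edges with a final combined score of at least
    ``min_combined`` survive.
    """
    df = _read_table(path, ["protein_a", "species_a", "protein_b", "species_b",
                            "combined_score"])
    has_exp = "experimental_score" in df.columns
    scores = _numeric_column(df, "combined_score", path)
    exp_scores = _numeric_column(df, "experimental_score", path) if has_exp else None

    base: dict[tuple[GeneId, GeneId], float] = {}
    base_exp: dict[tuple[GeneId, GeneId], float] = {}
    n_read = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        n_read += 1
        _check_species(row.species_a, species_registry, line, path)
        _check_species(row.species_b, species_registry, line, path)
        if row.species_a != row.species_b:
            raise FormatError(
                f"{path}, line {line}: cross-species edge "
                f"{row.species_a}:{row.protein_a} -- {row.species_b}:{row.protein_b}"
            )
        s = float(scores[i])
        if not 0.0 <= s <= 1.0:
            raise FormatError(f"{path}, line {line}: combined score {s} outside [0, 1]")
        a = GeneId(row.species_a, row.protein_a)
        b = GeneId(row.species_b, row.protein_b)
        if a == b:
            raise FormatError(f"{path}, line {line}: self-interaction {a}")
        key = (a, b) if a <= b else (b, a)
        base[key] = max(base.get(key, 0.0), s)
        if exp_scores is not None and not pd.isna(exp_scores[i]):
            e = float(exp_scores[i])
            if not 0.0 <= e <= 1.0:
                raise FormatError(f"{path}, line {line}: experimental score {e} outside [0, 1]")
            base_exp[key] = max(base_exp.get(key, 0.0), e)

    injected: set[tuple[GeneId, GeneId]] = set()
    if experimental_injections is not None:
        inj = _read_table(experimental_injections,
                          ["protein_a", "species_a", "protein_b", "species_b"])
        for i, row in enumerate(inj.itertuples(index=False)):
            line = i + 2
            _check_species(row.species_a, species_registry, line, experimental_injections)
            _check_species(row.species_b, species_registry, line, experimental_injections)
            if row.species_a != row.species_b:
                raise FormatError(
                    f"{experimental_injections}, line {line}: cross-species pair"
                )
            a = GeneId(row.species_a, row.protein_a)
            b = GeneId(row.species_b, row.protein_b)
            injected.add((a, b) if a <= b else (b, a))

    net = InteractionNetwork()
    n_dropped = 0
    for key in sorted(set(base) | injected):
        a, b = key
        if key in base and key in injected:
            s = 1.0 - (1.0 - base[key]) * (1.0 - injection_score)
            exp = max(base_exp.get(key, 0.0), injection_score)
            tag = "combined"
        elif key in base:
            s, exp, tag = base[key], base_exp.get(key), "string_like"
        else:
            s, exp, tag = injection_score, injection_score, "experimental_injected"
        if s < min_combined:
            n_dropped += 1
            continue
        net.add(PpiEdge(a, b, s, experimental_only_score=exp, source_tag=tag))
    logger.info(
        "ppi: rows_read=%d pairs=%d injected=%d kept=%d dropped=%d",
        n_read, len(base), len(injected), net.n_edges, n_dropped,
    )
    return net


def load_phenotype_similarity(path, min_similarity: float = 0.5) -> PhenotypeSimilarityTable:
    """Load cross-species phenotype similarities, keeping sim >= threshold."""
    df = _read_table(path, ["term_a", "species_a", "term_b", "species_b", "similarity"])
    sims = _numeric_column(df, "similarity", path)
    table = PhenotypeSimilarityTable()
    n_read = n_kept = 0
    for i, row in enumerate(df.itertuples(index=False)):
        n_read += 1
        s = float(sims[i])
        if not 0.0 <= s <= 1.0:
            raise FormatError(f"{path}, line {i + 2}: similarity {s} outside [0, 1]")
        if s < min_similarity:
            continue
        table.add(PhenotypeId(row.species_a, row.term_a),
                  PhenotypeId(row.species_b, row.term_b), s)
        n_kept += 1
    logger.info("phenet: rows_read=%d kept=%d dropped=%d", n_read, n_kept, n_read - n_kept)
    return table


def load_associations(path, species_registry: Sequence[str] = DEFAULT_SPECIES) -> AssociationTable:
    """Load known gene-phenotype associations (deduplicated)."""
    df = _read_table(path, ["gene", "species", "phenotype"])
    table = AssociationTable()
    for i, row in enumerate(df.itertuples(index=False)):
        _check_species(row.species, species_registry, i + 2, path)
        table.add(GeneId(row.species, row.gene), PhenotypeId(row.species, row.phenotype))
    logger.info("assoc: rows_read=%d kept=%d", len(df), len(table))
    return table


def load_domain_profiles(
    path, species_registry: Sequence[str] = DEFAULT_SPECIES
) -> dict[GeneId, DomainProfile]:
    """Load PfamScan-style domain hits into per-protein count vectors."""
    df = _read_table(path, ["protein", "species", "domain"])
    counts: dict[GeneId, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for i, row in enumerate(df.itertuples(index=False)):
        _check_species(row.species, species_registry, i + 2, path)
        if not row.domain:
            raise FormatError(f"{path}, line {i + 2}: empty domain accession")
        counts[GeneId(row.species, row.protein)][row.domain] += 1
    profiles = {
        g: DomainProfile(g, dict(sorted(c.items()))) for g, c in sorted(counts.items())
    }
    logger.info("domains: rows_read=%d proteins=%d", len(df), len(profiles))
    return profiles


def load_orthology(
    path,
    domain_profiles: Mapping[GeneId, DomainProfile],
    species_registry: Sequence[str] = DEFAULT_SPECIES,
) -> OrthologyMap:
    """Load ortholog pairs; each pair's weight is the domain cosine of the
    two proteins' profiles (0 when either protein has no scanned domains)."""
    from .scoring import domain_cosine  # local import to avoid a cycle

    df = _read_table(path, ["gene", "species", "ortholog", "ortholog_species"])
    omap = OrthologyMap()
    empty = DomainProfile(GeneId("x", "_"), {})
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        _check_species(row.species, species_registry, line, path)
        _check_species(row.ortholog_species, species_registry, line, path)
        if row.species == row.ortholog_species:
            raise FormatError(f"{path}, line {line}: same-species ortholog pair")
        g = GeneId(row.species, row.gene)
        o = GeneId(row.ortholog_species, row.ortholog)
        sim = domain_cosine(domain_profiles.get(g, empty), domain_profiles.get(o, empty))
        omap.add(OrthologPair(g, o, sim))
    logger.info("orthology: rows_read=%d pairs=%d", len(df), len(omap))
    return omap


def load_gene_sets(path) -> GeneSetCollection:
    """Load a GMT gene-set collection; empty sets are rejected with a warning."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}, line {lineno}: expected name/description/members")
            name, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                warnings.warn(f"{path}, line {lineno}: gene set {name!r} has no members; skipped")
                continue
            coll.sets[name] = (desc, members)
    logger.info("gene sets: n_sets=%d universe=%d", len(coll), len(coll.universe))
    return coll


def load_obo_names(path, species: str | None = None) -> dict:
    """Extract an id -> name map from an OBO file (obsolete terms skipped).

    With ``species`` given, keys are :class:`PhenotypeId`; otherwise plain
    term-id strings (an ontology file carries no species information).
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    names = {
        term: data["name"] for term, data in graph.nodes(data=True) if "name" in data
    }
    if species is not None:
        return {PhenotypeId(species, t): n for t, n in names.items()}
    return names


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ppi(net: InteractionNetwork, path, extra_rows: Iterable[tuple] = ()) -> None:
    """Write the PPI table. ``extra_rows`` are raw (a, b, score[, exp]) tuples
    appended verbatim (used for deliberately sub-threshold decoy blocks)."""
    rows = []
    for e in net.edges():
        rows.append((e.a.identifier, e.a.species, e.b.identifier, e.b.species,
                     f"{e.combined_score:.6f}",
                     "" if e.experimental_only_score is None
                     else f"{e.experimental_only_score:.6f}"))
    for a, b, s, *rest in extra_rows:
        exp = f"{rest[0]:.6f}" if rest else ""
        rows.append((a.identifier, a.species, b.identifier, b.species, f"{s:.6f}", exp))
    pd.DataFrame(rows, columns=["protein_a", "species_a", "protein_b", "species_b",
                                "combined_score", "experimental_score"]
                 ).to_csv(path, sep="\t", index=False)


def write_phenotype_similarity(
    table: PhenotypeSimilarityTable, path, extra_rows: Iterable[tuple] = ()
) -> None:
    rows = [
        (a.identifier, a.species, b.identifier, b.species, f"{s:.6f}")
        for a, b, s in table.edges()
    ]
    rows += [
        (a.identifier, a.species, b.identifier, b.species, f"{s:.6f}")
        for a, b, s in extra_rows
    ]
    pd.DataFrame(rows, columns=["term_a", "species_a", "term_b", "species_b",
                                "similarity"]).to_csv(path, sep="\t", index=False)


def write_associations(table: AssociationTable, path) -> None:
    rows = [(g.identifier, g.species, p.identifier) for g, p in table.records()]
    pd.DataFrame(rows, columns=["gene", "species", "phenotype"]
                 ).to_csv(path, sep="\t", index=False)


def write_domain_profiles(profiles: Mapping[GeneId, DomainProfile], path) -> None:
    rows = []
    for g in sorted(profiles):
        for dom, c in sorted(profiles[g].counts.items()):
            rows.extend([(g.identifier, g.species, dom)] * c)
    pd.DataFrame(rows, columns=["protein", "species", "domain"]
                 ).to_csv(path, sep="\t", index=False)


def write_orthology(omap: OrthologyMap, path) -> None:
    rows = [
        (p.gene.identifier, p.gene.species, p.ortholog.identifier, p.ortholog.species)
        for p in omap.pairs()
    ]
    pd.DataFrame(rows, columns=["gene", "species", "ortholog", "ortholog_species"]
                 ).to_csv(path, sep="\t", index=False)


def write_ranked(candidates, path) -> None:
    """Write scored candidates as the ranked-inference TSV."""
    rows = []
    for c in candidates:
        evidence = ";".join(e.token() for e in c.evidence)
        rows.append((
            c.gene.identifier, c.gene.species, c.phenotype.identifier,
            f"{c.final_score:.6f}", f"{c.norm_ppi:.6f}", f"{c.norm_orth:.6f}",
            int(c.is_known), evidence,
        ))
    pd.DataFrame(rows, columns=["gene", "species", "phenotype", "score",
                                "ppi_component", "orthology_component",
                                "is_known", "evidence"]
                 ).to_csv(path, sep="\t", index=False)


def read_ranked_genes(path, species_registry: Sequence[str] = DEFAULT_SPECIES) -> list[GeneId]:
    """Read the gene column of a ranked-inference TSV, preserving order and
    dropping repeats (a gene may appear once per phenotype)."""
    df = _read_table(path, ["gene", "species"])
    seen: set[GeneId] = set()
    out: list[GeneId] = []
    for i, row in enumerate(df.itertuples(index=False)):
        _check_species(row.species, species_registry, i + 2, path)
        g = GeneId(row.species, row.gene)
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# world directories
# ---------------------------------------------------------------------------

WORLD_FILES = {
    "ppi": "ppi.tsv",
    "orthology": "orthology.tsv",
    "domains": "domains.tsv",
    "associations": "associations.tsv",
    "phenet": "phenotype_similarity.tsv",
}


def load_world(
    directory,
    min_combined: float = 0.5,
    min_similarity: float = 0.5,
    injection_score: float = 0.9,
    species_registry: Sequence[str] | None = None,
) -> World:
    """Load a directory of world tables (the layout ``write_world`` emits)."""
    directory = Path(directory)
    if species_registry is None:
        manifest = directory / "manifest.json"
        if manifest.exists():
            with open(manifest) as fh:
                species_registry = tuple(json.load(fh).get("species", DEFAULT_SPECIES))
        else:
            species_registry = DEFAULT_SPECIES
    domains = load_domain_profiles(directory / WORLD_FILES["domains"], species_registry)
    injections = directory / "experimental_injections.tsv"
    return World(
        net=load_ppi(directory / WORLD_FILES["ppi"], min_combined,
                     experimental_injections=injections if injections.exists() else None,
                     injection_score=injection_score, species_registry=species_registry),
        orth=load_orthology(directory / WORLD_FILES["orthology"], domains, species_registry),
        domains=domains,
        assoc=load_associations(directory / WORLD_FILES["associations"], species_registry),
        phenet=load_phenotype_similarity(directory / WORLD_FILES["phenet"], min_similarity),
    )
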