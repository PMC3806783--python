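"""Self-contained synthetic multi-species worlds with planted truth.

The generator emulates the two statistical regularities the inference
method exploits: genes causing similar phenotypes tend to interact
(phenotype *modules* wired densely in the PPI network), and orthologs tend
to keep both their domain composition and their phenotype spectrum across
species (matched phenotype modules connected in the cross-species
similarity table). Part of the planted gene-phenotype truth is held out of
the visible association table so downstream evaluation can measure
recovery of associations the scorer has never seen.

Every quantity is driven by a single integer seed; identical configs
produce byte-identical worlds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import iodata
from .iodata import (
    AssociationTable,
    DEFAULT_SPECIES,
    DomainProfile,
    GeneId,
    InteractionNetwork,
    OrthologPair,
    OrthologyMap,
    PhenotypeId,
    PhenotypeSimilarityTable,
    PpiEdge,
    World,
)
from .scoring import domain_cosine, raw_orthology_score, raw_ppi_score

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "verify_world",
    "preset_config",
    "PRESETS",
]

# ontology-flavored term prefixes per species code
_TERM_PREFIX = {
    "fly": "FBcv", "human": "HP", "mouse": "MP",
    "worm": "WBPheno", "yeast": "APO", "zebrafish": "ZP",
}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    ``ppi_signal`` is the wiring probability of two genes sharing a
    phenotype module; ``ppi_noise`` the background wiring probability.
    ``phenet_signal`` is the probability that matched cross-species
    phenotypes get a similarity edge (drawn >= 0.5). A world is
    informative only when ppi_signal > ppi_noise or phenet_signal > 0.
    """

    seed: int = 0
    n_species: int = 3
    genes_per_species: int = 60
    phenotypes_per_species: int = 30
    n_domains: int = 40
    mean_domains_per_gene: float = 3.0
    mean_module_size: float = 6.0
    ppi_signal: float = 0.6
    ppi_noise: float = 0.02
    ortholog_fraction: float = 0.5
    ortholog_domain_retention: float = 0.8
    phenet_signal: float = 0.7
    holdout_fraction: float = 0.3
    score_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        for name in ("ppi_signal", "ppi_noise", "ortholog_fraction",
                     "ortholog_domain_retention", "phenet_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.score_jitter_sd < 0:
            raise ValueError("score_jitter_sd must be >= 0")

    @property
    def species(self) -> tuple[str, ...]:
        named = DEFAULT_SPECIES[: self.n_species]
        extra = tuple(f"sp{i + 1}" for i in range(len(named), self.n_species))
        return named + extra


@dataclass
class SyntheticWorld:
    """A generated world plus its planted ground truth and held-out split."""

    world: World
    truth: AssociationTable          # visible ∪ held-out
    heldout: AssociationTable
    config: WorldConfig
    all_phenotypes: dict[str, list[PhenotypeId]]
    decoy_ppi: list = field(default_factory=list)     # sub-threshold rows, written only
    decoy_phenet: list = field(default_factory=list)

    @property
    def visible(self) -> AssociationTable:
        return self.world.assoc


def preset_config(name: str, seed: int = 0) -> WorldConfig:
    """Named study conditions: default, ppi-only, orth-only, null."""
    try:
        return replace(PRESETS[name], seed=seed)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def _gene(species: str, i: int) -> GeneId:
    return GeneId(species, f"g{i:03d}")


def _phenotype(species: str, j: int) -> PhenotypeId:
    prefix = _TERM_PREFIX.get(species, "XP")
    return PhenotypeId(species, f"{prefix}:{j:07d}")


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a complete synthetic world from a config (see module docs).

    Raises ``ValueError`` with a diagnosis when the held-out split cannot
    satisfy the inferability invariant (every held-out association keeps at
    least one live PPI or orthology path).
    """
    rng = np.random.default_rng(config.seed)
    species = config.species
    G, P = config.genes_per_species, config.phenotypes_per_species
    informative_ppi = config.ppi_signal > config.ppi_noise

    # --- 1. domain profiles -------------------------------------------------
    # Each gene index owns a base profile; each species keeps each base
    # domain with probability ortholog_domain_retention, so ortholog cosines
    # concentrate near that retention level. Domain popularity is Zipf-like.
    dom_weights = 1.0 / np.arange(1, config.n_domains + 1)
    dom_weights /= dom_weights.sum()
    base_profiles: list[dict[str, int]] = []
    for i in range(G):
        k = min(config.n_domains, max(1, int(rng.poisson(config.mean_domains_per_gene))))
        doms = rng.choice(config.n_domains, size=k, replace=False, p=dom_weights)
        base_profiles.append({
            f"PF{int(d):05d}": 1 + int(rng.poisson(0.3)) for d in sorted(doms)
        })
    domains: dict[GeneId, DomainProfile] = {}
    for sp in species:
        for i in range(G):
            kept = {d: c for d, c in base_profiles[i].items()
                    if rng.random() < config.ortholog_domain_retention}
            g = _gene(sp, i)
            if kept:
                domains[g] = DomainProfile(g, kept)

    # --- 2. phenotype modules / planted truth --------------------------------
    # Module gene indices are shared across species so orthology aligns with
    # matched phenotypes; genes may sit in several modules (multi-functionality).
    modules: list[np.ndarray] = []
    for j in range(P):
        m = min(G, max(2, int(rng.poisson(config.mean_module_size))))
        modules.append(np.sort(rng.choice(G, size=m, replace=False)))
    truth = AssociationTable()
    for sp in species:
        for j, members in enumerate(modules):
            for i in members:
                truth.add(_gene(sp, int(i)), _phenotype(sp, j))

    member_sets = [set(int(i) for i in m) for m in modules]
    co_module = set()
    for mem in member_sets:
        s = sorted(mem)
        for x in range(len(s)):
            for y in range(x + 1, len(s)):
                co_module.add((s[x], s[y]))

    # --- 3. PPI wiring --------------------------------------------------------
    net = InteractionNetwork()
    for sp in species:
        for i in range(G):
            for j in range(i + 1, G):
                is_signal = (i, j) in co_module
                p = config.ppi_signal if is_signal else config.ppi_noise
                if rng.random() >= p:
                    continue
                if is_signal and informative_ppi:
                    s = 0.5 + 0.5 * rng.beta(4.0, 1.5)  # biased high
                else:
                    s = 0.5 + 0.5 * rng.random()
                s += rng.normal(0.0, config.score_jitter_sd)
                # scores carry 6 decimals so worlds are exactly file-representable
                s = round(float(np.clip(s, 0.5, 1.0)), 6)
                net.add(PpiEdge(_gene(sp, i), _gene(sp, j), s))

    # sub-threshold decoy rows: written to disk, must die at load time
    n_decoy = max(3, round(0.05 * net.n_edges))
    decoy_ppi = []
    attempts = 0
    while len(decoy_ppi) < n_decoy and attempts < 50 * n_decoy:
        attempts += 1
        sp = species[int(rng.integers(len(species)))]
        i, j = rng.choice(G, size=2, replace=False)
        a, b = _gene(sp, int(i)), _gene(sp, int(j))
        if net.edge(a, b) is None:
            decoy_ppi.append((a, b, float(0.05 + 0.44 * rng.random())))

    # --- 4. orthology ---------------------------------------------------------
    orth = OrthologyMap()
    empty = DomainProfile(GeneId("x", "_"), {})
    for si in range(len(species)):
        for sj in range(si + 1, len(species)):
            for i in range(G):
                if rng.random() >= config.ortholog_fraction:
                    continue
                a, b = _gene(species[si], i), _gene(species[sj], i)
                sim = domain_cosine(domains.get(a, empty), domains.get(b, empty))
                orth.add(OrthologPair(a, b, sim))

    # --- 5. cross-species phenotype similarity --------------------------------
    phenet = PhenotypeSimilarityTable()
    for si in range(len(species)):
        for sj in range(si + 1, len(species)):
            for j in range(P):
                if rng.random() < config.phenet_signal:
                    phenet.add(_phenotype(species[si], j), _phenotype(species[sj], j),
                               round(float(0.5 + 0.5 * rng.random()), 6))
    n_decoy_ph = max(3, round(0.1 * max(1, len(phenet))))
    decoy_phenet = []
    attempts = 0
    while len(decoy_phenet) < n_decoy_ph and attempts < 50 * n_decoy_ph:
        attempts += 1
        si, sj = rng.choice(len(species), size=2, replace=False)
        ja, jb = int(rng.integers(P)), int(rng.integers(P))
        a, b = _phenotype(species[int(si)], ja), _phenotype(species[int(sj)], jb)
        if phenet.similarity(a, b) == 0.0:
            decoy_phenet.append((a, b, float(0.49 * rng.random())))

    # --- 6. visible / held-out split ------------------------------------------
    heldout_tentative = []
    visible = AssociationTable()
    for g, ph in truth.records():
        if rng.random() < config.holdout_fraction:
            heldout_tentative.append((g, ph))
        else:
            visible.add(g, ph)

    # repair pass: a held-out pair with no live path goes back to visible.
    # Moving a pair back only adds associations, which can only create new
    # paths for the remaining held-out pairs, so one ordered pass suffices.
    heldout = AssociationTable()
    for g, ph in heldout_tentative:
        ppi, _ = raw_ppi_score(g, ph, net, visible)
        orth_score, _ = raw_orthology_score(g, ph, orth, visible, phenet)
        if ppi > 0 or orth_score > 0:
            heldout.add(g, ph)
        else:
            visible.add(g, ph)

    if len(truth) and not len(heldout):
        raise ValueError(
            "inferability invariant unsatisfiable: no held-out association "
            "retains a PPI or orthology path; the world is too sparse "
            "(raise ppi_signal/ppi_noise, ortholog_fraction or phenet_signal, "
            "or enlarge the world)"
        )

    all_phenotypes = {sp: [_phenotype(sp, j) for j in range(P)] for sp in species}
    world = World(net=net, orth=orth, domains=domains, assoc=visible, phenet=phenet)
    return SyntheticWorld(
        world=world, truth=truth, heldout=heldout, config=config,
        all_phenotypes=all_phenotypes,
        decoy_ppi=decoy_ppi, decoy_phenet=decoy_phenet,
    )


PRESETS: dict[str, WorldConfig] = {
    "default": WorldConfig(),
    # no orthology data at all: lambda recovery must land on 1.0
    "ppi-only": WorldConfig(ortholog_fraction=0.0),
    # PPI wiring purely random; orthology channel strengthened
    "orth-only": WorldConfig(ppi_signal=0.02, ppi_noise=0.02,
                             ortholog_fraction=0.8, phenet_signal=0.8),
    # no signal anywhere: uniform PPI wiring at the default world's expected
    # edge density (density-matched null) and no cross-species similarity
    "null": WorldConfig(ppi_signal=0.165, ppi_noise=0.165, phenet_signal=0.0),
}


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_world(sworld: SyntheticWorld, directory) -> dict:
    """Write every table in the dialects the loaders read, plus a manifest.

    The visible association table never contains a held-out pair; the
    held-out truth goes to its own file. Decoy PPI/similarity rows (scores
    below the load-time thresholds) are appended to the written tables so a
    round-trip exercises the filters. Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    w = sworld.world
    iodata.write_ppi(w.net, directory / iodata.WORLD_FILES["ppi"],
                     extra_rows=sworld.decoy_ppi)
    iodata.write_orthology(w.orth, directory / iodata.WORLD_FILES["orthology"])
    iodata.write_domain_profiles(w.domains, directory / iodata.WORLD_FILES["domains"])
    iodata.write_associations(w.assoc, directory / iodata.WORLD_FILES["associations"])
    iodata.write_phenotype_similarity(w.phenet, directory / iodata.WORLD_FILES["phenet"],
                                      extra_rows=sworld.decoy_phenet)
    iodata.write_associations(sworld.heldout, directory / "heldout_associations.tsv")

    files = sorted(list(iodata.WORLD_FILES.values()) + ["heldout_associations.tsv"])
    manifest = {
        "config": dataclasses.asdict(sworld.config),
        "species": list(sworld.config.species),
        "n_visible": len(w.assoc),
        "n_heldout": len(sworld.heldout),
        "n_truth": len(sworld.truth),
        "checksums": {f: _sha256(directory / f) for f in files},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def verify_world(directory) -> dict:
    """Check the manifest's checksums; raises ValueError on tampering."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, expected in manifest["checksums"].items():
        actual = _sha256(directory / name)
        if actual != expected:
            raise ValueError(f"checksum mismatch for {name}: "
                             f"expected {expected[:12]}..., got {actual[:12]}...")
    return manifest


def load_heldout(directory) -> AssociationTable:
    """Read back the held-out truth written by :func:`write_world`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        registry = tuple(json.load(fh)["species"])
    return iodata.load_associations(directory / "heldout_associations.tsv", registry)
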