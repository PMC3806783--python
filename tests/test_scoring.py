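import math

import pytest
from hypothesis import given, strategies as st

from phenolink.iodata import (
    AssociationTable,
    DomainProfile,
    GeneId,
    InteractionNetwork,
    PhenotypeId,
    PpiEdge,
)
from phenolink.scoring import (
    ScoredCandidate,
    ScoringConfig,
    combine,
    domain_cosine,
    raw_orthology_score,
    raw_ppi_score,
    score_gene,
    score_gene_in_world,
    score_phenotype,
)
from phenolink.synthdata import WorldConfig, generate_world

from .oracles import brute_score_gene, cosine_oracle

P = GeneId("human", "p")


def _profile(counts):
    return DomainProfile(P, counts)


profiles = st.dictionaries(
    st.sampled_from([f"PF{i}" for i in range(8)]),
    st.integers(min_value=1, max_value=9),
    max_size=6,
)


class TestDomainCosine:
    def test_identical_profiles_score_one(self):
        a = _profile({"PF1": 2, "PF2": 5})
        assert domain_cosine(a, a) == pytest.approx(1.0)

    def test_disjoint_profiles_score_zero(self):
        assert domain_cosine(_profile({"PF1": 1}), _profile({"PF2": 3})) == 0.0

    def test_hand_computed_value(self):
        a = _profile({"PF1": 1, "PF2": 1})
        b = _profile({"PF1": 1})
        assert domain_cosine(a, b) == pytest.approx(1.0 / math.sqrt(2.0))

    def test_empty_profile_scores_zero(self):
        assert domain_cosine(_profile({}), _profile({"PF1": 1})) == 0.0

    def test_positive_scalar_multiple_scores_one(self):
        a = _profile({"PF1": 2, "PF2": 4})
        b = _profile({"PF1": 3, "PF2": 6})
        assert domain_cosine(a, b) == pytest.approx(1.0)

    @given(a=profiles, b=profiles)
    def test_matches_oracle_symmetric_and_bounded(self, a, b):
        pa, pb = _profile(a), _profile(b)
        got = domain_cosine(pa, pb)
        assert got == pytest.approx(cosine_oracle(a, b), abs=1e-12)
        assert got == pytest.approx(domain_cosine(pb, pa), abs=1e-15)
        assert 0.0 <= got <= 1.0


class TestRawPpiScore:
    def test_sums_scores_of_associated_partners(self, toy_world):
        ids = toy_world.ids
        score, evidence = raw_ppi_score(ids["g1"], ids["ph_a"],
                                        toy_world.net, toy_world.assoc)
        assert score == pytest.approx(1.5)
        assert len(evidence) == 2
        assert {e.via for e in evidence} == {ids["p1"], ids["p2"]}

    def test_no_associated_partner_scores_zero(self, toy_world):
        ids = toy_world.ids
        ph = PhenotypeId("human", "HP:none")
        score, evidence = raw_ppi_score(ids["g1"], ph, toy_world.net, toy_world.assoc)
        assert score == 0.0 and evidence == []

    def test_self_association_is_not_a_path(self, toy_world):
        ids = toy_world.ids
        assoc = AssociationTable(toy_world.assoc.records())
        ph = PhenotypeId("human", "HP:self")
        assoc.add(ids["g1"], ph)
        score, _ = raw_ppi_score(ids["g1"], ph, toy_world.net, assoc)
        assert score == 0.0

    def test_experimental_only_restricts_to_experimental_channel(self):
        g, a, b = (GeneId("human", x) for x in ("g", "a", "b"))
        ph = PhenotypeId("human", "HP:1")
        net = InteractionNetwork([
            PpiEdge(g, a, 0.9, experimental_only_score=0.7),
            PpiEdge(g, b, 0.9),  # no experimental evidence
        ])
        assoc = AssociationTable([(a, ph), (b, ph)])
        cfg = ScoringConfig(experimental_ppi_only=True)
        score, evidence = raw_ppi_score(g, ph, net, assoc, cfg)
        assert score == pytest.approx(0.7)
        assert [e.via for e in evidence] == [a]


class TestRawOrthologyScore:
    def test_single_ortholog_product(self, toy_world):
        ids = toy_world.ids
        score, evidence = raw_orthology_score(
            ids["g1"], ids["ph_a"], toy_world.orth, toy_world.assoc, toy_world.phenet
        )
        assert score == pytest.approx(0.8 / math.sqrt(2.0))
        (ev,) = evidence
        assert ev.via == ids["o1"]
        assert ev.phenotype_link == (ids["ph_x"], 0.8)

    def test_spec_magnitude_example(self):
        g = GeneId("human", "g")
        o = GeneId("mouse", "o")
        ph = PhenotypeId("human", "HP:1")
        ph_o = PhenotypeId("mouse", "MP:1")
        from phenolink.iodata import OrthologPair, OrthologyMap, PhenotypeSimilarityTable
        orth = OrthologyMap([OrthologPair(g, o, 0.97)])
        assoc = AssociationTable([(o, ph_o)])
        phenet = PhenotypeSimilarityTable()
        phenet.add(ph_o, ph, 0.8)
        score, _ = raw_orthology_score(g, ph, orth, assoc, phenet)
        assert score == pytest.approx(0.776)

    def test_unlinked_phenotype_contributes_nothing(self, toy_world):
        ids = toy_world.ids
        score, evidence = raw_orthology_score(
            ids["g1"], ids["ph_b"], toy_world.orth, toy_world.assoc, toy_world.phenet
        )
        assert score == 0.0 and evidence == []

    def test_two_orthologs_sum(self):
        from phenolink.iodata import OrthologPair, OrthologyMap, PhenotypeSimilarityTable
        g = GeneId("human", "g")
        o1, o2 = GeneId("mouse", "o1"), GeneId("fly", "o2")
        ph = PhenotypeId("human", "HP:1")
        m1, m2 = PhenotypeId("mouse", "MP:1"), PhenotypeId("fly", "FBcv:1")
        orth = OrthologyMap([OrthologPair(g, o1, 0.5), OrthologPair(g, o2, 0.4)])
        assoc = AssociationTable([(o1, m1), (o2, m2)])
        phenet = PhenotypeSimilarityTable()
        phenet.add(m1, ph, 0.6)   # 0.5 * 0.6 = 0.3
        phenet.add(m2, ph, 0.5)   # 0.4 * 0.5 = 0.2
        score, evidence = raw_orthology_score(g, ph, orth, assoc, phenet)
        assert score == pytest.approx(0.5)
        assert len(evidence) == 2


class TestScoreGene:
    def test_combination_and_final_normalization(self):
        g = GeneId("human", "g")
        c1 = ScoredCandidate(g, PhenotypeId("human", "HP:1"), 1.0, 0.5,
                             norm_ppi=1.0, norm_orth=0.5)
        c2 = ScoredCandidate(g, PhenotypeId("human", "HP:2"), 0.2, 1.0,
                             norm_ppi=0.2, norm_orth=1.0)
        out = combine([c1, c2], ScoringConfig(lambda_weight=0.8))
        assert out[0].combined_raw == pytest.approx(0.9)
        assert out[1].combined_raw == pytest.approx(0.36)
        assert out[0].final_score == pytest.approx(1.0)
        assert out[1].final_score == pytest.approx(0.4)

    def test_max_final_score_is_one(self, default_world):
        cfg = ScoringConfig(lambda_weight=0.8)
        found = 0
        for g in default_world.visible.genes()[:20]:
            cands = score_gene_in_world(g, cfg, default_world.world)
            if cands:
                found += 1
                assert max(c.final_score for c in cands) == pytest.approx(1.0)
                assert all(0.0 <= c.final_score <= 1.0 + 1e-12 for c in cands)
        assert found > 0

    @pytest.mark.parametrize("lam,component", [(1.0, "raw_ppi"), (0.0, "raw_orth")])
    def test_degenerate_weight_matches_single_path_ranking(self, default_world, lam, component):
        cfg = ScoringConfig(lambda_weight=lam)
        for g in default_world.visible.genes()[:10]:
            cands = score_gene_in_world(g, cfg, default_world.world)
            for hi, lo in zip(cands, cands[1:]):
                assert getattr(hi, component) >= getattr(lo, component) - 1e-12

    def test_monotone_in_added_interactor(self, toy_world):
        ids = toy_world.ids
        base, _ = raw_ppi_score(ids["g1"], ids["ph_a"], toy_world.net, toy_world.assoc)
        p3 = GeneId("human", "p3")
        net = InteractionNetwork([e for e in toy_world.net.edges()] + [PpiEdge(ids["g1"], p3, 0.55)])
        assoc = AssociationTable(toy_world.assoc.records() + [(p3, ids["ph_a"])])
        more, _ = raw_ppi_score(ids["g1"], ids["ph_a"], net, assoc)
        assert more >= base

    def test_known_phenotypes_flagged_and_retained(self, toy_world):
        ids = toy_world.ids
        assoc = AssociationTable(toy_world.assoc.records() + [(ids["g1"], ids["ph_a"])])
        cands = score_gene(ids["g1"], ScoringConfig(), toy_world.net,
                           toy_world.orth, assoc, toy_world.phenet)
        by_ph = {c.phenotype: c for c in cands}
        assert by_ph[ids["ph_a"]].is_known
        assert not by_ph[ids["ph_b"]].is_known

    def test_gene_without_paths_yields_empty_list(self, toy_world):
        lonely = GeneId("human", "nobody")
        assert score_gene(lonely, ScoringConfig(), toy_world.net,
                          toy_world.orth, toy_world.assoc, toy_world.phenet) == []

    def test_sum_final_normalization_is_ranking_equivalent(self, toy_world):
        ids = toy_world.ids
        a = score_gene(ids["g1"], ScoringConfig(final_normalization="max"),
                       toy_world.net, toy_world.orth, toy_world.assoc, toy_world.phenet)
        b = score_gene(ids["g1"], ScoringConfig(final_normalization="sum"),
                       toy_world.net, toy_world.orth, toy_world.assoc, toy_world.phenet)
        assert [c.phenotype for c in a] == [c.phenotype for c in b]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        cfg = WorldConfig(seed=seed, n_species=2, genes_per_species=10,
                          phenotypes_per_species=8, n_domains=12,
                          mean_module_size=3.0)
        sw = generate_world(cfg)
        scfg = ScoringConfig(lambda_weight=0.7)
        for g in sw.world.gene_universe():
            expected = brute_score_gene(g, 0.7, sw.world)
            got = {c.phenotype: c for c in score_gene_in_world(g, scfg, sw.world)}
            assert set(got) == set(expected)
            for ph, (rp, ro, final) in expected.items():
                assert got[ph].raw_ppi == pytest.approx(rp, abs=1e-12)
                assert got[ph].raw_orth == pytest.approx(ro, abs=1e-12)
                assert got[ph].final_score == pytest.approx(final, abs=1e-12)


class TestScorePhenotype:
    def test_agrees_with_score_gene_everywhere(self, small_world):
        cfg = ScoringConfig(lambda_weight=0.6)
        w = small_world.world
        species = small_world.config.species[0]
        for ph in w.phenome(species)[:6]:
            ranked = dict(score_phenotype(ph, cfg, w.net, w.orth, w.assoc, w.phenet))
            for g in w.gene_universe(species):
                expected = {c.phenotype: c.final_score
                            for c in score_gene_in_world(g, cfg, w)}
                if ph in expected:
                    assert ranked[g] == pytest.approx(expected[ph])
                else:
                    assert g not in ranked

    def test_unreachable_phenotype_gives_empty_list(self, toy_world):
        ph = PhenotypeId("human", "HP:unseen")
        assert score_phenotype(ph, ScoringConfig(), toy_world.net,
                               toy_world.orth, toy_world.assoc, toy_world.phenet) == []

    def test_ranking_descends(self, small_world):
        w = small_world.world
        cfg = ScoringConfig()
        for ph in w.phenome(small_world.config.species[0])[:4]:
            ranked = score_phenotype(ph, cfg, w.net, w.orth, w.assoc, w.phenet)
            scores = [s for _, s in ranked]
            assert scores == sorted(scores, reverse=True)


def test_lambda_out_of_range_rejected():
    with pytest.raises(ValueError):
        ScoringConfig(lambda_weight=1.5)
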