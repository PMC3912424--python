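"""Cross-species semantic similarity: IC, term similarity, model and gene scores.

Hand-computed expectations on a six-term two-species DAG, plus randomized
equivalence against the brute-force oracle in phenomatch_oracle.
"""

import math

import pytest
from phenomatch_oracle import (
    brute_ic,
    brute_model_score,
    brute_similarity,
    merged_adjacency,
    random_world,
)

from phive.phenomatch import (
    DiseaseProfile,
    ModelCorpus,
    PhenotypeGraph,
    gene_relevance,
)

LN2 = math.log(2)
LN4 = math.log(4)


@pytest.fixture()
def tiny_graph(tiny_ontologies):
    hpo, mpo, bridges = tiny_ontologies
    graph = PhenotypeGraph(hpo, mpo, bridges)
    corpus = ModelCorpus.from_tables(
        model_terms={
            "M1": frozenset({"m1"}),
            "M2": frozenset({"m11"}),
            "M3": frozenset({"m2"}),
            "M4": frozenset({"m2"}),
        },
        model_gene={"M1": "Ga_m", "M2": "Gb_m", "M3": "Gc_m", "M4": "Gc_m"},
        ortholog_pairs=[("Ga_m", "GA"), ("Gb_m", "GB"), ("Gc_m", "GC")],
    )
    graph.compute_ic(corpus)
    return graph, corpus


class TestInformationContent:
    def test_term_in_one_of_four_models(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.ic["m11"] == pytest.approx(LN4)  # -ln(1/4) ~ 1.386

    def test_root_subsuming_all_models_has_zero_ic(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.ic["mroot"] == 0.0
        assert graph.ic["PHENO:ROOT"] == 0.0

    def test_identical_annotation_closure_identical_ic(self, tiny_graph):
        # h1 and m1 are bridged equivalents: same closure, same count
        graph, _ = tiny_graph
        assert graph.ic["h1"] == graph.ic["m1"] == pytest.approx(LN2)

    def test_unobserved_terms_get_max_observed_ic(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.ic["h2"] == pytest.approx(LN4)

    def test_empty_corpus_fatal(self, tiny_ontologies):
        hpo, mpo, bridges = tiny_ontologies
        with pytest.raises(ValueError):
            ModelCorpus(model_terms={}, model_gene={})


class TestTermSimilarity:
    def test_self_similarity_is_sqrt_ic(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.term_similarity("m11", "m11") == pytest.approx(math.sqrt(LN4))

    def test_only_root_in_common_scores_zero(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.term_similarity("m1", "m2") == 0.0

    def test_bridged_terms_score_like_self_comparison(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.term_similarity("h1", "m1") == pytest.approx(
            graph.term_similarity("h1", "h1")
        )

    def test_unknown_term_fatal(self, tiny_graph):
        graph, _ = tiny_graph
        with pytest.raises(KeyError):
            graph.term_similarity("h1", "nope")


class TestModelScore:
    def test_exact_bridged_model_scores_one(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.model_score({"h1"}, {"m1"}) == pytest.approx(1.0)

    def test_unrelated_model_scores_zero(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.model_score({"h2"}, {"m2"}) == 0.0

    def test_hand_computed_partial_match(self, tiny_graph):
        """disease {h1, h2} vs model {m1}: full best-match table by hand.

        sim(h1,m1) = sqrt(ln2)           (bridged equivalents)
        sim(h2,m1) = sqrt((2/6) * ln2)   (share {hroot, ROOT}; IC(hroot)=ln2)
        raw  = (mean[s11, s21, s11] + s11) / 2
        norm = (mean[sqrt(ln2), sqrt(ln4)] * over both directions + sqrt(ln4)) / 2
        """
        graph, _ = tiny_graph
        s11 = math.sqrt(LN2)
        s21 = math.sqrt(2 / 6 * LN2)
        raw = ((s11 + s21 + s11) / 3 + s11) / 2
        self_best = [math.sqrt(LN2), math.sqrt(LN4)] * 2
        norm = (sum(self_best) / 4 + math.sqrt(LN4)) / 2
        expected = min(1.0, raw / norm)
        assert graph.model_score({"h1", "h2"}, {"m1"}) == pytest.approx(expected)

    def test_symmetry_and_range(self, tiny_graph):
        graph, _ = tiny_graph
        a = graph.model_score({"h1", "h11"}, {"m1", "m2"})
        assert 0.0 <= a <= 1.0

    def test_empty_sets_score_zero(self, tiny_graph):
        graph, _ = tiny_graph
        assert graph.model_score(set(), {"m1"}) == 0.0
        assert graph.model_score({"h1"}, set()) == 0.0

    def test_removing_a_matched_term_never_raises_the_score(self, tiny_graph):
        graph, _ = tiny_graph
        with_match = graph.model_score({"h1", "h2"}, {"m1", "m2"})
        without = graph.model_score({"h1", "h2"}, {"m2"})
        assert without <= with_match + 1e-12


class TestGeneRelevance:
    def test_best_model_wins_and_default_for_unmodeled(self, tiny_graph):
        graph, corpus = tiny_graph
        disease = DiseaseProfile("D", frozenset({"h1"}))
        rel = gene_relevance(disease, ["GA", "GB", "GC", "GZ"], corpus, graph)
        assert rel["GA"].r == pytest.approx(1.0)  # bridged exact match
        assert rel["GA"].best_model == "M1"
        assert rel["GZ"].r == 0.6  # no phenotyped model -> default
        assert rel["GZ"].best_model is None
        # perfect-match gene ranks strictly first among scored genes
        assert rel["GA"].r > max(rel["GB"].r, rel["GC"].r)

    def test_masked_gene_falls_back_to_default(self, tiny_graph):
        graph, corpus = tiny_graph
        disease = DiseaseProfile("D", frozenset({"h1"}))
        rel = gene_relevance(
            disease, ["GA"], corpus, graph, masked_genes=frozenset({"GA"})
        )
        assert rel["GA"].r == 0.6 and rel["GA"].best_model is None

    def test_default_is_overridable(self, tiny_graph):
        graph, corpus = tiny_graph
        disease = DiseaseProfile("D", frozenset({"h1"}))
        rel = gene_relevance(disease, ["GZ"], corpus, graph, default_r=0.4)
        assert rel["GZ"].r == 0.4


class TestGraphStructure:
    def test_cycle_in_isa_edges_rejected(self, tiny_ontologies):
        import networkx as nx

        hpo, mpo, bridges = tiny_ontologies
        bad = nx.DiGraph(hpo)
        bad.add_edge("hroot", "h11")  # closes a cycle
        with pytest.raises(ValueError, match="cycle"):
            PhenotypeGraph(bad, mpo, bridges)

    def test_unknown_bridge_term_rejected(self, tiny_ontologies):
        hpo, mpo, _ = tiny_ontologies
        with pytest.raises(ValueError, match="bridge"):
            PhenotypeGraph(hpo, mpo, [("h1", "not-a-term")])


@pytest.mark.parametrize("seed", range(12))
def test_matches_brute_force_oracle_on_random_dags(seed):
    """IC, pairwise similarity and model scores vs the BFS/loop oracle."""
    hpo, mpo, bridges, model_terms = random_world(seed)
    graph = PhenotypeGraph(hpo, mpo, bridges)
    genes = {mid: f"g{mid}" for mid in model_terms}
    corpus = ModelCorpus.from_tables(model_terms, genes, [(g, g.upper()) for g in genes.values()])
    graph.compute_ic(corpus)

    adj = merged_adjacency(hpo.edges, mpo.edges, bridges)
    ic = brute_ic(adj, model_terms)
    for t in adj:
        assert graph.ic[t] == pytest.approx(ic[t]), t
    terms = sorted(adj)
    for t1 in terms[::3]:
        for t2 in terms[::4]:
            assert graph.term_similarity(t1, t2) == pytest.approx(
                brute_similarity(adj, ic, t1, t2)
            ), (t1, t2)
    h_terms = sorted(hpo.nodes)
    disease = frozenset(h_terms[: min(3, len(h_terms))])
    for mid in model_terms:
        assert graph.model_score(disease, model_terms[mid]) == pytest.approx(
            brute_model_score(adj, ic, disease, model_terms[mid])
        ), mid
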