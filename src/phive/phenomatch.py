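"""Cross-species phenotype matching: HPO disease profiles vs MPO mouse models.

The two phenotype ontologies are merged into one DAG; a term-bridge table of
precomputed cross-species equivalences (the product of Entity-Quality
logical-definition reasoning, supplied as input) links HPO and MPO terms so
ancestor closures cross species. Term specificity is measured by Resnik
information content over the mouse-model corpus:

    IC(t) = -ln( #models annotated to t or any descendant / #models )

Two terms are compared by sqrt(simJ * IC(MICA)) where simJ is the Jaccard
index of their ancestor sets (including the terms themselves) and MICA is
their common ancestor of maximal IC. A disease-vs-model score averages the
best pairwise matches symmetrically, combines mean and max, and normalizes
by the disease's self-comparison. A gene's phenotypic relevance r is the
best score over all models of its orthologous mouse genes, with a default
of 0.6 when no phenotyped model exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Relevance assigned to genes with no phenotyped mouse model. Calibrated so
#: an unmodeled gene neither sinks (real coverage is partial) nor drowns out
#: genuinely matching models.
DEFAULT_RELEVANCE = 0.6

#: Synthetic global root joining the species roots of the merged graph.
GLOBAL_ROOT = "PHENO:ROOT"


@dataclass(frozen=True)
class DiseaseProfile:
    disease_id: str
    terms: frozenset

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"disease {self.disease_id} has an empty HPO profile")


@dataclass
class ModelCorpus:
    """Mouse models with their MPO annotations and gene/ortholog wiring."""

    model_terms: dict[str, frozenset]  # model id -> MPO term set
    model_gene: dict[str, str]  # model id -> mouse gene
    orthologs: dict[str, set] = field(default_factory=dict)  # mouse -> human genes
    _models_of_human: dict[str, list] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.model_terms:
            raise ValueError("empty model corpus")
        for mid, terms in self.model_terms.items():
            if not terms:
                raise ValueError(f"model {mid} has no MPO terms")
        self._models_of_human = {}
        for mid, mgene in sorted(self.model_gene.items()):
            # one mouse gene may map to several human orthologs: contribute to each
            for hgene in self.orthologs.get(mgene, ()):
                self._models_of_human.setdefault(hgene, []).append(mid)

    @classmethod
    def from_tables(
        cls,
        model_terms: Mapping[str, frozenset],
        model_gene: Mapping[str, str],
        ortholog_pairs: Iterable[tuple[str, str]],
    ) -> "ModelCorpus":
        orthologs: dict[str, set] = {}
        for mouse, human in ortholog_pairs:
            orthologs.setdefault(mouse, set()).add(human)
        return cls(dict(model_terms), dict(model_gene), orthologs)

    def models_for_human_gene(self, gene: str) -> list:
        return list(self._models_of_human.get(gene, []))

    def __len__(self) -> int:
        return len(self.model_terms)


class PhenotypeGraph:
    """Merged human+mouse phenotype DAG with bridges and per-term IC.

    Edges run child -> parent; a term's ancestor set is its upward closure
    (itself included) and crosses bridge edges, which are bidirectional
    equivalences. Both species roots hang off a synthetic global root so
    that cross-species pairs always have a (zero-IC) common ancestor.
    """

    def __init__(
        self,
        human: nx.DiGraph,
        mouse: nx.DiGraph,
        bridges: Iterable[tuple[str, str]] = (),
    ):
        g = nx.DiGraph()
        for onto in (human, mouse):
            g.add_nodes_from(onto.nodes)
            g.add_edges_from(onto.edges)
            roots = [n for n in onto.nodes if onto.out_degree(n) == 0]
            for r in roots:
                g.add_edge(r, GLOBAL_ROOT)
        for a, b in bridges:
            if a not in g or b not in g:
                raise ValueError(f"bridge ({a}, {b}) references unknown term(s)")
            g.add_edge(a, b)
            g.add_edge(b, a)
        isa_only = g.copy()
        isa_only.remove_edges_from([(a, b) for a, b in bridges] + [(b, a) for a, b in bridges])
        if not nx.is_directed_acyclic_graph(isa_only):
            raise ValueError("is-a edges of the merged ontology contain a cycle")
        self.graph = g
        self.ic: dict[str, float] = {}
        self._anc_cache: dict[str, frozenset] = {}
        self._sim_cache: dict[tuple, float] = {}
        self._profile_cache: dict[tuple, float] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> frozenset:
        """Upward closure of a term, itself included, bridges crossed."""
        cached = self._anc_cache.get(term)
        if cached is None:
            if term not in self.graph:
                raise KeyError(f"unknown term {term!r}")
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._anc_cache[term] = cached
        return cached

    # -- information content --------------------------------------------------

    def compute_ic(self, corpus: ModelCorpus) -> None:
        """Resnik IC from the mouse-model corpus.

        A term's annotation count is the number of models annotated to it or
        to any term in whose ancestor closure it appears. Terms subsuming no
        model get the IC of the rarest observed term (bounded, not infinite).
        """
        if len(corpus) == 0:
            raise ValueError("cannot compute IC from an empty corpus")
        n = len(corpus)
        counts: dict[str, int] = {}
        for mid in sorted(corpus.model_terms):
            closure = frozenset().union(*(self.ancestors(t) for t in corpus.model_terms[mid]))
            for t in closure:
                counts[t] = counts.get(t, 0) + 1
        ic = {t: -math.log(c / n) for t, c in counts.items()}
        max_ic = max(ic.values(), default=0.0)
        self.ic = {t: ic.get(t, max_ic) for t in self.graph.nodes}
        self._sim_cache.clear()
        self._profile_cache.clear()

    # -- term and profile similarity ------------------------------------------

    def term_similarity(self, t1: str, t2: str) -> float:
        """sqrt(simJ x IC(MICA)): specificity-weighted ancestor overlap."""
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        cached = self._sim_cache.get(key)
        if cached is not None:
            return cached
        a1, a2 = self.ancestors(t1), self.ancestors(t2)
        common = a1 & a2
        if not common:
            sim = 0.0
        else:
            mica_ic = max(self.ic.get(t, 0.0) for t in common)
            sim_j = len(common) / len(a1 | a2)
            sim = math.sqrt(sim_j * mica_ic)
        self._sim_cache[key] = sim
        return sim

    def _best_match_stat(self, set_a: Sequence[str], set_b: Sequence[str]) -> float:
        """Symmetric (mean + max)/2 over best per-term matches of A vs B."""
        best = [max(self.term_similarity(a, b) for b in set_b) for a in set_a]
        best += [max(self.term_similarity(b, a) for a in set_a) for b in set_b]
        return (sum(best) / len(best) + max(best)) / 2.0

    def model_score(self, disease_terms: Iterable[str], model_terms: Iterable[str]) -> float:
        """Disease-vs-model phenotype similarity, self-normalized to [0, 1]."""
        d = sorted(disease_terms)
        m = sorted(model_terms)
        if not d or not m:
            return 0.0
        key = (frozenset(d), frozenset(m))
        cached = self._profile_cache.get(key)
        if cached is not None:
            return cached
        raw = self._best_match_stat(d, m)
        norm = self._best_match_stat(d, d)
        score = 0.0 if norm <= 0.0 else min(1.0, raw / norm)
        self._profile_cache[key] = score
        return score


@dataclass(frozen=True)
class GeneRelevance:
    gene: str
    r: float
    best_model: str | None


def gene_relevance(
    disease: DiseaseProfile,
    genes: Iterable[str],
    corpus: ModelCorpus,
    graph: PhenotypeGraph,
    default_r: float = DEFAULT_RELEVANCE,
    masked_genes: frozenset = frozenset(),
) -> dict[str, GeneRelevance]:
    """Phenotypic relevance r per candidate gene.

    r(gene) is the best model_score over all mouse models of the gene's
    orthologs; genes with no phenotyped model (or listed in ``masked_genes``,
    which simulates absent phenotype coverage) get ``default_r`` and no best
    model. Ties between models break toward the lexicographically smallest id.
    """
    out: dict[str, GeneRelevance] = {}
    for gene in genes:
        models = [] if gene in masked_genes else corpus.models_for_human_gene(gene)
        if not models:
            out[gene] = GeneRelevance(gene=gene, r=default_r, best_model=None)
            continue
        best_score, best_model = -1.0, None
        for mid in sorted(models):
            s = graph.model_score(disease.terms, corpus.model_terms[mid])
            if s > best_score:
                best_score, best_model = s, mid
        out[gene] = GeneRelevance(gene=gene, r=best_score, best_model=best_model)
    return out
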