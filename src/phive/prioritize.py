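"""Final gene ranking: combine variant score v and phenotypic relevance r.

The per-gene score is g = (v + r) / 2. Ranking is ordinal and fully
deterministic: genes are sorted by the selected score descending, ties are
resolved alphabetically (case-insensitive), and unique ranks 1..N assigned —
mirroring the real-life situation where equally scored candidates must be
worked through one by one anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from . import variant_score as vs
from .annotate import AnnotatedVariant, GeneModelIndex, annotate_variants
from .filters import (
    FilterConfig,
    FilterReport,
    apply_inheritance,
    filter_variants,
    group_by_gene,
)
from .io_formats import (
    FrequencyTable,
    PathogenicityTable,
    RawVariant,
    read_bridges,
    read_disease_annotations,
    read_gene_models,
    read_model_annotations,
    read_obo,
    read_orthologs,
    read_reference,
)
from .phenomatch import (
    DEFAULT_RELEVANCE,
    DiseaseProfile,
    ModelCorpus,
    PhenotypeGraph,
    gene_relevance,
)


class ScoreMode(Enum):
    PHIVE = "PHIVE"
    VARIANT_ONLY = "VARIANT_ONLY"
    PHENOTYPE_ONLY = "PHENOTYPE_ONLY"


@dataclass
class GeneCandidate:
    gene: str
    variants: list[AnnotatedVariant]
    v: float
    r: float
    best_model: str | None = None
    rank: int | None = None

    @property
    def g(self) -> float:
        return phive_score(self.v, self.r)

    def score(self, mode: ScoreMode) -> float:
        if mode is ScoreMode.PHIVE:
            return self.g
        if mode is ScoreMode.VARIANT_ONLY:
            return self.v
        return self.r


def phive_score(v: float, r: float) -> float:
    """g = (v + r) / 2, the mean of variant and phenotype relevance scores."""
    if not (0.0 <= v <= 1.0) or not (0.0 <= r <= 1.0):
        raise ValueError(f"scores must be in [0, 1]: v={v}, r={r}")
    return (v + r) / 2.0


def rank_genes(
    candidates: Sequence[GeneCandidate], mode: ScoreMode = ScoreMode.PHIVE
) -> list[GeneCandidate]:
    """Ordinal ranking: score descending, alphabetical tie-break, ranks 1..N."""
    ordered = sorted(candidates, key=lambda c: (-c.score(mode), c.gene.upper(), c.gene))
    for i, cand in enumerate(ordered, start=1):
        cand.rank = i
    return ordered


# ---------------------------------------------------------------------------
# Resource bundle and end-to-end pipeline
# ---------------------------------------------------------------------------

#: Standard file names inside a data directory (as written by the fixtures
#: generator and expected by the CLI).
DATA_FILES = {
    "reference": "reference.fa",
    "gene_models": "gene_models.tsv",
    "frequency": "frequency.tsv",
    "pathogenicity": "pathogenicity.tsv",
    "hpo": "hp.obo",
    "mpo": "mp.obo",
    "bridges": "bridges.tsv",
    "models": "models.tsv",
    "orthologs": "orthologs.tsv",
    "diseases": "diseases.tsv",
}


@dataclass
class Resources:
    """Everything the pipeline needs besides the exome itself."""

    reference: Mapping[str, str]
    index: GeneModelIndex
    frequency: FrequencyTable
    pathogenicity: PathogenicityTable
    graph: PhenotypeGraph
    corpus: ModelCorpus
    diseases: dict[str, DiseaseProfile]
    class_scores: dict = field(default_factory=lambda: dict(vs.DEFAULT_CLASS_SCORES))

    @classmethod
    def load(cls, data_dir: str | Path) -> "Resources":
        d = Path(data_dir)
        model_terms, model_gene = read_model_annotations(d / DATA_FILES["models"])
        corpus = ModelCorpus.from_tables(
            model_terms, model_gene, read_orthologs(d / DATA_FILES["orthologs"])
        )
        graph = PhenotypeGraph(
            human=read_obo(d / DATA_FILES["hpo"]),
            mouse=read_obo(d / DATA_FILES["mpo"]),
            bridges=read_bridges(d / DATA_FILES["bridges"]),
        )
        graph.compute_ic(corpus)
        diseases = {
            did: DiseaseProfile(did, terms)
            for did, terms in read_disease_annotations(d / DATA_FILES["diseases"]).items()
        }
        return cls(
            reference=read_reference(d / DATA_FILES["reference"]),
            index=GeneModelIndex(read_gene_models(d / DATA_FILES["gene_models"])),
            frequency=FrequencyTable.from_tsv(d / DATA_FILES["frequency"]),
            pathogenicity=PathogenicityTable.from_tsv(d / DATA_FILES["pathogenicity"]),
            graph=graph,
            corpus=corpus,
            diseases=diseases,
        )

    def profile_for(self, disease_id: str) -> DiseaseProfile:
        try:
            return self.diseases[disease_id]
        except KeyError:
            near = sorted(self.diseases)[:5]
            raise KeyError(
                f"unknown disease id {disease_id!r}; known ids include {near}"
            ) from None


@dataclass
class PrioritizationResult:
    candidates: list[GeneCandidate]  # ranked under `mode`
    report: FilterReport
    mode: ScoreMode
    disease: DiseaseProfile

    def rank_of(self, gene: str) -> int | None:
        for c in self.candidates:
            if c.gene == gene:
                return c.rank
        return None


def build_candidates(
    gene_map: Mapping[str, Sequence[AnnotatedVariant]],
    relevance: Mapping[str, "object"],
    cfg: FilterConfig,
    class_scores: Mapping | None = None,
) -> list[GeneCandidate]:
    cands = []
    for gene in sorted(gene_map):
        variants = list(gene_map[gene])
        scores = [vs.score_variant(v, class_scores).variant_score for v in variants]
        rel = relevance[gene]
        cands.append(
            GeneCandidate(
                gene=gene,
                variants=variants,
                v=vs.gene_variant_score(scores, cfg.inheritance),
                r=rel.r,
                best_model=rel.best_model,
            )
        )
    return cands


def prioritize_exome(
    variants: Sequence[RawVariant],
    resources: Resources,
    disease: DiseaseProfile,
    cfg: FilterConfig | None = None,
    mode: ScoreMode = ScoreMode.PHIVE,
    default_r: float = DEFAULT_RELEVANCE,
    masked_genes: frozenset = frozenset(),
) -> PrioritizationResult:
    """Run the full prioritization pipeline on one exome.

    annotate -> filter variants -> inheritance filter -> per-gene variant
    score -> phenotypic relevance -> g = (v + r)/2 -> ordinal ranking.
    """
    annotated = annotate_variants(
        variants, resources.index, resources.reference, resources.frequency, resources.pathogenicity
    )
    return prioritize_annotated(
        annotated, resources, disease, cfg, mode, default_r, masked_genes
    )


def prioritize_annotated(
    annotated: Sequence[AnnotatedVariant],
    resources: Resources,
    disease: DiseaseProfile,
    cfg: FilterConfig | None = None,
    mode: ScoreMode = ScoreMode.PHIVE,
    default_r: float = DEFAULT_RELEVANCE,
    masked_genes: frozenset = frozenset(),
) -> PrioritizationResult:
    """Pipeline stages downstream of annotation (reused by the benchmark)."""
    cfg = cfg or FilterConfig()
    surviving, report = filter_variants(annotated, cfg)
    gene_map = apply_inheritance(group_by_gene(surviving), cfg.inheritance)
    relevance = gene_relevance(
        disease,
        sorted(gene_map),
        resources.corpus,
        resources.graph,
        default_r=default_r,
        masked_genes=masked_genes,
    )
    candidates = build_candidates(gene_map, relevance, cfg, resources.class_scores)
    return PrioritizationResult(
        candidates=rank_genes(candidates, mode), report=report, mode=mode, disease=disease
    )


def result_table_rows(result: PrioritizationResult) -> list[dict]:
    """Rows for the ranked-gene output TSV."""
    return [
        {
            "RANK": c.rank,
            "GENE": c.gene,
            "PHIVE": round(c.g, 6),
            "VARIANT_SCORE": round(c.v, 6),
            "PHENO_SCORE": round(c.r, 6),
            "BEST_MODEL": c.best_model or ".",
            "N_VARIANTS": len(c.variants),
        }
        for c in result.candidates
    ]


def variant_detail_rows(result: PrioritizationResult) -> list[dict]:
    rows = []
    for c in result.candidates:
        for av in c.variants:
            parts = vs.score_variant(av)
            rows.append(
                {
                    "GENE": c.gene,
                    "CHROM": av.variant.chrom,
                    "POS": av.variant.pos,
                    "REF": av.variant.ref,
                    "ALT": av.variant.alt,
                    "GENOTYPE": av.genotype.value,
                    "EFFECT": av.effect.value,
                    "MAX_MAF": "." if av.max_maf is None else round(av.max_maf, 6),
                    "FREQ_FACTOR": round(parts.frequency_factor, 6),
                    "PATHOGENICITY": round(parts.pathogenicity, 6),
                    "VARIANT_SCORE": round(parts.variant_score, 6),
                }
            )
    return rows
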