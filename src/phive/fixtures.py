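"""Synthetic toy-world generator for the full pipeline and benchmark.

Generates a mutually consistent set of every input the prioritizer touches:
a small reference genome with exon-level gene models, random HPO-like and
MPO-like ontology DAGs with cross-species bridge equivalences, a mouse-model
corpus with gene assignments and orthologs, disease phenotype profiles, per-
source frequency and pathogenicity tables, background exomes, and spike-in
specs with rare, coding, predicted-pathogenic causal variants.

The designated disease profiles are built from their causal gene's mouse
model via the bridges, with configurable sharpness: at sharpness 1 the
profile is the exact bridged image of the model's terms, so that model
scores 1 against the disease by construction. Term usage across models is
Zipf-skewed, which induces a heterogeneous information-content spectrum.
Everything is deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .annotate import EffectClass, GeneModelIndex, transcript_effect
from .benchmark import SpikeInSpec, write_spikein_specs
from .filters import InheritanceMode
from .io_formats import (
    FrequencyTable,
    GeneModel,
    Genotype,
    PathogenicityRecord,
    PathogenicityTable,
    RawVariant,
    write_vcf,
)
from .phenomatch import DiseaseProfile, ModelCorpus, PhenotypeGraph
from .prioritize import DATA_FILES, Resources

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    n_genes: int = 40
    n_exons_per_gene: int = 3
    exon_length: int = 90
    intron_length: int = 30
    n_background_variants: int = 160  # variants per background exome
    n_background_exomes: int = 12
    n_models: int = 80
    n_hpo_terms: int = 60
    n_mpo_terms: int = 60
    ontology_depth: int = 4
    ontology_branching: int = 3
    n_bridges: int = 40
    fraction_genes_with_models: float = 0.6
    n_diseases: int = 12
    sharpness: float = 1.0  # 1 = disease profile is the exact bridged model image
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_exons_per_gene", "exon_length", "intron_length",
            "n_background_variants", "n_background_exomes", "n_models",
            "n_hpo_terms", "n_mpo_terms", "ontology_depth",
            "ontology_branching", "n_bridges", "n_diseases",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.fraction_genes_with_models <= 1.0):
            raise ValueError("fraction_genes_with_models must be in [0, 1]")
        if not (0.0 <= self.sharpness <= 1.0):
            raise ValueError("sharpness must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class ToyWorld:
    """All generated inputs, in memory, plus writers to the on-disk formats."""

    cfg: FixtureConfig
    reference: dict[str, str]
    gene_models: list[GeneModel]
    hpo: nx.DiGraph
    mpo: nx.DiGraph
    bridges: list[tuple[str, str]]
    model_terms: dict[str, frozenset]
    model_gene: dict[str, str]
    ortholog_pairs: list[tuple[str, str]]
    diseases: dict[str, frozenset]
    disease_gene: dict[str, str]
    spike_specs: list[SpikeInSpec]
    frequency_records: dict
    pathogenicity_records: dict
    backgrounds: dict[str, list[RawVariant]] = field(default_factory=dict)

    def resources(self) -> Resources:
        corpus = ModelCorpus.from_tables(self.model_terms, self.model_gene, self.ortholog_pairs)
        graph = PhenotypeGraph(self.hpo, self.mpo, self.bridges)
        graph.compute_ic(corpus)
        return Resources(
            reference=self.reference,
            index=GeneModelIndex(self.gene_models),
            frequency=FrequencyTable(self.frequency_records),
            pathogenicity=PathogenicityTable(self.pathogenicity_records),
            graph=graph,
            corpus=corpus,
            diseases={d: DiseaseProfile(d, t) for d, t in self.diseases.items()},
        )

    # -- writers ------------------------------------------------------------

    def write(self, out_dir: str | Path) -> Path:
        """Write a self-contained data directory of all input files."""
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        self._write_fasta(d / DATA_FILES["reference"])
        self._write_gene_models(d / DATA_FILES["gene_models"])
        _write_obo(self.hpo, d / DATA_FILES["hpo"], "human phenotype (synthetic)")
        _write_obo(self.mpo, d / DATA_FILES["mpo"], "mouse phenotype (synthetic)")
        _write_tsv(d / DATA_FILES["bridges"], ["TERM_A", "TERM_B"], sorted(self.bridges))
        _write_tsv(
            d / DATA_FILES["models"],
            ["MODEL_ID", "MOUSE_GENE", "MP_TERMS"],
            [
                (mid, self.model_gene[mid], ";".join(sorted(self.model_terms[mid])))
                for mid in sorted(self.model_terms)
            ],
        )
        _write_tsv(d / DATA_FILES["orthologs"], ["MOUSE_GENE", "HUMAN_GENE"], sorted(self.ortholog_pairs))
        _write_tsv(
            d / DATA_FILES["diseases"],
            ["DISEASE_ID", "HP_TERMS"],
            [(did, ";".join(sorted(terms))) for did, terms in sorted(self.diseases.items())],
        )
        _write_tsv(
            d / DATA_FILES["frequency"],
            ["CHROM", "POS", "REF", "ALT", "SOURCE", "MAF"],
            [
                (k[0], k[1], k[2], k[3], src, f"{maf:.6g}")
                for k, sources in sorted(self.frequency_records.items())
                for src, maf in sorted(sources.items())
            ],
        )
        _write_tsv(
            d / DATA_FILES["pathogenicity"],
            ["CHROM", "POS", "REF", "ALT", "SIFT", "POLYPHEN", "MUTTASTER"],
            [
                (
                    k[0], k[1], k[2], k[3],
                    _fmt(rec.sift_raw), _fmt(rec.polyphen_raw), _fmt(rec.mutation_taster_raw),
                )
                for k, rec in sorted(self.pathogenicity_records.items())
            ],
        )
        exome_dir = d / "exomes"
        exome_dir.mkdir(exist_ok=True)
        for bid, variants in sorted(self.backgrounds.items()):
            write_vcf(variants, exome_dir / f"{bid}.vcf", sample_id=bid)
        write_spikein_specs(self.spike_specs, d / "spikein_specs.tsv")
        return d

    def _write_fasta(self, path: Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.reference):
                fh.write(f">{chrom}\n")
                seq = self.reference[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def _write_gene_models(self, path: Path) -> None:
        rows = [
            (
                m.gene, m.transcript, m.chrom, m.strand,
                ",".join(str(s) for s, _ in m.exons),
                ",".join(str(e) for _, e in m.exons),
                m.cds_start if m.cds_start is not None else ".",
                m.cds_end if m.cds_end is not None else ".",
            )
            for m in self.gene_models
        ]
        _write_tsv(
            path,
            ["GENE", "TRANSCRIPT", "CHROM", "STRAND", "EXON_STARTS", "EXON_ENDS", "CDS_START", "CDS_END"],
            rows,
        )


def _fmt(v: float | None) -> str:
    return "." if v is None else f"{v:.4f}"


def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_obo(graph: nx.DiGraph, path: Path, name: str) -> None:
    lines = ["format-version: 1.2", f"ontology: {name}", ""]
    for term in sorted(graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        for parent in sorted(graph.successors(term)):
            lines.append(f"is_a: {parent} ! synthetic term {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _make_dag(prefix: str, n_terms: int, depth: int, branching: int, rng) -> tuple[nx.DiGraph, list[list[str]]]:
    """Random layered DAG: root at level 0, each term parented by 1-2 terms
    one level up. Returns (graph, terms per level)."""
    g = nx.DiGraph()
    ids = [f"{prefix}:{i + 1:07d}" for i in range(n_terms)]
    root = ids[0]
    g.add_node(root)
    # level sizes grow ~geometrically with `branching`
    weights = np.array([float(branching) ** l for l in range(1, depth)])
    sizes = np.maximum(1, np.round((n_terms - 1) * weights / weights.sum())).astype(int)
    while sizes.sum() > n_terms - 1:
        sizes[int(np.argmax(sizes))] -= 1
    while sizes.sum() < n_terms - 1:
        sizes[int(np.argmax(weights))] += 1
    levels: list[list[str]] = [[root]]
    cursor = 1
    for size in sizes:
        level = ids[cursor : cursor + size]
        cursor += size
        for term in level:
            parents = rng.choice(len(levels[-1]), size=min(len(levels[-1]), 1 + int(rng.random() < 0.3)), replace=False)
            for p in parents:
                g.add_edge(term, levels[-1][p])
        levels.append(level)
    return g, levels


def _zipf_probs(n: int, exponent: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def make_toy_world(cfg: FixtureConfig) -> ToyWorld:
    """Generate a complete, internally consistent toy world from the config."""
    rng = np.random.default_rng(cfg.seed)

    # --- genes and reference -------------------------------------------------
    genes = [f"GENE{i + 1:03d}" for i in range(cfg.n_genes)]
    chrom_of: dict[str, str] = {}
    cursors = {"1": 1000, "2": 1000, "3": 1000, "X": 1000}
    models: list[GeneModel] = []
    gap = 400
    for i, gene in enumerate(genes):
        chrom = "X" if i % 10 == 9 else str(i % 3 + 1)
        chrom_of[gene] = chrom
        start = cursors[chrom]
        exons = []
        pos = start
        for _ in range(cfg.n_exons_per_gene):
            exons.append((pos, pos + cfg.exon_length - 1))
            pos += cfg.exon_length + cfg.intron_length
        span_end = exons[-1][1]
        cds_start = exons[0][0] + 6
        cds_end = span_end - 6
        coding_len = sum(
            max(0, min(e, cds_end) - max(s, cds_start) + 1) for s, e in exons
        )
        cds_end -= coding_len % 3
        strand = "+" if i % 2 == 0 else "-"
        models.append(
            GeneModel(
                gene=gene,
                transcript=f"{gene}.t1",
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
                chrom=chrom,
            )
        )
        cursors[chrom] = span_end + gap
    reference = {
        chrom: "".join(rng.choice(_BASES, size=cursors[chrom] + 500))
        for chrom in sorted(cursors)
    }
    index = GeneModelIndex(models)
    model_of_gene = {m.gene: m for m in models}

    # --- ontologies and bridges ---------------------------------------------
    hpo, hpo_levels = _make_dag("HP", cfg.n_hpo_terms, cfg.ontology_depth, cfg.ontology_branching, rng)
    mpo, mpo_levels = _make_dag("MP", cfg.n_mpo_terms, cfg.ontology_depth, cfg.ontology_branching, rng)
    deep_hpo = [t for lvl in hpo_levels[1:] for t in lvl]
    deep_mpo = [t for lvl in mpo_levels[1:] for t in lvl]

    # --- mouse models, orthologs, diseases ----------------------------------
    n_modeled = max(1, int(round(cfg.fraction_genes_with_models * cfg.n_genes)))
    modeled_genes = sorted(rng.choice(genes, size=n_modeled, replace=False))
    ortholog_pairs = [(g.capitalize(), g) for g in modeled_genes]
    mouse_of = {human: mouse for mouse, human in ortholog_pairs}

    n_dis = min(cfg.n_diseases, n_modeled)
    disease_genes = sorted(rng.choice(modeled_genes, size=n_dis, replace=False))

    zipf = _zipf_probs(len(deep_mpo))
    model_terms: dict[str, frozenset] = {}
    model_gene: dict[str, str] = {}
    disease_model: dict[str, str] = {}

    mid_counter = 0

    def new_model(gene: str, terms: frozenset) -> str:
        nonlocal mid_counter
        mid_counter += 1
        mid = f"MODEL{mid_counter:04d}"
        model_terms[mid] = terms
        model_gene[mid] = mouse_of[gene]
        return mid

    # matching model per disease gene: terms drawn uniformly from deep terms
    # (rare usage -> high IC -> sharp, specific profiles)
    for gene in disease_genes:
        k = 3 + int(rng.integers(3))
        terms = frozenset(rng.choice(deep_mpo, size=min(k, len(deep_mpo)), replace=False))
        disease_model[gene] = new_model(gene, terms)

    # background models: Zipf-skewed term usage over randomly chosen genes
    while mid_counter < cfg.n_models:
        gene = modeled_genes[int(rng.integers(len(modeled_genes)))]
        k = 2 + int(rng.integers(4))
        terms = frozenset(
            rng.choice(deep_mpo, size=min(k, len(deep_mpo)), replace=False, p=zipf)
        )
        new_model(gene, terms)

    # bridges: every term of a disease-matching model gets a dedicated HPO
    # equivalent; extra random bridges fill up to n_bridges
    bridged: dict[str, str] = {}  # MPO term -> HPO term
    hpo_pool = [t for t in deep_hpo]
    rng.shuffle(hpo_pool)
    pool_iter = iter(hpo_pool)
    needed = sorted({t for g in disease_genes for t in model_terms[disease_model[g]]})
    for t in needed:
        try:
            bridged[t] = next(pool_iter)
        except StopIteration as exc:
            raise ValueError("n_hpo_terms too small for the required bridges") from exc
    extra_mpo = [t for t in deep_mpo if t not in bridged]
    rng.shuffle(extra_mpo)
    for t in extra_mpo[: max(0, cfg.n_bridges - len(bridged))]:
        try:
            bridged[t] = next(pool_iter)
        except StopIteration:
            break
    bridges = sorted((bridged[t], t) for t in bridged)  # (HPO, MPO)

    unbridged_hpo = [t for t in deep_hpo if t not in set(bridged.values())]

    # disease profiles: bridged image of the matching model, diluted by
    # (1 - sharpness) with unrelated HPO terms
    diseases: dict[str, frozenset] = {}
    disease_gene_map: dict[str, str] = {}
    for j, gene in enumerate(disease_genes):
        did = f"DIS{j + 1:03d}"
        image = sorted(bridged[t] for t in model_terms[disease_model[gene]])
        n_keep = max(1, int(round(cfg.sharpness * len(image))))
        kept = image[:n_keep]
        n_noise = len(image) - n_keep
        noise = (
            list(rng.choice(unbridged_hpo, size=min(n_noise, len(unbridged_hpo)), replace=False))
            if n_noise > 0 and unbridged_hpo
            else []
        )
        diseases[did] = frozenset(kept + noise)
        disease_gene_map[did] = gene

    # --- background variant pool --------------------------------------------
    frequency_records: dict = {}
    pathogenicity_records: dict = {}
    pool: list[tuple] = []  # (RawVariant-template fields, maf or None)
    kinds = ["cds"] * 70 + ["intron"] * 10 + ["splice"] * 5 + ["utr"] * 5 + ["intergenic"] * 10
    pool_size = cfg.n_background_variants * 3
    seen_keys: set = set()
    attempts = 0
    while len(pool) < pool_size and attempts < pool_size * 50:
        attempts += 1
        gene = genes[int(rng.integers(len(genes)))]
        gm = model_of_gene[gene]
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "cds":
            positions = [p for s, e in gm.exons for p in range(max(s, gm.cds_start), min(e, gm.cds_end) + 1)]
        elif kind == "intron":
            positions = [
                p
                for (s1, e1), (s2, _) in zip(gm.exons, gm.exons[1:])
                for p in range(e1 + 3, s2 - 2)
            ]
        elif kind == "splice":
            positions = [p for (s1, e1), (s2, _) in zip(gm.exons, gm.exons[1:]) for p in (e1 + 1, e1 + 2, s2 - 1, s2 - 2)]
        elif kind == "utr":
            positions = list(range(gm.span[0], gm.cds_start)) + list(range(gm.cds_end + 1, gm.span[1] + 1))
        else:
            positions = list(range(gm.span[1] + 50, gm.span[1] + 200))
        if not positions:
            continue
        pos = int(positions[int(rng.integers(len(positions)))])
        chrom = gm.chrom
        ref = reference[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = (chrom, pos, ref, alt)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        if rng.random() < 0.35:
            maf = float(rng.uniform(0.03, 0.5))  # common
        else:
            maf = float(10 ** rng.uniform(-4, -2))  # rare
        if rng.random() < 0.10:
            maf_known = None  # novel: absent from frequency tables
        else:
            maf_known = maf
            sources = {"KG": round(maf, 6)}
            if rng.random() < 0.7:
                sources["ESP"] = round(min(1.0, maf * float(rng.uniform(0.7, 1.0))), 6)
            frequency_records[key] = sources
        if kind == "cds" and rng.random() < 0.8:
            pathogenicity_records[key] = PathogenicityRecord(
                sift_raw=round(1.0 - float(rng.beta(2, 4)), 4) if rng.random() < 0.8 else None,
                polyphen_raw=round(float(rng.beta(2, 4)), 4) if rng.random() < 0.8 else None,
                mutation_taster_raw=round(float(rng.beta(2, 4)), 4) if rng.random() < 0.8 else None,
            )
        pool.append((key, maf))

    # --- background exomes ---------------------------------------------------
    pool_weights = np.array([max(m, 0.002) for _, m in pool])
    pool_weights = np.sqrt(pool_weights)
    pool_weights /= pool_weights.sum()
    backgrounds: dict[str, list[RawVariant]] = {}
    n_draw = min(cfg.n_background_variants, len(pool))
    for b in range(cfg.n_background_exomes):
        bid = f"BG{b + 1:03d}"
        chosen = rng.choice(len(pool), size=n_draw, replace=False, p=pool_weights)
        variants = []
        for idx in sorted(chosen):
            (chrom, pos, ref, alt), maf = pool[idx]
            common = maf is not None and maf > 0.03
            gt = Genotype.HOM_ALT if (common and rng.random() < 0.3) else Genotype.HET
            variants.append(
                RawVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=gt,
                    call_quality=float(np.round(rng.uniform(40, 99), 1)), sample_id=bid,
                )
            )
        backgrounds[bid] = variants

    # --- causal variants and spike-in specs ----------------------------------
    spike_specs: list[SpikeInSpec] = []
    mode_cycle = [InheritanceMode.AD, InheritanceMode.AR, InheritanceMode.AR]
    for j, gene in enumerate(disease_genes):
        did = f"DIS{j + 1:03d}"
        gm = model_of_gene[gene]
        want = EffectClass.NONSENSE if j % 3 == 2 else EffectClass.MISSENSE
        mode = mode_cycle[j % 3]
        comphet = mode is InheritanceMode.AR and j % 2 == 0
        needed_n = 2 if comphet else 1
        causal: list[RawVariant] = []
        cds_positions = [
            p for s, e in gm.exons for p in range(max(s, gm.cds_start), min(e, gm.cds_end) + 1)
        ]
        order = rng.permutation(len(cds_positions))
        for oi in order:
            pos = cds_positions[int(oi)]
            ref = reference[gm.chrom][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                trial = RawVariant(chrom=gm.chrom, pos=pos, ref=ref, alt=alt, genotype=Genotype.HET)
                if (gm.chrom, pos, ref, alt) in seen_keys:
                    continue
                if transcript_effect(trial, gm, reference) is want:
                    causal.append(trial)
                    break
            if len(causal) >= needed_n:
                break
        if len(causal) < needed_n:
            raise RuntimeError(f"could not place causal variant(s) in {gene}")
        if mode is InheritanceMode.AD:
            gts = [Genotype.HET]
        elif comphet:
            gts = [Genotype.HET, Genotype.HET]
        else:
            gts = [Genotype.HOM_ALT]
        final = tuple(
            RawVariant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, genotype=g, call_quality=99.0)
            for v, g in zip(causal, gts)
        )
        for v in final:
            if want is EffectClass.MISSENSE:
                pathogenicity_records[v.key] = PathogenicityRecord(
                    sift_raw=round(float(rng.uniform(0.0, 0.05)), 4),
                    polyphen_raw=round(float(rng.uniform(0.92, 1.0)), 4),
                    mutation_taster_raw=round(float(rng.uniform(0.92, 1.0)), 4),
                )
            # causal variants are novel: no frequency record
        spike_specs.append(SpikeInSpec(disease_id=did, gene=gene, mode=mode, variants=final))

    return ToyWorld(
        cfg=cfg,
        reference=reference,
        gene_models=models,
        hpo=hpo,
        mpo=mpo,
        bridges=bridges,
        model_terms=model_terms,
        model_gene=model_gene,
        ortholog_pairs=ortholog_pairs,
        diseases=diseases,
        disease_gene=disease_gene_map,
        spike_specs=spike_specs,
        frequency_records=frequency_records,
        pathogenicity_records=pathogenicity_records,
        backgrounds=backgrounds,
    )
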