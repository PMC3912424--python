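"""Spike-in validation: insert known causal variants into background exomes.

Each simulated exome is a background ("unaffected") exome plus spiked
disease-causing variant(s): one heterozygous variant for autosomal dominant
diseases; one homozygous variant or two heterozygous variants in the same
gene for autosomal recessive. The pipeline then runs with the associated
disease's phenotype profile and the rank of the causal gene is recorded
under each score mode (PHIVE, variant-only, phenotype-only). Summary metrics
are top-k rates, pooled gene-level ROC AUC via the rank-sum formulation, and
precision-recall points; a random-disease control replaces each run's
disease with a different, uniformly drawn one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve

from .annotate import annotate_variants
from .filters import FilterConfig, InheritanceMode
from .io_formats import Genotype, RawVariant, read_vcf, write_vcf
from .phenomatch import DEFAULT_RELEVANCE, DiseaseProfile
from .prioritize import (
    PrioritizationResult,
    Resources,
    ScoreMode,
    prioritize_annotated,
)

ALL_MODES = (ScoreMode.PHIVE, ScoreMode.VARIANT_ONLY, ScoreMode.PHENOTYPE_ONLY)


@dataclass(frozen=True)
class SpikeInSpec:
    """One causal spike-in: variant(s), target genotype, disease, mode."""

    disease_id: str
    gene: str
    mode: InheritanceMode
    variants: tuple[RawVariant, ...]

    def __post_init__(self) -> None:
        gts = [v.genotype for v in self.variants]
        if self.mode is InheritanceMode.AD:
            if gts != [Genotype.HET]:
                raise ValueError("AD spike-in must be exactly one HET variant")
        elif self.mode in (InheritanceMode.AR, InheritanceMode.XR):
            hom = gts.count(Genotype.HOM_ALT)
            het = gts.count(Genotype.HET)
            if not ((hom == 1 and het == 0) or (het >= 2 and hom == 0)):
                raise ValueError(
                    "recessive spike-in must be one HOM_ALT or two+ HET variants"
                )
        if not self.variants:
            raise ValueError("spike-in needs >= 1 variant")


def read_spikein_specs(path: str | Path) -> list[SpikeInSpec]:
    """Read a spike-in spec TSV (DISEASE_ID, GENE, CHROM, POS, REF, ALT,
    GENOTYPE, MODE); rows sharing DISEASE_ID+GENE+MODE form one spec."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["DISEASE_ID", "GENE", "CHROM", "POS", "REF", "ALT", "GENOTYPE", "MODE"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    specs = []
    for (did, gene, mode), grp in df.groupby(["DISEASE_ID", "GENE", "MODE"], sort=True):
        variants = tuple(
            RawVariant(
                chrom=row.CHROM,
                pos=int(row.POS),
                ref=row.REF,
                alt=row.ALT,
                genotype=Genotype[row.GENOTYPE],
            )
            for row in grp.itertuples(index=False)
        )
        specs.append(
            SpikeInSpec(disease_id=did, gene=gene, mode=InheritanceMode[mode], variants=variants)
        )
    return specs


def write_spikein_specs(specs: Sequence[SpikeInSpec], path: str | Path) -> None:
    lines = ["DISEASE_ID\tGENE\tCHROM\tPOS\tREF\tALT\tGENOTYPE\tMODE"]
    for s in specs:
        for v in s.variants:
            lines.append(
                f"{s.disease_id}\t{s.gene}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.genotype.value}\t{s.mode.value}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def spike_in(background_vcf: str | Path, spec: SpikeInSpec, out_path: str | Path) -> int:
    """Write background + causal record(s) as a new VCF; returns #records added.

    A background record at the same variant key is overwritten by the causal
    one (logged by the reader as part of normal rescanning).
    """
    scan = read_vcf(background_vcf)
    causal_keys = {v.key for v in spec.variants}
    kept = [v for v in scan.variants if v.key not in causal_keys]
    sample = kept[0].sample_id if kept else "SAMPLE"
    causal = [
        RawVariant(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            genotype=v.genotype, call_quality=99.0, sample_id=sample,
        )
        for v in spec.variants
    ]
    write_vcf(kept + causal, out_path, sample_id=sample)
    return len(causal)


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class RunOutcome:
    spec: SpikeInSpec
    disease_used: str
    background_id: str
    causal_masked: bool
    n_genes: int
    rank: dict[ScoreMode, int | None]
    # per-run gene scores for pooled ROC/PR: mode -> (scores, is_causal)
    scores: dict[ScoreMode, tuple[list[float], list[int]]]


@dataclass
class BenchmarkSummary:
    n_runs: int
    top_k: dict[ScoreMode, dict[int, float]]  # mode -> {1: %, 10: %}
    auc: dict[ScoreMode, float]
    per_exome_auc: dict[ScoreMode, float]
    pr_points: dict[ScoreMode, list[tuple[float, float]]]  # (recall, precision)
    mean_candidates: float = 0.0

    def as_rows(self) -> list[dict]:
        return [
            {
                "MODE": mode.value,
                "TOP1_PCT": round(self.top_k[mode][1], 3),
                "TOP10_PCT": round(self.top_k[mode][10], 3),
                "AUC": round(self.auc[mode], 5),
                "PER_EXOME_AUC": round(self.per_exome_auc[mode], 5),
            }
            for mode in self.top_k
        ]


def rank_sum_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC via the Mann-Whitney rank-sum identity (ties mid-ranked)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pooled_scores(
    runs: Sequence[RunOutcome], mode: ScoreMode
) -> tuple[list[float], list[int]]:
    """Gene scores pooled across runs with causal (1) / background (0) labels."""
    scores: list[float] = []
    labels: list[int] = []
    for r in runs:
        s, lab = r.scores[mode]
        scores.extend(s)
        labels.extend(lab)
    return scores, labels


def evaluate(runs: Sequence[RunOutcome], modes: Sequence[ScoreMode] = ALL_MODES) -> BenchmarkSummary:
    """Top-k rates, pooled and per-exome ROC AUC, and PR points per mode."""
    n = len(runs)
    top_k: dict[ScoreMode, dict[int, float]] = {}
    auc: dict[ScoreMode, float] = {}
    per_exome: dict[ScoreMode, float] = {}
    pr: dict[ScoreMode, list[tuple[float, float]]] = {}
    for mode in modes:
        top_k[mode] = {
            k: 100.0 * sum(1 for r in runs if r.rank[mode] is not None and r.rank[mode] <= k) / n
            for k in (1, 10)
        }
        pooled_scores: list[float] = []
        pooled_labels: list[int] = []
        exome_aucs = []
        for r in runs:
            s, lab = r.scores[mode]
            pooled_scores.extend(s)
            pooled_labels.extend(lab)
            a = rank_sum_auc(s, lab)
            if not np.isnan(a):
                exome_aucs.append(a)
        auc[mode] = rank_sum_auc(pooled_scores, pooled_labels)
        per_exome[mode] = float(np.mean(exome_aucs)) if exome_aucs else float("nan")
        if any(pooled_labels):
            precision, recall, _ = precision_recall_curve(pooled_labels, pooled_scores)
            pr[mode] = list(zip(recall.tolist(), precision.tolist()))
        else:
            pr[mode] = []
    return BenchmarkSummary(
        n_runs=n,
        top_k=top_k,
        auc=auc,
        per_exome_auc=per_exome,
        pr_points=pr,
        mean_candidates=float(np.mean([r.n_genes for r in runs])) if runs else 0.0,
    )


def run_benchmark(
    resources: Resources,
    specs: Sequence[SpikeInSpec],
    backgrounds: Mapping[str, Sequence[RawVariant]],
    n_runs: int = 500,
    seed: int = 0,
    cfg: FilterConfig | None = None,
    default_r: float = DEFAULT_RELEVANCE,
    model_coverage: float = 1.0,
    random_disease: bool = False,
    modes: Sequence[ScoreMode] = ALL_MODES,
) -> list[RunOutcome]:
    """Run the spike-in benchmark and return per-run outcomes.

    ``model_coverage`` is the fraction of runs in which the causal gene has
    mouse phenotype data; in the remaining runs its models are masked and it
    falls back to ``default_r``. ``random_disease`` replaces each run's
    disease with a uniformly drawn different one (negative control).
    Background exomes are annotated once and cached; the causal records are
    appended per run, replacing colliding background keys.
    """
    if not specs:
        raise ValueError("no spike-in specs supplied")
    if random_disease and len(resources.diseases) < 2:
        raise ValueError("random-disease control needs a pool of >= 2 diseases")
    rng = np.random.default_rng(seed)
    base_cfg = cfg or FilterConfig()
    bg_ids = sorted(backgrounds)

    ann_bg: dict[str, list] = {}
    bg_keys: dict[str, set] = {}
    ann_spec: dict[int, list] = {}

    def annotated_background(bid: str):
        if bid not in ann_bg:
            ann = annotate_variants(
                backgrounds[bid], resources.index, resources.reference,
                resources.frequency, resources.pathogenicity,
            )
            ann_bg[bid] = ann
            bg_keys[bid] = {a.key for a in ann}
        return ann_bg[bid]

    disease_ids = sorted(resources.diseases)
    outcomes: list[RunOutcome] = []
    for i in range(n_runs):
        spec = specs[i % len(specs)]
        bid = bg_ids[int(rng.integers(len(bg_ids)))]
        masked = bool(rng.random() >= model_coverage)
        if random_disease:
            others = [d for d in disease_ids if d != spec.disease_id]
            disease_id = others[int(rng.integers(len(others)))]
        else:
            disease_id = spec.disease_id
        disease = resources.profile_for(disease_id)

        spec_idx = i % len(specs)
        if spec_idx not in ann_spec:
            ann_spec[spec_idx] = annotate_variants(
                spec.variants, resources.index, resources.reference,
                resources.frequency, resources.pathogenicity,
            )
        causal_keys = {v.key for v in spec.variants}
        background_ann = [a for a in annotated_background(bid) if a.key not in causal_keys]
        annotated = background_ann + ann_spec[spec_idx]

        run_cfg = FilterConfig(
            max_maf=base_cfg.max_maf,
            min_quality=base_cfg.min_quality,
            remove_synonymous=base_cfg.remove_synonymous,
            remove_offtarget=base_cfg.remove_offtarget,
            remove_nonpathogenic=base_cfg.remove_nonpathogenic,
            nonpathogenic_cutoff=base_cfg.nonpathogenic_cutoff,
            inheritance=spec.mode,
        )
        result = prioritize_annotated(
            annotated, resources, disease, run_cfg,
            mode=ScoreMode.PHIVE, default_r=default_r,
            masked_genes=frozenset({spec.gene}) if masked else frozenset(),
        )
        outcomes.append(
            _score_run(result, spec, disease_id, bid, masked, modes)
        )
    return outcomes


def _score_run(
    result: PrioritizationResult,
    spec: SpikeInSpec,
    disease_id: str,
    bid: str,
    masked: bool,
    modes: Sequence[ScoreMode],
) -> RunOutcome:
    from .prioritize import rank_genes

    rank: dict[ScoreMode, int | None] = {}
    scores: dict[ScoreMode, tuple[list[float], list[int]]] = {}
    cands = result.candidates
    for mode in modes:
        ranked = rank_genes(cands, mode)
        rank[mode] = next((c.rank for c in ranked if c.gene == spec.gene), None)
        scores[mode] = (
            [c.score(mode) for c in ranked],
            [1 if c.gene == spec.gene else 0 for c in ranked],
        )
    return RunOutcome(
        spec=spec,
        disease_used=disease_id,
        background_id=bid,
        causal_masked=masked,
        n_genes=len(cands),
        rank=rank,
        scores=scores,
    )


def random_disease_control(
    resources: Resources,
    specs: Sequence[SpikeInSpec],
    backgrounds: Mapping[str, Sequence[RawVariant]],
    seed: int = 0,
    **kwargs,
) -> list[RunOutcome]:
    """Negative control: rerun the benchmark with mismatched disease profiles."""
    return run_benchmark(
        resources, specs, backgrounds, seed=seed, random_disease=True, **kwargs
    )
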