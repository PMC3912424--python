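"""The variant filter cascade and Mendelian inheritance-model gene filters.

Variant-level filtering removes low-quality, common, off-target and
synonymous variants (each stage independently switchable); variants with no
frequency data are always kept — absence of evidence of commonness is not
evidence of commonness. Gene-level inheritance filtering then keeps only
genes whose surviving variants are compatible with the assumed mode:
autosomal dominant needs at least one heterozygous variant, autosomal
recessive at least one homozygous or two or more heterozygous variants
(compound heterozygote; no phasing is attempted), X-linked recessive a
homozygous variant in a chromosome X gene (hemizygous male calls appear as
homozygous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .annotate import OFFTARGET_CLASSES, AnnotatedVariant, EffectClass
from .io_formats import Genotype


class InheritanceMode(Enum):
    NONE = "NONE"
    AD = "AD"
    AR = "AR"
    XR = "XR"


@dataclass
class FilterConfig:
    max_maf: float = 0.01
    min_quality: float = 0.0
    remove_synonymous: bool = True
    remove_offtarget: bool = True
    remove_nonpathogenic: bool = False
    nonpathogenic_cutoff: float = 0.5
    inheritance: InheritanceMode = InheritanceMode.NONE

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_maf <= 1.0):
            raise ValueError(f"max_maf must be in [0, 1], got {self.max_maf}")
        if isinstance(self.inheritance, str):
            self.inheritance = InheritanceMode[self.inheritance]


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_dropped: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_dropped


@dataclass
class FilterReport:
    """Per-stage counts plus a retrievable drop reason per removed variant."""

    stages: list[FilterStage] = field(default_factory=list)
    reasons: dict = field(default_factory=dict)  # (key, gene) -> stage name
    n_input: int = 0
    n_surviving: int = 0

    def reason_for(self, variant: AnnotatedVariant) -> str | None:
        return self.reasons.get((variant.key, variant.gene))

    def as_rows(self) -> list[dict]:
        return [
            {"STAGE": s.name, "IN": s.n_in, "DROPPED": s.n_dropped, "OUT": s.n_out}
            for s in self.stages
        ]


# Stage predicates return True when the variant is DROPPED. Each stage looks
# only at the variant itself, so the cascade outcome is order-insensitive.


def _drop_quality(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return cfg.min_quality > 0 and v.variant.call_quality < cfg.min_quality


def _drop_frequency(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return v.max_maf is not None and v.max_maf > cfg.max_maf


def _drop_offtarget(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return cfg.remove_offtarget and v.effect in OFFTARGET_CLASSES


def _drop_synonymous(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return cfg.remove_synonymous and v.effect is EffectClass.SYNONYMOUS


def _drop_nonpathogenic(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if not cfg.remove_nonpathogenic:
        return False
    from .variant_score import pathogenicity_score

    return pathogenicity_score(v) < cfg.nonpathogenic_cutoff


_STAGES = [
    ("quality", _drop_quality),
    ("frequency", _drop_frequency),
    ("offtarget", _drop_offtarget),
    ("synonymous", _drop_synonymous),
    ("pathogenicity", _drop_nonpathogenic),
]


def filter_variants(
    variants: Sequence[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Run the variant filter cascade; returns survivors and the stage report."""
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(variants))
    current = list(variants)
    for name, drop in _STAGES:
        kept, n_dropped = [], 0
        for v in current:
            if drop(v, cfg):
                n_dropped += 1
                report.reasons[(v.key, v.gene)] = name
            else:
                kept.append(v)
        report.stages.append(FilterStage(name=name, n_in=len(current), n_dropped=n_dropped))
        current = kept
    report.n_surviving = len(current)
    return current, report


def group_by_gene(variants: Sequence[AnnotatedVariant]) -> dict[str, list[AnnotatedVariant]]:
    """Group surviving variants per gene, dropping intergenic leftovers."""
    genes: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.gene is not None:
            genes.setdefault(v.gene, []).append(v)
    return genes


def _is_x(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() == "X"


def gene_passes_inheritance(variants: Sequence[AnnotatedVariant], mode: InheritanceMode) -> bool:
    n_het = sum(1 for v in variants if v.genotype is Genotype.HET)
    n_hom = sum(1 for v in variants if v.genotype is Genotype.HOM_ALT)
    if mode is InheritanceMode.NONE:
        return True
    if mode is InheritanceMode.AD:
        return n_het >= 1
    if mode is InheritanceMode.AR:
        return n_hom >= 1 or n_het >= 2
    if mode is InheritanceMode.XR:
        return any(
            v.genotype is Genotype.HOM_ALT and _is_x(v.variant.chrom) for v in variants
        )
    raise ValueError(f"unknown inheritance mode: {mode!r}")


def apply_inheritance(
    genes: Mapping[str, Sequence[AnnotatedVariant]], mode: InheritanceMode
) -> dict[str, list[AnnotatedVariant]]:
    """Keep only genes whose variants fit the assumed inheritance mode."""
    if not isinstance(mode, InheritanceMode):
        raise ValueError(f"unknown inheritance mode: {mode!r}")
    return {g: list(vs) for g, vs in genes.items() if gene_passes_inheritance(vs, mode)}
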