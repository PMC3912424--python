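"""Functional effect classification of variants against exon-level gene models.

A deliberately minimal transcript-effect annotator: SNVs inside a CDS are
translated against the coding frame to call missense / nonsense / synonymous;
CDS indels are frameshift when their length is not a multiple of three;
variants within 2 bp of an exon/intron boundary are splice-site. Transcript
calls within one gene are collapsed to the most deleterious class. A variant
overlapping several genes yields one annotation per gene.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import (
    FrequencyTable,
    GeneModel,
    PathogenicityRecord,
    PathogenicityTable,
    RawVariant,
)

SPLICE_WINDOW = 2  # bp into the intron counted as canonical splice site


class EffectClass(Enum):
    FRAMESHIFT = "FRAMESHIFT"
    NONSENSE = "NONSENSE"
    SPLICE_SITE = "SPLICE_SITE"
    MISSENSE = "MISSENSE"
    NON_FS_INDEL = "NON_FS_INDEL"
    SYNONYMOUS = "SYNONYMOUS"
    UTR = "UTR"
    INTRONIC = "INTRONIC"
    NONCODING_RNA = "NONCODING_RNA"
    INTERGENIC = "INTERGENIC"


#: Collapse order: lower rank = more deleterious. FRAMESHIFT and NONSENSE are
#: deliberately tied at the top (both get the same fixed pathogenicity later).
SEVERITY: dict[EffectClass, int] = {
    EffectClass.FRAMESHIFT: 0,
    EffectClass.NONSENSE: 0,
    EffectClass.SPLICE_SITE: 1,
    EffectClass.MISSENSE: 2,
    EffectClass.NON_FS_INDEL: 3,
    EffectClass.SYNONYMOUS: 4,
    EffectClass.UTR: 5,
    EffectClass.INTRONIC: 6,
    EffectClass.NONCODING_RNA: 6,
    EffectClass.INTERGENIC: 7,
}

#: Classes treated as off-target by the filter cascade.
OFFTARGET_CLASSES = frozenset(
    {EffectClass.UTR, EffectClass.INTRONIC, EffectClass.NONCODING_RNA, EffectClass.INTERGENIC}
)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its per-gene effect call and table lookups attached.

    ``gene`` is ``None`` exactly when the effect is INTERGENIC. ``max_maf``
    and ``predictions`` are ``None`` when the variant has no table entry
    ("no data" — distinct from a value of zero).
    """

    variant: RawVariant
    effect: EffectClass
    gene: str | None
    max_maf: float | None = None
    predictions: PathogenicityRecord | None = None

    def __post_init__(self) -> None:
        if (self.gene is None) != (self.effect is EffectClass.INTERGENIC):
            raise ValueError("gene must be None iff effect is INTERGENIC")

    @property
    def key(self):
        return self.variant.key

    @property
    def genotype(self):
        return self.variant.genotype


class GeneModelIndex:
    """Per-chromosome interval lookup over transcripts (span +/- splice window)."""

    def __init__(self, models: Sequence[GeneModel]):
        self._by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for m in models:
            s, e = m.span
            self._by_chrom.setdefault(m.chrom, []).append((s, e, m))
        self._starts: dict[str, list[int]] = {}
        for chrom, entries in self._by_chrom.items():
            entries.sort(key=lambda t: (t[0], t[1], t[2].transcript))
            self._starts[chrom] = [s for s, _, _ in entries]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        entries = self._by_chrom.get(chrom)
        if not entries:
            return []
        hi = bisect.bisect_right(self._starts[chrom], pos)
        # Toy-scale transcripts: linear scan left of the insertion point.
        return [m for s, e, m in entries[:hi] if s <= pos <= e]


def _cds_positions(model: GeneModel) -> list[int]:
    """Genomic positions of coding bases, ascending."""
    out: list[int] = []
    for s, e in model.exons:
        lo = max(s, model.cds_start)
        hi = min(e, model.cds_end)
        if lo <= hi:
            out.extend(range(lo, hi + 1))
    return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def transcript_effect(variant: RawVariant, model: GeneModel, reference: Mapping[str, str]) -> EffectClass | None:
    """Effect of one variant on one transcript, or None if outside its span."""
    pos = variant.pos
    span_s, span_e = model.span
    if variant.chrom != model.chrom or not (span_s <= pos <= span_e):
        return None

    in_exon = any(s <= pos <= e for s, e in model.exons)
    if not in_exon:
        # intron: distance to the nearest exon edge decides splice vs intronic
        dist = min(
            min(abs(pos - (e + 1)), abs(pos - (s - 1)))
            for s, e in model.exons
            if pos < s or pos > e
        )
        return EffectClass.SPLICE_SITE if dist < SPLICE_WINDOW else EffectClass.INTRONIC

    if not model.is_coding:
        return EffectClass.NONCODING_RNA
    if pos < model.cds_start or pos > model.cds_end:
        return EffectClass.UTR

    if not variant.is_snv:
        shift = abs(len(variant.ref) - len(variant.alt))
        if shift == 0:  # MNV: treat like an in-frame change
            return EffectClass.NON_FS_INDEL
        return EffectClass.FRAMESHIFT if shift % 3 else EffectClass.NON_FS_INDEL

    cds = _cds_positions(model)
    i = bisect.bisect_left(cds, pos)
    seq = reference[variant.chrom]
    coding = "".join(seq[p - 1] for p in cds)
    alt_base = variant.alt
    if model.strand == "-":
        coding = coding.translate(_COMPLEMENT)[::-1]
        i = len(cds) - 1 - i
        alt_base = alt_base.translate(_COMPLEMENT)

    codon_idx, offset = divmod(i, 3)
    codon = coding[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:  # trailing partial codon in a toy model
        return EffectClass.SYNONYMOUS
    mutated = codon[:offset] + alt_base + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if ref_aa == alt_aa:
        return EffectClass.SYNONYMOUS
    if alt_aa == "*":
        return EffectClass.NONSENSE
    return EffectClass.MISSENSE  # includes stop-loss


def classify(
    variant: RawVariant,
    index: GeneModelIndex,
    reference: Mapping[str, str],
    frequency: FrequencyTable | None = None,
    pathogenicity: PathogenicityTable | None = None,
) -> list[AnnotatedVariant]:
    """Classify a variant against all overlapping genes.

    Returns one :class:`AnnotatedVariant` per overlapped gene, each carrying
    the most deleterious effect among that gene's transcripts; a single
    INTERGENIC annotation when no gene overlaps.
    """
    per_gene: dict[str, EffectClass] = {}
    for model in index.overlapping(variant.chrom, variant.pos):
        eff = transcript_effect(variant, model, reference)
        if eff is None:
            continue
        prev = per_gene.get(model.gene)
        if prev is None or SEVERITY[eff] < SEVERITY[prev]:
            per_gene[model.gene] = eff

    maf = frequency.max_maf(variant.key) if frequency is not None else None
    preds = pathogenicity.get(variant.key) if pathogenicity is not None else None

    if not per_gene:
        return [
            AnnotatedVariant(
                variant=variant,
                effect=EffectClass.INTERGENIC,
                gene=None,
                max_maf=maf,
                predictions=preds,
            )
        ]
    return [
        AnnotatedVariant(variant=variant, effect=eff, gene=gene, max_maf=maf, predictions=preds)
        for gene, eff in sorted(per_gene.items())
    ]


def annotate_variants(
    variants: Sequence[RawVariant],
    index: GeneModelIndex,
    reference: Mapping[str, str],
    frequency: FrequencyTable | None = None,
    pathogenicity: PathogenicityTable | None = None,
) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    for v in variants:
        out.extend(classify(v, index, reference, frequency, pathogenicity))
    return out
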