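"""Readers and writers for every external file the pipeline touches.

All downstream modules consume only the domain types produced here:
variants from single-sample VCF 4.x, per-source allele frequencies and
pathogenicity predictions from TSV tables, exon-level gene models from TSV,
phenotype ontologies from OBO, and the mouse-model / ortholog / disease
annotation tables.

Coordinates are VCF-style 1-based throughout; gene-model exon intervals are
1-based inclusive. Multi-allelic VCF records are decomposed into one variant
per ALT allele before anything else; indels are not left-normalized.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

logger = logging.getLogger("phive")

#: Key identifying a variant across all lookup tables: (chrom, pos, ref, alt).
VariantKey = tuple[str, int, str, str]


class Genotype(enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


@dataclass(frozen=True)
class RawVariant:
    """One decomposed VCF record for the analysed sample."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotype: Genotype
    call_quality: float = 0.0
    sample_id: str = "SAMPLE"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.call_quality < 0:
            raise ValueError("call_quality must be non-negative")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class PathogenicityRecord:
    """Raw predictor outputs for one variant; ``None`` marks an absent value.

    SIFT is on its native scale (0 = damaging); the 1 - s transform is
    applied downstream in the scoring module, never here.
    """

    sift_raw: float | None = None
    polyphen_raw: float | None = None
    mutation_taster_raw: float | None = None

    def __post_init__(self) -> None:
        for name in ("sift_raw", "polyphen_raw", "mutation_taster_raw"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def has_any(self) -> bool:
        return any(
            v is not None
            for v in (self.sift_raw, self.polyphen_raw, self.mutation_taster_raw)
        )


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure plus the CDS interval (genomic coords).

    ``cds_start``/``cds_end`` are ``None`` for non-coding transcripts.
    """

    gene: str
    transcript: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    cds_start: int | None
    cds_end: int | None
    chrom: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have >= 1 exon")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon interval ({s}, {e}) inverted")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start <= self.cds_end <= self.span[1]):
                raise ValueError("CDS must lie within the exon span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfScan:
    """Variants read from one VCF plus the bookkeeping counters."""

    variants: list[RawVariant] = field(default_factory=list)
    n_records: int = 0
    n_malformed: int = 0
    n_missing_genotype: int = 0

    def __iter__(self) -> Iterator[RawVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def read_vcf(path: str | Path, sample_id: str | None = None) -> VcfScan:
    """Read a VCF 4.x file into decomposed :class:`RawVariant` records.

    Multi-allelic records are split into one variant per ALT allele, with the
    genotype resolved per allele (e.g. GT 1/2 yields HET for both alleles).
    Records whose genotype for the analysed sample is missing (./.) are
    dropped and counted; malformed records are skipped with a warning.

    Parameters
    ----------
    path
        VCF (optionally bgzipped) file path.
    sample_id
        Sample to analyse. May be omitted only for single-sample files.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError(
                f"{path}: {len(samples)} samples present; pass an explicit sample_id"
            )
        sample_id = samples[0]
    if sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not in VCF header ({samples})")
    sidx = samples.index(sample_id)

    scan = VcfScan()
    for rec in vcf:
        scan.n_records += 1
        try:
            gt = rec.genotypes[sidx]
            alleles = [a for a in gt[:-1] if isinstance(a, int)]
            qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
            for alt_idx, alt in enumerate(rec.ALT, start=1):
                if alt is None or alt in (".", "*", "<NON_REF>") or alt == rec.REF:
                    scan.n_malformed += 1
                    continue
                if any(a < 0 for a in alleles) or not alleles:
                    scan.n_missing_genotype += 1
                    continue
                n_alt = sum(1 for a in alleles if a == alt_idx)
                if n_alt == 0:
                    genotype = Genotype.HOM_REF
                elif n_alt >= len(alleles):
                    genotype = Genotype.HOM_ALT
                else:
                    genotype = Genotype.HET
                scan.variants.append(
                    RawVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        genotype=genotype,
                        call_quality=max(qual, 0.0),
                        sample_id=sample_id,
                    )
                )
        except Exception:  # malformed record: skip, count, keep going
            scan.n_malformed += 1
            logger.warning("skipping malformed record #%d in %s", scan.n_records, path)
    if scan.n_missing_genotype:
        logger.info(
            "%s: dropped %d allele calls with missing genotype",
            path,
            scan.n_missing_genotype,
        )
    return scan


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    variants: Sequence[RawVariant],
    path: str | Path,
    sample_id: str | None = None,
    info: Mapping[VariantKey, str] | None = None,
) -> None:
    """Write variants as a minimal single-sample VCFv4.2 text file.

    Records are sorted by (chrom, pos, ref, alt). ``info`` optionally maps a
    variant key to a pre-formatted INFO string (used for EFFECT/GENE tags).
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else "SAMPLE"
    contigs = sorted({v.chrom for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=phive",
        *(f"##contig=<ID={c}>" for c in contigs),
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Variant effect class">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    for v in variants:
        inf = info.get(v.key, ".") if info else "."
        qual = f"{v.call_quality:g}" if v.call_quality else "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t{inf}\tGT\t"
            + _GT_STRING[v.genotype]
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


class FrequencyTable:
    """Per-source minor allele frequencies keyed by variant.

    ``max_maf`` returns the maximal reported MAF across sources, or ``None``
    (the "no data" sentinel) for variants absent from every source — defaults
    are applied downstream, never here.
    """

    def __init__(self, records: Mapping[VariantKey, Mapping[str, float]]):
        self._records = {k: dict(v) for k, v in records.items()}
        for key, per_source in self._records.items():
            for source, maf in per_source.items():
                if not (0.0 <= maf <= 1.0):
                    raise ValueError(f"MAF {maf} for {key} ({source}) outside [0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = _read_tsv(path, ["CHROM", "POS", "REF", "ALT", "SOURCE", "MAF"])
        records: dict[VariantKey, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            key = (row.CHROM, int(row.POS), row.REF, row.ALT)
            records.setdefault(key, {})[row.SOURCE] = float(row.MAF)
        return cls(records)

    def sources(self, key: VariantKey) -> dict[str, float] | None:
        rec = self._records.get(key)
        return dict(rec) if rec is not None else None

    def max_maf(self, key: VariantKey) -> float | None:
        rec = self._records.get(key)
        if not rec:
            return None
        return max(rec.values())

    def __len__(self) -> int:
        return len(self._records)


class PathogenicityTable:
    """SIFT / PolyPhen-2 / MutationTaster raw predictions keyed by variant."""

    def __init__(self, records: Mapping[VariantKey, PathogenicityRecord]):
        self._records = dict(records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathogenicityTable":
        df = _read_tsv(path, ["CHROM", "POS", "REF", "ALT", "SIFT", "POLYPHEN", "MUTTASTER"])
        records: dict[VariantKey, PathogenicityRecord] = {}

        def parse(v: str) -> float | None:
            return None if v in (".", "") else float(v)

        for row in df.itertuples(index=False):
            key = (row.CHROM, int(row.POS), row.REF, row.ALT)
            records[key] = PathogenicityRecord(
                sift_raw=parse(row.SIFT),
                polyphen_raw=parse(row.POLYPHEN),
                mutation_taster_raw=parse(row.MUTTASTER),
            )
        return cls(records)

    def get(self, key: VariantKey) -> PathogenicityRecord | None:
        """Predictions for a variant, or ``None`` if it has no table entry."""
        return self._records.get(key)

    def __len__(self) -> int:
        return len(self._records)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the exon-level transcript table.

    Expected columns: GENE, TRANSCRIPT, CHROM, STRAND, EXON_STARTS, EXON_ENDS
    (comma-separated, 1-based inclusive), CDS_START, CDS_END ('.' for
    non-coding transcripts).
    """
    df = _read_tsv(
        path,
        ["GENE", "TRANSCRIPT", "CHROM", "STRAND", "EXON_STARTS", "EXON_ENDS", "CDS_START", "CDS_END"],
    )
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.EXON_STARTS.split(",") if x]
        ends = [int(x) for x in row.EXON_ENDS.split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(
                f"{path}: transcript {row.TRANSCRIPT} has {len(starts)} starts "
                f"but {len(ends)} ends"
            )
        models.append(
            GeneModel(
                gene=row.GENE,
                transcript=row.TRANSCRIPT,
                strand=row.STRAND,
                exons=tuple(zip(starts, ends)),
                cds_start=None if row.CDS_START == "." else int(row.CDS_START),
                cds_end=None if row.CDS_END == "." else int(row.CDS_END),
                chrom=row.CHROM,
            )
        )
    return models


def read_model_annotations(path: str | Path) -> tuple[dict[str, frozenset], dict[str, str]]:
    """Read mouse-model annotations: MODEL_ID, MOUSE_GENE, MP_TERMS (';'-sep).

    Returns (model -> MPO term set, model -> mouse gene).
    """
    df = _read_tsv(path, ["MODEL_ID", "MOUSE_GENE", "MP_TERMS"])
    terms: dict[str, frozenset] = {}
    genes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        tset = frozenset(t for t in row.MP_TERMS.split(";") if t)
        if not tset:
            raise ValueError(f"{path}: model {row.MODEL_ID} has no MP terms")
        terms[row.MODEL_ID] = tset
        genes[row.MODEL_ID] = row.MOUSE_GENE
    return terms, genes


def read_orthologs(path: str | Path) -> list[tuple[str, str]]:
    """Read the mouse->human ortholog map: MOUSE_GENE, HUMAN_GENE."""
    df = _read_tsv(path, ["MOUSE_GENE", "HUMAN_GENE"])
    return [(row.MOUSE_GENE, row.HUMAN_GENE) for row in df.itertuples(index=False)]


def read_disease_annotations(path: str | Path) -> dict[str, frozenset]:
    """Read disease HPO profiles: DISEASE_ID, HP_TERMS (';'-separated)."""
    df = _read_tsv(path, ["DISEASE_ID", "HP_TERMS"])
    out: dict[str, frozenset] = {}
    for row in df.itertuples(index=False):
        tset = frozenset(t for t in row.HP_TERMS.split(";") if t)
        if not tset:
            raise ValueError(f"{path}: disease {row.DISEASE_ID} has no HP terms")
        out[row.DISEASE_ID] = tset
    return out


def read_bridges(path: str | Path) -> list[tuple[str, str]]:
    """Read cross-species term equivalences: TERM_A, TERM_B."""
    df = _read_tsv(path, ["TERM_A", "TERM_B"])
    return [(row.TERM_A, row.TERM_B) for row in df.itertuples(index=False)]


def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology keeping only is_a edges, child -> parent."""
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return g


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a reference FASTA into a chrom -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def max_maf_of(sources: Mapping[str, float] | None) -> float | None:
    """Maximal MAF across sources; ``None`` in, ``None`` out."""
    if not sources:
        return None
    m = max(sources.values())
    if math.isnan(m):
        return None
    return m
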