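"""Effect classification against toy transcripts, including a brute-force
codon-translation oracle over every CDS position."""

import itertools

import pytest
from Bio.Seq import Seq

from phive.annotate import (
    SEVERITY,
    EffectClass,
    GeneModelIndex,
    classify,
    transcript_effect,
)
from phive.io_formats import GeneModel, Genotype, RawVariant


def _ref_for(model: GeneModel, fill: str = "A") -> dict:
    """Reference where every CDS codon is CAA (Gln) so single-base effects
    are easy to state by hand; non-CDS bases are `fill`."""
    length = model.span[1] + 50
    seq = [fill] * length
    cds = [
        p
        for s, e in model.exons
        for p in range(max(s, model.cds_start), min(e, model.cds_end) + 1)
    ]
    codon = "CAA"
    for i, p in enumerate(cds):
        seq[p - 1] = codon[i % 3]
    return {model.chrom: "".join(seq)}


def _variant(model, pos, alt, ref_seq, genotype=Genotype.HET):
    return RawVariant(model.chrom, pos, ref_seq[model.chrom][pos - 1], alt, genotype)


class TestSnvClasses:
    def test_caa_to_taa_is_nonsense(self, simple_transcript):
        ref = _ref_for(simple_transcript)
        v = _variant(simple_transcript, simple_transcript.cds_start, "T", ref)
        assert transcript_effect(v, simple_transcript, ref) is EffectClass.NONSENSE

    def test_gaa_to_gca_is_missense(self):
        # Glu -> Ala, the classic pathogenic missense change
        gm = GeneModel("G", "t", "+", ((1, 12),), 1, 12, "c")
        ref = {"c": "GAAGAAGAAGAA"}
        v = RawVariant("c", 2, "A", "C", Genotype.HET)
        assert transcript_effect(v, gm, ref) is EffectClass.MISSENSE

    def test_synonymous_third_position(self):
        gm = GeneModel("G", "t", "+", ((1, 12),), 1, 12, "c")
        ref = {"c": "GAAGAAGAAGAA"}  # GAA (Glu) -> GAG (Glu)
        v = RawVariant("c", 3, "A", "G", Genotype.HET)
        assert transcript_effect(v, gm, ref) is EffectClass.SYNONYMOUS

    def test_minus_strand_nonsense(self):
        # genomic TTA on '-' strand reads TAA after reverse-complement... use
        # CAA codon on the transcript: genomic is TTG; mutate to create stop.
        gm = GeneModel("G", "t", "-", ((1, 12),), 1, 12, "c")
        # transcript (revcomp of genomic) should be CAA CAA CAA CAA
        ref = {"c": str(Seq("CAA" * 4).reverse_complement())}
        # transcript coding index 0 (the 'C' of the first codon) sits at
        # genomic position 12; C->T there gives TAA = stop
        v = RawVariant("c", 12, ref["c"][11], "A", Genotype.HET)
        assert transcript_effect(v, gm, ref) is EffectClass.NONSENSE


class TestIndelsAndRegions:
    @pytest.mark.parametrize(
        "ref_len,alt_len",
        [
            (2, 1),  # 1-bp deletion -> frameshift
            (4, 1),  # 3-bp deletion -> in-frame
            (1, 3),  # 2-bp insertion -> frameshift
            (1, 4),  # 3-bp insertion -> in-frame
        ],
    )
    def test_cds_indel_frame_rule(self, simple_transcript, ref_len, alt_len):
        ref = _ref_for(simple_transcript)
        pos = simple_transcript.cds_start + 3
        seq = ref[simple_transcript.chrom]
        ref_allele = seq[pos - 1 : pos - 1 + ref_len]
        alt_allele = seq[pos - 1] + "G" * (alt_len - 1)
        if ref_allele == alt_allele:
            alt_allele = alt_allele[:-1] + "C"
        v = RawVariant(simple_transcript.chrom, pos, ref_allele, alt_allele, Genotype.HET)
        got = transcript_effect(v, simple_transcript, ref)
        shift = abs(ref_len - alt_len)
        assert got is (EffectClass.FRAMESHIFT if shift % 3 else EffectClass.NON_FS_INDEL)

    def test_splice_site_window(self, simple_transcript):
        ref = _ref_for(simple_transcript)
        exon1_end = simple_transcript.exons[0][1]  # 40; intron 41..50
        for pos, expected in [
            (41, EffectClass.SPLICE_SITE),
            (42, EffectClass.SPLICE_SITE),
            (43, EffectClass.INTRONIC),
            (45, EffectClass.INTRONIC),
            (49, EffectClass.SPLICE_SITE),
            (50, EffectClass.SPLICE_SITE),
        ]:
            v = _variant(simple_transcript, pos, "G", ref)
            assert transcript_effect(v, simple_transcript, ref) is expected, pos

    def test_utr_and_outside_span(self, simple_transcript):
        ref = _ref_for(simple_transcript)
        v = _variant(simple_transcript, 12, "G", ref)  # exon1 before CDS start
        assert transcript_effect(v, simple_transcript, ref) is EffectClass.UTR
        v = _variant(simple_transcript, 79, "G", ref)  # exon2 after CDS end
        assert transcript_effect(v, simple_transcript, ref) is EffectClass.UTR
        v = _variant(simple_transcript, 5, "G", ref)
        assert transcript_effect(v, simple_transcript, ref) is None

    def test_noncoding_transcript(self):
        gm = GeneModel("NC", "t", "+", ((10, 30),), None, None, "c")
        ref = {"c": "A" * 40}
        v = RawVariant("c", 15, "A", "G", Genotype.HET)
        assert transcript_effect(v, gm, ref) is EffectClass.NONCODING_RNA


class TestClassify:
    def test_intergenic_when_no_gene_overlaps(self, simple_transcript):
        ref = _ref_for(simple_transcript)
        index = GeneModelIndex([simple_transcript])
        v = RawVariant("Z", 100, "A", "G", Genotype.HET)
        (ann,) = classify(v, index, ref)
        assert ann.effect is EffectClass.INTERGENIC
        assert ann.gene is None

    def test_multi_gene_overlap_annotates_each_gene(self, simple_transcript):
        other = GeneModel("TOY2", "TOY2.t1", "+", ((11, 80),), None, None, "T")
        ref = _ref_for(simple_transcript)
        index = GeneModelIndex([simple_transcript, other])
        v = _variant(simple_transcript, simple_transcript.cds_start, "T", ref)
        anns = classify(v, index, ref)
        assert {a.gene: a.effect for a in anns} == {
            "TOY1": EffectClass.NONSENSE,
            "TOY2": EffectClass.NONCODING_RNA,
        }

    def test_transcript_collapse_is_most_deleterious_and_order_free(self, simple_transcript):
        ref = _ref_for(simple_transcript)
        # second transcript of the same gene: the variant position falls in UTR
        alt_tx = GeneModel("TOY1", "TOY1.t2", "+", ((11, 80),), 60, 71, "T")
        pos = simple_transcript.cds_start
        v = _variant(simple_transcript, pos, "T", ref)
        for order in itertools.permutations([simple_transcript, alt_tx]):
            (ann,) = classify(v, GeneModelIndex(list(order)), ref)
            assert ann.effect is EffectClass.NONSENSE


def test_snv_classification_agrees_with_protein_translation_oracle(simple_transcript):
    """Every CDS SNV x every alt base, checked against full-protein translation."""
    ref = _ref_for(simple_transcript)
    seq = ref[simple_transcript.chrom]
    cds = [
        p
        for s, e in simple_transcript.exons
        for p in range(simple_transcript.cds_start, simple_transcript.cds_end + 1)
        if s <= p <= e
    ]
    coding = "".join(seq[p - 1] for p in cds)
    n_codons = len(coding) // 3
    ref_protein = str(Seq(coding[: n_codons * 3]).translate())
    checked = 0
    for i, pos in enumerate(cds[: n_codons * 3]):
        for alt in "ACGT":
            if alt == seq[pos - 1]:
                continue
            mutated = coding[:i] + alt + coding[i + 1 :]
            alt_protein = str(Seq(mutated[: n_codons * 3]).translate())
            if alt_protein == ref_protein:
                expected = EffectClass.SYNONYMOUS
            elif "*" in alt_protein and alt_protein.index("*") < len(ref_protein.rstrip("*")):
                expected = EffectClass.NONSENSE
            else:
                expected = EffectClass.MISSENSE
            v = RawVariant(simple_transcript.chrom, pos, seq[pos - 1], alt, Genotype.HET)
            assert transcript_effect(v, simple_transcript, ref) is expected, (pos, alt)
            checked += 1
    assert checked > 100


def test_severity_ordering_places_truncating_first():
    order = sorted(SEVERITY, key=SEVERITY.get)
    assert set(order[:2]) == {EffectClass.FRAMESHIFT, EffectClass.NONSENSE}
    assert SEVERITY[EffectClass.MISSENSE] < SEVERITY[EffectClass.SYNONYMOUS]
    assert SEVERITY[EffectClass.INTERGENIC] == max(SEVERITY.values())
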