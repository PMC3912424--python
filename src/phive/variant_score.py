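"""Per-variant and per-gene variant scores from rarity and predicted pathogenicity.

The variant score ranks highly variants that are both rare and predicted
deleterious: it is the product of a frequency factor (1 at MAF 0, decaying
linearly to 0 at 2%, 0 above) and a pathogenicity sub-score in [0, 1].

Pathogenicity: nonsense and frameshift variants receive a fixed, deliberately
conservative 0.95 (premature-truncation variants are not always pathogenic);
missense variants take the maximum of MutationTaster, PolyPhen-2 and the
transformed SIFT score s' = 1 - s, falling back to 0.6 when no predictor
reports; the remaining classes take fixed, configurable class scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .annotate import AnnotatedVariant, EffectClass
from .filters import InheritanceMode

#: MAF above which the frequency factor is exactly 0.
MAF_CUTOFF = 0.02

#: Fixed pathogenicity sub-score for premature-truncation classes.
TRUNCATING_SCORE = 0.95

#: Fallback for missense variants with no predictor output at all.
MISSENSE_DEFAULT = 0.6

#: Fixed per-class pathogenicity sub-scores. Only the 0.95 truncating value
#: is anchored; the others are conventional and overridable via YAML config.
DEFAULT_CLASS_SCORES: dict[EffectClass, float] = {
    EffectClass.NONSENSE: TRUNCATING_SCORE,
    EffectClass.FRAMESHIFT: TRUNCATING_SCORE,
    EffectClass.SPLICE_SITE: 0.90,
    EffectClass.NON_FS_INDEL: 0.85,
    EffectClass.SYNONYMOUS: 0.10,
    EffectClass.UTR: 0.0,
    EffectClass.INTRONIC: 0.0,
    EffectClass.NONCODING_RNA: 0.0,
    EffectClass.INTERGENIC: 0.0,
}


def load_class_scores(path: str | Path) -> dict[EffectClass, float]:
    """Load class-score overrides from a YAML mapping (CLASS_NAME: score)."""
    table = dict(DEFAULT_CLASS_SCORES)
    data = yaml.safe_load(Path(path).read_text()) or {}
    for name, score in data.items():
        cls = EffectClass[name]
        score = float(score)
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"class score for {name} outside [0, 1]: {score}")
        table[cls] = score
    return table


@dataclass(frozen=True)
class VariantScoreParts:
    """Decomposition of one variant's score: factor x pathogenicity."""

    frequency_factor: float
    pathogenicity: float

    @property
    def variant_score(self) -> float:
        return self.frequency_factor * self.pathogenicity


def frequency_factor(maf: float | None, exponent: float = 1.0) -> float:
    """Rarity factor in [0, 1] for a minor allele frequency.

    Linear decay from 1 at MAF 0 to 0 at 2%; 0 above 2%. Variants with no
    frequency data (``maf is None``) are treated as maximally rare (factor 1).
    ``exponent`` > 1 gives the more stringent variant of the curve, < 1 the
    more lenient one; the linear default is used throughout.
    """
    if maf is None:
        return 1.0
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"MAF must be in [0, 1], got {maf}")
    if maf >= MAF_CUTOFF:
        return 0.0
    return (1.0 - maf / MAF_CUTOFF) ** exponent


def pathogenicity_score(
    variant: AnnotatedVariant, table: dict[EffectClass, float] | None = None
) -> float:
    """Pathogenicity sub-score in [0, 1] for an annotated variant."""
    table = DEFAULT_CLASS_SCORES if table is None else table
    if variant.effect is not EffectClass.MISSENSE:
        return table[variant.effect]
    preds = variant.predictions
    if preds is None or not preds.has_any:
        return MISSENSE_DEFAULT
    candidates = []
    if preds.mutation_taster_raw is not None:
        candidates.append(preds.mutation_taster_raw)
    if preds.polyphen_raw is not None:
        candidates.append(preds.polyphen_raw)
    if preds.sift_raw is not None:
        candidates.append(1.0 - preds.sift_raw)  # SIFT: 0 = damaging
    return max(candidates)


def score_variant(
    variant: AnnotatedVariant,
    table: dict[EffectClass, float] | None = None,
    exponent: float = 1.0,
) -> VariantScoreParts:
    return VariantScoreParts(
        frequency_factor=frequency_factor(variant.max_maf, exponent=exponent),
        pathogenicity=pathogenicity_score(variant, table),
    )


def gene_variant_score(
    scores: Sequence[float] | Iterable[float],
    mode: InheritanceMode = InheritanceMode.NONE,
) -> float:
    """Aggregate per-variant scores of one gene into its variant score v.

    Dominant-style modes (NONE, AD, XR) take the best single variant. Under
    AR, both alleles of a compound heterozygote should contribute: with two
    or more qualifying variants, v is the mean of the two highest scores;
    with a single (homozygous) variant, its own score.
    """
    scores = sorted(scores, reverse=True)
    if not scores:
        raise ValueError("gene_variant_score requires >= 1 surviving variant")
    if mode is InheritanceMode.AR and len(scores) >= 2:
        return (scores[0] + scores[1]) / 2.0
    return scores[0]
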