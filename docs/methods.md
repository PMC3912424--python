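# Methods

## Overview

`phive` ranks candidate disease genes in a single exome by averaging a
variant-level score `v` with a cross-species phenotypic relevance score `r`:
`g = (v + r)/2`. The two halves are deliberately independent: `v` looks only
at the variants (population frequency, predicted deleteriousness, functional
class), `r` looks only at phenotypes (patient HPO profile vs mouse-model MPO
annotations). Candidates are every gene retaining at least one variant after
the filter cascade and the optional inheritance-model filter.

## Variant filtering

Variant-level filters are independent predicates (call quality, maximum
population MAF over all frequency sources, off-target effect classes,
synonymous class, and an optional pathogenicity cutoff), so the cascade's
survivor set does not depend on stage order; the per-stage report uses the
fixed order quality → frequency → off-target → synonymous → pathogenicity.
Variants absent from every frequency source are **kept**: for a rare-disease
tool, absence of frequency data is evidence of rarity, not commonness.

Inheritance filtering is a per-gene existence test over surviving variants:
AD needs ≥ 1 heterozygous variant (homozygous variants in the same gene do
not disqualify it); AR needs ≥ 1 homozygous or ≥ 2 heterozygous variants —
the compound-heterozygous test is unphased, so two variants on the same
haplotype cannot be distinguished from a true compound heterozygote; XR
needs a homozygous variant in a chromosome X gene (hemizygous male calls
present as homozygous).

## Variant score

Per-variant score = `frequency_factor × pathogenicity`, a conjunction: a
variant must be *both* rare and deleterious; the product preserves [0, 1]
and zeroes common variants.

- `frequency_factor(maf) = max(0, 1 − maf/0.02)^k` with `k = 1` by default.
  The factor is 1 at MAF 0, 0 at and above 2%, and `None` (no data) maps
  to 1. The exponent exposes stringent (`k > 1`) and lenient (`k < 1`)
  variants of the curve.
- Pathogenicity by effect class: nonsense and frameshift are fixed at
  **0.95** — deliberately below 1 because premature-truncation variants near
  a gene's 3′ end are often tolerated, and a ceiling of 1 would let the
  ~dozens of truncating calls in any normal exome drown out true causal
  missense variants. Missense takes
  `max(MutationTaster, PolyPhen-2, 1 − SIFT)` over whichever predictors
  report (SIFT's native scale is inverted: 0 = damaging), and **0.6** when
  none do. The remaining classes use fixed scores — splice-site 0.90,
  in-frame indel 0.85, synonymous 0.10, UTR/intronic/noncoding 0.0 — all
  overridable via a YAML table (`load_class_scores`); only the 0.95
  truncating value is treated as a calibrated constant.

Per-gene aggregation: dominant-style modes take the best single variant; AR
takes the mean of the two best variant scores when ≥ 2 variants survive
(both alleles of a compound heterozygote contribute), else the single
homozygous variant's score.

## Phenotypic relevance

The two ontologies are merged into one child→parent DAG. Cross-species
equivalences come from a precomputed **term-bridge table** — the product of
Entity–Quality logical-definition reasoning (e.g. human *craniosynostosis* ≡
mouse *premature closure of sutures*), supplied as an input file and treated
as bidirectional edges that ancestor closures may cross. A synthetic global
root joins the species roots so any cross-species pair has a common
(zero-information) ancestor.

Term specificity is Resnik information content over the mouse-model corpus:
`IC(t) = −ln(m_t / M)` where `m_t` counts models annotated to `t` or to any
term whose closure contains `t`, and `M` is the corpus size. Terms subsuming
no model receive the maximum observed IC (bounded, rather than infinite, so
one exotic term cannot dominate a profile). The corpus-side (MPO) root and
the global root always have IC 0; the human-side root's IC depends on how
much of the corpus reaches it through bridges and may be positive in
bridge-poor ontologies.

Pairwise term similarity is `sqrt(simJ × IC(MICA))`: the Jaccard overlap of
the two ancestor closures (terms included) weighted by the information of
the most informative common ancestor. A disease-vs-model score takes each
term's best match in the other set, in both directions, combines
`(mean + max)/2` over all best matches, and normalizes by the disease's
self-comparison statistic, clipped to 1. The symmetric two-directional form
was a design choice (a one-directional disease→model variant is equally
defensible); it makes the score symmetric under profile exchange and is the
form checked against the brute-force oracle in the tests.

A gene's relevance `r` is the maximum model score over all models of its
orthologous mouse genes (a mouse gene with several human orthologs
contributes its models to each; model-id ties break lexicographically).
Genes with no phenotyped model receive **default_r = 0.6**: high enough
that an unmodeled causal gene with a strong variant still competes
(g = (0.95 + 0.6)/2 ≈ 0.78), low enough that genuine phenotype matches
(r → 1) dominate. The default is exposed (`--default-relevance`) for the
coverage trade-off sweep below.

## Ranking

`g = (v + r)/2` exactly; ranking is ordinal: descending score, ties broken
by case-insensitive alphabetical gene symbol, unique ranks 1..N. This makes
every run reproducible and mirrors how a geneticist would work through an
equal-scoring shortlist anyway. Three score modes (combined, variant-only,
phenotype-only) rank the same candidate set by `g`, `v`, or `r`.

## Spike-in benchmark

Each simulated exome = one background exome + causal record(s) per the
disease's inheritance mode (one HET for AD; one HOM or two HET in one gene
for AR). The pipeline runs with the disease's phenotype profile and the
causal gene's rank is recorded per score mode. Metrics: top-1/top-10
percentages, pooled gene-level ROC AUC via the Mann–Whitney rank-sum
identity (positives = causal-gene scores across runs), the mean per-exome
AUC, and precision-recall points. The negative control re-runs each exome
with a uniformly drawn *different* disease.

`model_coverage` reproduces the phenotype-coverage experiment: in a
`1 − coverage` fraction of runs the causal gene's models are masked at
relevance lookup (falling back to `default_r`), background genes keep
theirs. Corpus IC is not recomputed under masking — the corpus itself is
considered fixed, only the gene↔model link is missing. Because sweep runs
are paired by seed, per-run ranks are structurally monotone in `default_r`
at both coverage extremes, which is exactly the trade-off the sweep is meant
to exhibit: a higher default helps when the causal gene is unmodeled and
never helps when it is perfectly modeled.

The benchmark driver works on in-memory variant lists and caches background
annotation per exome id (annotation is pure per-variant); `spike_in()`
writes real VCFs for file-level use and is tested for that contract
separately. Benchmark problem sizes are 500 runs over 12 background exomes
of 160 variants against 40 genes — small enough to iterate on a laptop,
large enough that top-1 differences of a few percent are resolvable.

## Synthetic toy world

The generator emulates the *statistical structure* of the real inputs, not
their content:

- **Genome/genes**: 40 three-exon genes (90 bp exons, 30 bp introns, short
  UTR margins) on chromosomes 1–3 and X, alternating strands, over a random
  reference. CDS lengths are trimmed to full codons.
- **Ontologies**: layered random DAGs (~60 terms per species, depth 4,
  geometric level sizes, 1–2 parents per term). Model term usage is
  Zipf-skewed, which spreads IC over a wide range like real annotation
  corpora. Realized depth/branching are approximate, not exact.
- **Corpus**: 60% of genes get a mouse ortholog; 80 models with 2–5 MPO
  terms. Each of 12 diseases designates a causal gene whose "matching
  model" terms are drawn from the rarely-used pool, and the disease's HPO
  profile is the bridged image of those terms — at `sharpness = 1` that
  model scores exactly 1 against the disease, the unique perfect match.
  Lower sharpness dilutes the profile with unrelated HPO terms.
- **Variants**: a pool of ~3× the per-exome count, 70% coding; 35% common
  (MAF 3–50%), the rest rare (10⁻⁴–10⁻²), 10% absent from the frequency
  table entirely; predictor values Beta-skewed toward benign with a
  pathogenic tail; two frequency sources with jitter. Causal variants are
  novel, coding (missense with strong predictions, or nonsense), placed by
  scanning the CDS for a position/allele with the desired codon effect.

What the toy world does **not** emulate: realistic allele-frequency spectra,
linkage structure, real HPO/MPO topology and annotation depth, sequencing
artifacts, or population stratification. Passing benchmarks here demonstrate
that the machinery is correct and that the score behaves directionally as
designed — not that real-data performance figures would be reproduced; those
depend on proprietary variant databases and the full mouse-phenotype corpus.
With every causal gene given a uniquely matching model, the synthetic
benchmark is an easier task than real prioritization, which is why its top-1
rates approach 100%.

The generator's corpus always contains at least one modeled gene (profiles
are built from models), so a zero-coverage world is expressed through the
benchmark's `model_coverage=0` masking rather than an empty corpus.

## Numerical and degenerate-input choices

- Coordinates are VCF 1-based everywhere; exon intervals 1-based inclusive.
- Multi-allelic records are decomposed per ALT allele before anything else;
  indels are **not** left-normalized (a variant and its shifted equivalent
  would not match the same table keys — a known limitation).
- Missing genotypes are dropped at read time, counted, and logged.
- Splice window: 2 bp into the intron (canonical donor/acceptor).
- A variant overlapping several genes yields one annotation per gene, each
  collapsed to the most deleterious transcript-level class
  (frameshift = nonsense > splice > missense > in-frame indel > synonymous >
  UTR > intronic/noncoding > intergenic). Stop-loss is binned as missense.
- A trailing partial codon in a toy transcript classifies as synonymous.
- `model_score` of an empty term set is 0; a disease whose self-comparison
  statistic is 0 scores 0 against everything.
- ROC AUC with no positives or no negatives is NaN and excluded from
  per-exome averaging.

## Known limitations

- The effect classifier is a minimal exon-model annotator: no HGVS, no
  UTR-regulatory or deep-intronic effects, one class per gene per variant.
- No phasing; AR compound-heterozygote detection can be fooled by two
  variants in cis.
- The bridge table stands in for ontology logical-definition reasoning;
  bridge quality directly bounds cross-species score quality.
- Frequency-factor shape between 0 and 2% is linear by choice; only the
  endpoints are anchored.
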