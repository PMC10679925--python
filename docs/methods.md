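# Methods

`triovar` reimplements, as a reusable library, the rare-variant
prioritization strategy used in whole-genome studies of common variable
immunodeficiency (CVID) cohorts composed of affected probands, their healthy
first-degree relatives (trios), and unrelated sporadic cases. The package
covers everything downstream of variant calling and annotation: site QC,
rarity/deleteriousness filtering, Mendelian segregation screening,
gene-panel intersection, ACMG-style tiering, CNV/SV co-occurrence
clustering, gene-set over-representation, and cohort-level reporting. It
consumes ANNOVAR-style annotated multi-sample VCFs; it does not call,
align, or annotate.

## Filtering cascade

Each variant × affected-sample pair passes through six ordered stages. All
inequalities are strict, matching the protocol's printed bounds:

| stage | rule | default |
|---|---|---|
| site_qc | per-sample depth > `min_depth`; site RMS MQ > `min_mq`; QUAL > `min_qual` | 4 / 30 / 20 |
| region | exonic, or splicing within `splice_window_bp` of the junction (inclusive) | 10 bp |
| synonymous | synonymous SNVs discarded unless either dbscSNV score ≥ `dbscsnv_splice_cutoff` | 0.6 |
| repeat_indel | non-frameshift indels < `indel_repeat_max_len` bp inside RepeatMasker repeats discarded | 10 bp |
| frequency | every configured database AF ABSENT or < `max_af` | 0.01 |
| deleteriousness | see below | — |

The splice window is inclusive (≤ 10) because retained clinical candidates
include a +10 duplication; ABSENT allele frequencies (unobserved in a
database) always pass the rarity screen and are never conflated with 0.0.
The dbscSNV cutoff of 0.6 is that tool's published operating point. The
first failing stage short-circuits the trace, but every stage is a pure
predicate of the variant, so the final verdict equals the conjunction of
independently evaluated stages (tested).

### Deleteriousness: majority vote vs. retention

Four voters are tallied: SIFT (D supports), PolyPhen-2 (HVAR and HDIV
merged into one vote, supporting if either is D or P — keeping exactly four
voters), MutationTaster (D or A), and CADD (phred ≥
`cadd_deleterious_cutoff`, default 20). An absent voter never supports. The
**majority verdict** — more than half, i.e. ≥ 3 of 4 — is always computed,
recorded in the filter trace, and is what "predicted deleterious" means
downstream (it drives ACMG PP3).

**Retention** by the cascade is deliberately weaker. The predictors only
score missense changes, so non-missense consequences (stopgain, frameshift,
splice-region, in-frame indels) are retained on consequence class. For
missense variants the shipped default retains any variant with at least
`retain_min_votes` = 1 supporting vote. Retention and majority are separate
knobs because clinically reported candidate sets from this study design
demonstrably include missense variants with only a single supporting tool
(e.g. verdicts `T|B|B|D` with CADD ≈ 12): a strict 3-of-4 gate would
discard them, while a one-vote retention floor still removes the
uniformly-benign background. Setting `retain_min_votes = 3` restores the
strict majority gate. Variants with a loss-of-function consequence and no
predictor output at all bypass the vote rather than being penalized for
unscored tools.

## Segregation models

Per affected proband, against the pedigree:

* **de novo** — proband carries the allele; both parents genotyped hom-ref
  with depth above the site-QC bound (parental dropout must not masquerade
  as mutation). On the male X only the mother's genotype is informative.
* **homozygous recessive** — proband hom-alt, each genotyped parent carries
  ≥ 1 copy. A hom-alt proband with a genotyped hom-ref parent is a
  Mendelian inconsistency and is reported `possible_denovo_or_error`,
  never as recessive.
* **X-linked recessive** — hemizygous alt in an affected male with a
  carrier mother; displayed "hom" in reports, following clinical-table
  convention.
* **inherited het** — transmitted by an observed carrier parent; a het
  allele whose only genotyped parent is hom-ref (other parent missing) is
  not callable, since transmission and de novo origin cannot be separated.
* **compound het** — pairs of proband-het variants in one gene phased by
  parental origin; trans requires one paternal-only and one maternal-only
  variant. Unphasable pairs (a parent carries both, or genotypes missing)
  are emitted flagged `possible_cis` rather than silently dropped.
* **sporadic-only** — for singleton cases, the allele is present in the
  case and in no other cohort sample. A missing control genotype counts as
  "not detected" (absence of data is not presence) but flags the call.
* **oligogenic profile** — ≥ 2 heterozygous candidate loci across ≥ 2
  genes, each de novo or inherited from an unaffected parent. The
  definition is structural; no joint statistical model is implied.
  Homozygous/hemizygous models are monogenic explanations and are excluded.

## ACMG-lite classification

Eleven evidence codes are implemented — PVS1, PS2, PM2, PM3, PP1, PP2,
PP3, PP4, BA1, BS1, BP4 — exactly those derivable from the pipeline's own
annotations and segregation calls; codes requiring literature curation are
out of scope. Triggers:

* **PVS1** stopgain, frameshift, or canonical ±2 splice;
* **PS2** confirmed de novo **and** phenotype-consistent gene (on the
  PID/CVID panel or carrying the phenotype-match flag) — the consistency
  gate reflects the code's "patient with the disease" clause and prevents a
  de novo hit in an unrelated gene from reaching Likely Pathogenic;
* **PM2** absent from every configured population database;
* **PM3** phased trans compound het in a recessive gene;
* **PP1** segregation consistent with a recessive/X-linked model through
  genotyped unaffected carrier parents. This is a deliberately relaxed,
  model-consistency reading of co-segregation: in small nuclear families a
  single informative transmission (e.g. an unaffected carrier mother and an
  affected hemizygous son) is counted;
* **PP2** missense in a configured missense-constrained gene (default list:
  `CD40LG`);
* **PP3** the ≥ 3-of-4 deleteriousness majority;
* **PP4** clinician-asserted gene-specific phenotype flag in the sample
  metadata;
* **BA1/BS1** any database AF ≥ 5% / ≥ 1%;
* **BP4** zero supporting votes with ≥ 3 explicitly benign signals.

Combination follows the standard five-tier table (Pathogenic requires e.g.
PVS1 + ≥ 1 Strong; Likely Pathogenic 1 Strong + 1–2 Moderate, ≥ 3
Moderate, 2 Moderate + ≥ 2 Supporting, or 1 Moderate + ≥ 4 Supporting;
default VUS; benign branches through BA1/BS1/BP4). Contradictory pathogenic
and benign evidence yields VUS with a conflict flag. The combiner is a pure
function and executes the full 2^11 profile space in tests.

On the packaged published-cohort fixture this mapping reproduces the
printed tiers exactly: two Pathogenic loci (a de novo stopgain and a de
novo canonical splice variant, both PVS1+PS2+PM2), one Likely Pathogenic
X-linked missense (PM2 + PP1 + PP2 + PP3 + PP4), and VUS everywhere else.
The mapping reproduces the published classes but is not claimed to be the
original analysts' reasoning, which is unpublished.

## CNV/SV co-occurrence

Two events of the same chromosome, type, and source are "the same" when
their reciprocal overlap strictly exceeds 50 %:
min(overlap/len(a), overlap/len(b)) > 0.5 on 0-based half-open intervals
(exactly 50 % is *not* the same event). Clusters are single-linkage
connected components of this pairwise relation — a cluster may therefore
contain pairs below the bound via chaining; a strict `clique` mode is
available. The representative interval is the median of member starts and
ends. The recurrence screen keeps clusters carried by ≥ 2 distinct affected
samples and by zero unaffected samples, cohort-wide; CNVs and SVs are
screened as parallel analyses and never merged across source. Exon overlap
labelling uses a ≥ 1 bp intersection of the representative interval.

## Gene-set over-representation

Upper-tail hypergeometric test per gene set (`scipy.stats.hypergeom.sf`)
against a configurable background universe (default 20,000 protein-coding
genes), Benjamini–Hochberg adjusted across sets. Zero-overlap sets report
p = 1 rather than being dropped. No live pathway-database queries are
performed; users supply GMT files. The packaged GMT is a small synthetic
stand-in assembled for tests and examples (marked synthetic in its
filename), not a pathway-database export.

## Synthetic cohort generator

`simulate_cohort` emulates the study design: 12 trio families and 4
sporadic singletons (16 patients), 5,000 autosomal background sites, mean
depth 34×, a log-uniform true-AF spectrum over [1e-6, 0.5] (rarity
dominated), database AFs that are lognormally perturbed copies of the true
AF or ABSENT with probability 0.15, and a latent deleterious state
(prevalence 0.10) under which each predictor votes supporting with
probability 0.85 (0.05 when benign). Parents are drawn at Hardy–Weinberg
proportions; children by Mendelian transmission; an optional genotyping
error rate re-draws a sample's genotype uniformly. Causal variants are
spiked per inheritance model with annotations forced past the cascade
(absent everywhere, 4/4 vote, CADD 35), and the ground truth is written
beside the VCF. Genes are synthetic labels mapped to coordinate windows;
the X chromosome carries only the X-linked spikes.

What the generator does **not** emulate — linkage disequilibrium,
recombination, population structure, realistic gene lengths, sequencing
read-level artifacts, annotation disagreement between databases —
circumscribes what passing tests show: they validate the screening logic
(recall 1.0 on spiked models with zero Mendelian-inconsistent calls at
error rate 0, and a de novo false-positive rate that grows with the error
rate), not performance on real WGS data.

## Numerical and formatting choices

* Deterministic ordering everywhere: karyotype chromosome order, then
  position, ref, alt.
* VCF QUAL and typed Float INFO fields are 32-bit in htslib, so the
  simulator emits integer-valued QUAL/MQ and rounds string-typed annotation
  floats to text-stable precision; VCF round trips are byte-exact and
  field-exact (tested).
* ANNOVAR INFO keys that are illegal VCF identifiers are sanitized in the
  default dialect (`g1000_2015aug_all`, `GERP_RS`); any spelling can be
  mapped back via the YAML dialect config.
* Per-allele INFO values: a comma-separated list with exactly one entry per
  alternate allele is split per allele; anything else applies to all.
* Test problem sizes (1,000-site oracle cohorts, 50-interval clustering
  oracles, 2,000-site error-rate trend) were chosen as the smallest scales
  at which the checked properties are non-trivial.

## Known limitations

* Site QC is per-sample with a per-site summary in traces; whether the
  original analysis applied it per-site is unknown.
* The published table's per-site QC values, coordinates, and four-database
  AF breakdown are not printed; the packaged fixture synthesizes passing
  QC, synthetic positions, and carries the two printed AF columns.
* PP1's single-transmission reading and PS2's panel gate are documented
  design choices, not published analyst decisions.
* No statistical phasing, imprinting, mosaicism, kinship verification, or
  CNV/SV breakpoint refinement.
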