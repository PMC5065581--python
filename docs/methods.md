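# Methods

## Data model and normalization

All coordinates are 1-based, following VCF. Before any filtering,
multiallelic sites are split into one record per alternate allele — a
sample's allele index equal to the record's own alt maps to 1; reference
*and other alt* alleles map to 0, so a sample heterozygous for a different
alt does not count as carrying this record — and allele pairs are trimmed
to minimal representation (shared suffix, then shared prefix, advancing the
position). Full left-alignment through repeat tracts requires a reference
genome, which is deliberately out of scope (the pipeline consumes
pre-annotated VCFs and never re-annotates); minimal representation is
sufficient to give the set-subtraction filters a canonical
`(chrom, pos, ref, alt)` key as long as all inputs pass through the same
reader, which they do.

Annotation is consumed, not computed: gene symbol, consequence term,
population allele frequencies, the four predictor calls (discretized
P/B/NA) and the 0–1000 conservation score are read from INFO keys named by
an `AnnotationConfig`, so VEP- or ANNOVAR-style dialects map onto the same
model. No-calls (any missing allele) never count as carrying a variant:
subtraction stages therefore cannot remove a child variant on the strength
of a missing parental genotype; confidence in the *parental reference*
calls is enforced later by the de novo quality gates instead.

Variant classes are restricted to {SNV, insertion, deletion}; equal-length
multi-nucleotide substitutions are rejected at construction because the
cohorts this models contain only SNVs and simple indels, and silently
misclassifying an MNV as one of the three would corrupt the class tallies.

Allele frequencies are canonicalized to six significant digits on both
read and write, so that writing the normalized record set and re-reading it
(through htslib's float32 INFO storage) reproduces the records
field-by-field — the round-trip invariant the test suite asserts.

## The filter cascade

Stage order follows the narrative order of a trio study: functional
impact, population frequency, parental subtraction, pooled controls. Each
stage is a pure predicate or set subtraction, so the *final* candidate set
is order-invariant (asserted by permutation tests); only the intermediate
counts in the `CascadeReport` depend on the order.

Decisions worth stating explicitly:

- The frequency boundary is **inclusive** at the threshold (default 1%):
  a variant at exactly 1% is a polymorphism and is removed. Variants
  absent from every source are retained.
- "Present in parent/control" means any called genotype with ≥ 1 alternate
  allele, *regardless of quality*. Subtraction is deliberately aggressive
  and confirmation conservative: a marginal parental het should still
  veto a de novo claim at the subtraction stage.
- The pooled-control panel is all parents in the cohort, the proband's own
  included — harmless duplication after the parental stage, and it keeps
  the panel definition independent of the family under analysis.
- The qualifying-consequence default (missense, stop gained/lost, start
  lost, frameshift, in-frame indel, canonical splice donor/acceptor) is
  the standard reading of "non-synonymous with functional impact" and is
  configurable; records with *absent* consequence are dropped, since an
  unannotated variant cannot be claimed protein-altering.

## De novo calling

A candidate passes iff the trio genotypes are definitional (child 0/1,
both parents 0/0) and all gates hold: depth ≥ `min_depth` (default 10) in
all three members, GQ ≥ `min_genotype_quality` (default 20) in all three,
and child alternate-allele balance within `child_ab_range` (default
[0.25, 0.75]). The defaults are common trio-sequencing practice; the
underlying study reports that quality selection was applied but not its
numbers, so these are package defaults, config-exposed. Checks run in a
fixed order and the first violation becomes the recorded fail reason;
anomalies (missing member, no-call) are fail reasons, never exceptions, so
every examined variant leaves an auditable row. Indels are eligible
alongside SNVs.

All probands in the modeled cohorts are girls; children are treated as
diploid on X, and nothing in the pipeline is X-aware beyond that (no
X-inactivation or hemizygosity modeling — a documented non-goal).

## Recessive mode

Runs only for families with ≥ 2 affected children, on the rare,
impact-qualifying record set *before* parental subtraction — inherited
variants are the whole point, and the parental filter removes them by
construction. Homozygous-recessive candidates require every affected child
1/1 and both parents 0/1 (a 1/1 parent would be an affected carrier and is
not accepted). Compound-het candidate genes need ≥ 2 heterozygous variants
shared by all affected children; per variant the parental origin is read
off the parents' carrier states (father-only / mother-only / both), and the
gene is reported `trans_confirmed` when a paternal-only and a maternal-only
variant coexist, rejected when all variants are attributable to a single
parent (cis), and `phase_ambiguous` when both-parent carriers leave a trans
pair possible but unproven — flagged for manual review rather than
silently kept or dropped. Variants carried by neither parent are not
inherited and do not count toward the pair. The decision table over all
two-variant origin configurations is enumerated in the tests.

## Prioritization

Evidence is a ranking signal, never a hard gate — real cohorts report
all-benign, conservation-0 candidates among their final hits, so filtering
on predictor consensus would be wrong. The order is: pathogenic-support
count (P calls among non-NA predictors) descending, conservation
descending with absent treated as 0 (the least-informative default,
matching printed 0 values for real candidates), novel-before-known on the
frequency-novelty flag, then chromosome/position/allele tie-breaks for
determinism. Raw predictor scores are not recomputed (running
SIFT/PolyPhen2/PROVEAN/MutationTaster2/PhastCons is out of scope); only the
P/B/NA discretization is consumed. The bundled known-NDD gene map carries
the five disorder associations relevant to Rett-overlapping phenotypes and
is extensible from a user TSV; an unmapped gene classifies as `novel`.

## Pineda clinical severity scale

Nine ordinal features, summed; totals range 3–22 because three features
(onset, sitting, stereotypies) have minimum 1. Age is metadata, never
scored. Input CSVs are strictly validated — a missing feature column or an
out-of-range value is an error naming the feature; nothing is imputed.
Cohort summaries report derived binary traits (microcephaly present,
epilepsy present, never walked = ambulation 4, language never acquired,
breathing dysfunction, stereotypies present) as count, denominator and a
percentage rounded to one decimal, the reporting convention used
throughout the package.

The bundled `clinical_profiles.csv` holds the eleven probands of the
motivating cohort whose printed feature rows parse unambiguously and whose
digit-sums match their printed totals; rows with typographically ambiguous
or inconsistent printing were excluded rather than "corrected".

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 5 families (the last with two affected sisters),
10,000 background sites per cohort, 30% common sites (AF uniform on
[0.05, 0.5]), rare sites Beta(0.3, 60) clipped to [1e-4, 0.0099] with a
25% point mass of novel sites (absent from all frequency sources,
segregating at 0.002), background consequences 60% intronic / 35%
synonymous / 5% missense (so the functional-impact stage does real work at
roughly the scale real exomes show), 2% simple indels, 2 planted de novos
per child, 2 control-shared variants, genotyping error rate 0. The
10,000-site panel is a desk-scale stand-in for the hundreds of thousands
of raw variants of a real exome cohort; per-family dispersion is not
separately modeled because only cohort averages are available to target.

Parental genotypes are drawn per site under Hardy–Weinberg from the site
AF; children inherit one allele from each parent by fair Mendelian
transmission (no linkage disequilibrium between sites — a non-goal).
Planted de novos are child-het / parents-hom-ref at family-private
coordinates; control-shared variants are het in one child and in parents
of two *other* families, so they survive the parental stage and fall at
the pooled-control stage; the multiplex family gets one
homozygous-recessive site (parents het, both sisters 1/1) and a
compound-het gene pair with opposite parental origins. Genotyping errors
perturb calls one step in alt-allele count (0/0↔0/1, 0/1↔1/1) with the
configured probability; flips that create an apparent de novo are recorded
as `error_artifact` truth rows.

Quality fields for planted candidates are drawn from the passing region of
the default gates (DP 30–79, GQ 99, allele balance 0.35–0.65), so recovery
on an error-free cohort is exactly 100% with zero false positives — the
calibration the validation suite asserts. Borderline-quality calls for
gate-sensitivity testing come from a separate `borderline_fraction` knob,
not from loosening the planted events.

Randomness discipline: one master seed, hierarchical `SeedSequence`
substreams keyed by purpose (site panel / control plantings / per-family
genotypes / per-family emission). Same config ⇒ byte-identical VCF, PED
and truth table; changing one family's plantings leaves every other
family's columns byte-identical. The cost of that locality is that a
family's samples receive constant "solid reference" quality fields
(DP 50, GQ 99) at sites planted for other families.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level artifacts (strand bias, mapping
error), linkage disequilibrium, indel-alignment ambiguity in repeat
tracts, population stratification between families, mosaicism, and
X-specific inheritance. The exactness of synthetic recovery is a check of
the pipeline's logic, not a sensitivity estimate for real exomes.

## Numerical and degenerate-input choices

Percentages round half-even to one decimal via Python's `round`. An empty
pedigree or an empty clinical cohort refuses to run; an empty pooled
control panel degrades to an identity filter with a warning; an empty
record set flows through the cascade as all-zero counts. Truth-table rows
use `*` for cohort-wide site-class labels. VCF parse failures cite the
first structurally malformed data line (located by a cheap re-scan, since
the underlying htslib reader does not report line numbers). Seeds are kept
below 2^31.

## Known limitations

- No read-backed phasing: compound-het trans confirmation relies purely on
  parental genotypes, so double-het parents always yield
  `phase_ambiguous`.
- The cascade's intermediate counts (not its final set) depend on stage
  order; the default order is fixed and documented rather than inferred.
- Recessive candidates are not phenotype-filtered; everything segregating
  is reported for manual review.
- The simulator's per-call error model is independent across calls and
  sites, which understates the clustered errors real callers produce.
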