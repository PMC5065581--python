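# rettlike

Trio-exome variant prioritization for Rett-like cohorts: the variant
reduction cascade, quality-gated de novo calling, recessive-mode analysis
for multiplex families, candidate ranking by predictor consensus and
conservation, and the Pineda clinical severity scale — plus a synthetic
trio-cohort simulator so every stage can be exercised and validated at desk
scale without any sequence download.

## Who this is for

Rett syndrome (RTT) is a progressive neurodevelopmental disorder of early
childhood, mostly affecting girls. A substantial fraction of patients who
meet the clinical criteria carry no mutation in the usual genes (*MECP2*,
*CDKL5*, *FOXG1*); family-based whole-exome sequencing of such "RTT-like"
parent–child trios is the standard route to a molecular diagnosis, by
hunting for de novo coding variants — alleles present in the affected child
but in neither parent — and, in families with more than one affected child,
for recessive configurations. This package re-implements that analysis as a
tested, reusable library for anyone building or auditing a trio
prioritization workflow.

## The method

Starting from an annotated multi-sample VCF and a PED pedigree, each
family's variants pass through four filters:

1. **functional impact** — keep consequences that alter the protein or
   canonical splice sites (missense, nonsense, frameshift, …);
2. **population frequency** — remove variants with allele frequency ≥ 1%
   (the classic polymorphism definition, boundary inclusive) in *any*
   configured source (dbSNP, 1000 Genomes, ExAC); variants absent from all
   sources are retained as novel;
3. **parental subtraction** — remove variants carried by either of the
   proband's own parents;
4. **pooled controls** — remove variants carried by any healthy parent
   across the whole cohort.

Survivors become de novo candidates if the trio genotypes are definitional
(child 0/1, parents 0/0) and pass quality gates (depth ≥ 10 in all three
members, GQ ≥ 20, child allele balance in [0.25, 0.75]; all configurable).
For families with ≥ 2 affected children, the recessive mode runs on the
rare, impact-qualifying set *before* parental subtraction and reports
homozygous-recessive sites (children 1/1, parents 0/1) and compound
heterozygous genes (≥ 2 shared het variants with at least one inherited
from each parent; cis configurations rejected, unresolvable ones flagged
`phase_ambiguous`).

Candidates are ranked — never filtered — by the number of
likely-pathogenic calls among four predictors (SIFT, PolyPhen2, PROVEAN,
MutationTaster2), then cross-species conservation (0–1000), then novelty,
with deterministic coordinate tie-breaks, and are annotated against a
bundled map of genes already associated with neurodevelopmental disorders.

On the clinical side, the Pineda severity scale scores nine features
(onset, microcephaly, sitting, ambulation, respiration, epilepsy, hand use,
stereotypies, language), each on its own small ordinal range; the total is
their plain sum (3–22), and cohort summaries report trait prevalences with
one-decimal percentages.

## Worked example

Simulate a five-family cohort (the fifth family has two affected sisters
carrying planted recessive candidates) and run the whole pipeline:

```sh
$ rettlike simulate --seed 7 --families 5 --sites 10000 --out demo
wrote demo/cohort.vcf, demo/cohort.ped, demo/truth.tsv
  common_polymorphism: 2978
  compound_het_planted: 2
  control_shared: 2
  de_novo_planted: 12
  hom_recessive_planted: 1
  rare_inherited: 7022

$ rettlike all --vcf demo/cohort.vcf --ped demo/cohort.ped --out demo/run --seed 7
{
  "n_families": 5,
  "n_probands": 6,
  "probands_with_candidates": 6,
  "candidate_variants": 12
}
```

Every proband ends with exactly its planted de novo variants — the cascade
report (`demo/run/cascade_report.tsv`) shows the per-stage shrinkage, e.g.
family 1: 1399 carried variants → 66 after the functional-impact stage → 4
after the frequency filter → 3 after parental subtraction → 2 candidates
after the pooled-control stage (the planted pair). The multiplex family's
`recessive_candidates.tsv` contains the planted homozygous-recessive site
and the compound-het gene with `trans_confirmed` phase support.

Scoring the bundled clinical table prints each proband's severity total and
the cohort prevalences:

```sh
$ rettlike clinic --csv src/rettlike/data/clinical_profiles.csv
proband 8: total severity 18
proband 10: total severity 14
...
        trait  count  denominator  percent
 microcephaly     10           11     90.9
     epilepsy      7           11     63.6
...
```

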