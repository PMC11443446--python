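# cleftsift

Pedigree-aware rare-variant prioritization for multiplex families with
nonsyndromic orofacial cleft (NSOFC) — and, with a different gene list, for
any Mendelian phenotype studied through whole-exome sequencing of families
with two or more affected members.

Given an annotated multi-sample VCF per family, a PLINK pedigree file, and a
cohort configuration naming each family's inheritance model, `cleftsift`
applies a four-stage conjunctive filtering cascade:

1. **Rarity (model-aware).** Exclude variants whose population minor allele
   frequency (MAF) is *strictly above* 0.5% for autosomal-dominant (AD)
   families or 5% for autosomal-recessive (AR) families. Variants absent
   from population databases pass (novel variants are of interest).
2. **Consequence.** Keep protein-altering and splicing consequences
   (missense, nonsense, start-loss, in-frame/frameshift insertions and
   deletions, splice donor/acceptor/region).
3. **Mendelian segregation.** AD: every genotyped affected member is
   heterozygous and every genotyped unaffected member is homozygous
   reference. AR: every genotyped affected member is homozygous for the
   alternate allele, every obligate carrier (unaffected parent of an
   affected member) is heterozygous, and no genotyped unaffected member is
   homozygous alternate.
4. **Phenotype relevance.** Keep genes on a curated orofacial-cleft /
   craniofacial-development list (shipped as editable data).

Survivors receive an ACMG-style five-tier classification (Pathogenic /
Likely pathogenic / VUS / Likely benign / Benign) built from
annotation-derivable evidence codes — PVS1, PM2, PP1, PP3, BA1, BS1, BP4 —
combined by the published rule table, which ships as a YAML fixture. A
reporting layer aggregates per-family pathogenic/likely-pathogenic (P/LP)
hits into cohort-level per-gene and per-pathway family percentages.

Because real family WES data cannot be redistributed, the package includes a
seeded gene-dropping simulator: founder genotypes drawn from Hardy–Weinberg
equilibrium (hom-alt `maf²`, het `2·maf·(1−maf)`), child alleles drawn
uniformly from each parent's pair, a planted causal variant whose genotype
configuration satisfies the family's model by construction, and background
variants spanning both sides of every filter boundary. Pedigree templates
include a four-generation AR family with two affected second cousins whose
unaffected parents are obligate heterozygous carriers.

## Worked example

Simulate a four-generation AR family with a planted nonsense variant among
500 background variants, then run the cascade and classification:

```bash
cat > sim.yaml <<EOF
seed: 11
template: four_gen_ar
n_background_variants: 500
family_id: FAM30
planted_consequence: stop_gained
EOF
cleftsift simulate --config sim.yaml --out sim

cat > cohort.yaml <<EOF
families:
  FAM30: AR
lof_mechanism_genes: [ECPAS]
EOF
cleftsift classify --vcf sim/FAM30.vcf --ped sim/FAM30.ped \
    --config cohort.yaml --out out
```

which prints `FAM30: 1 candidate(s), 1 P/LP` and writes:

```
# out/FAM30.trace.tsv — per-stage attrition
family_id  input  after_maf  after_consequence  after_segregation  after_relevance
FAM30      501    364        240                1                  1

# out/FAM30.candidates.tsv
family_id  chrom  pos       ref  alt  gene   consequence  maf    ...  evidence          verdict
FAM30      9      99000000  C    G    ECPAS  stop_gained  0.001  ...  PM2,PP1,PP3,PVS1  Pathogenic
```

Reading the trace: of 501 variants, 364 were rare enough for the AR 5%
threshold, 240 of those were protein-altering or splicing, exactly one
co-segregated (both affected second cousins homozygous, all four parents
heterozygous), and that one lies in a relevance-list gene — the planted
variant. Its evidence: null variant in a loss-of-function-mechanism gene
(PVS1), rare (PM2), co-segregation across enough informative meioses (PP1),
damaging in-silico consensus (PP3) → Pathogenic. Had the planted variant
been a missense change instead, it would carry {PM2, PP1, PP3} and remain a
VUS — the combining rules are deliberately conservative.

`cleftsift report --candidates out/FAM30.candidates.tsv --total-families 1
--out rep` then aggregates classified tables into cohort percentages;
`cleftsift run-all` does family runs plus the report in one step; the same
operations are available as library functions
(`cleftsift.pipeline.run_family` / `run_cohort`).

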