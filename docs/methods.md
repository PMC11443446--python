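# Methods

## The analysis model

`cleftsift` operationalizes the standard family-based rare-variant
prioritization used for nonsyndromic orofacial cleft (NSOFC) and similar
congenital phenotypes: in a multiplex family (≥2 affected members) with a
declared autosomal single-gene inheritance model, a causal variant is
expected to be rare in the population, protein-altering or splice-disrupting,
co-segregating with affection status under that model, and located in a gene
plausibly related to the phenotype. The four filters are conjunctive, so the
candidate set shrinks monotonically; the fixed stage order
(rarity → consequence → segregation → relevance) only defines how attrition
is attributed in the trace, not the final set.

Assumptions inherited from this design, and therefore from every result the
package produces:

* **Full penetrance, no phenocopies.** The segregation rules are exact
  genotype constraints. A single non-penetrant carrier (AD) or phenocopy
  vetoes a true causal variant. The simulator's `penetrance` knob exists to
  demonstrate this failure mode, not to model any particular cohort.
* **Single causal variant per family, autosomal.** Compound heterozygotes,
  X-linked and mitochondrial models are out of scope. Non-autosomal records
  are excluded before the cascade (`autosomes_only`, on by default).
* **Per-site independence.** Variants are filtered independently; no linkage
  or haplotype information is used.

## Filter parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `maf_threshold_ad` | 0.005 | allele fraction | AD causal alleles for a rare congenital malformation must be very rare; 0.5% is the conventional cutoff |
| `maf_threshold_ar` | 0.05 | allele fraction | carriers of recessive alleles can be relatively common; 5% cutoff |
| MAF comparison | strict `>` excludes | — | "commoner than the threshold" reading; boundary values (exactly 0.5%/5%) are retained |
| missing MAF | passes | — | variants absent from population databases are treated as rare; novel variants are precisely the discovery target. Overridable (`missing_maf_is_rare=False`) |
| consequence whitelist | missense, stop-gained, start-lost, in-frame/frameshift ins/del, splice donor/acceptor/region | SO terms | protein-altering and splicing classes; synonymous/UTR/intronic/intergenic and unknown terms drop (unknown terms additionally log a warning) |
| `missing_genotype_policy` | `non_informative` | — | a missing call neither constrains nor vetoes; `strict` instead requires every constrained member genotyped. A variant with *no* genotyped affected member always drops |
| `ar_unaffected_policy` | `obligate_only` | — | only obligate carriers (unaffected parents of affected members) must be heterozygous; other unaffected members must merely not be hom-alt. The stricter reading — every genotyped unaffected member heterozygous — is available as `all_het`, because distant unaffected relatives need not be carriers under AR inheritance |
| MAF source field | `MAF` INFO key | — | which population (global vs. ancestry-specific) the frequency represents is a property of the annotation pipeline, so the field name is configurable rather than fixed |

Individuals with unknown affection status are non-informative for
segregation in both models. AD configurations where no affected member has
an affected parent pass the filter as literally specified (the genotype
pattern is indistinguishable from a transmitted variant at one site) but the
candidate table carries a `de_novo_like` flag for review.

## Classification

Only evidence derivable from the annotations and the pedigree is assigned:

* **PVS1** — consequence ∈ {stop-gained, frameshift, splice donor/acceptor,
  start-loss} *and* the gene is flagged as having a loss-of-function disease
  mechanism in the config (empty by default: LoF-mechanism status is curated
  knowledge, not derivable from a VCF).
* **PM2** — MAF absent or below the rarity bound, which defaults to the
  cascade's own model threshold.
* **PP1** — the variant passes the segregation filter and the pedigree
  offers at least `pp1_min_meioses` (default 2) informative meioses, counted
  as parent→child edges where both ends have non-missing genotypes and the
  child's affection status is known. Two is intentionally permissive — PP1
  is supporting-strength evidence; raise it for stricter co-segregation
  requirements.
* **PP3 / BP4** — strict-majority vote over the non-absent in-silico
  predictor calls (ties are inconclusive and assign nothing).
* **BA1** — MAF above 5% (stand-alone benign). **BS1** — MAF above the PM2
  rarity bound.

Criteria requiring external case/functional databases (PS1, PS4, PM1, PM5,
…) are not implemented; a generic strong slot (`PS_any`) can be injected by
external curation. The combining table is the published ACMG scheme encoded
as a versioned YAML fixture (`data/acmg_combining_rules.yaml`); with the
restricted evidence universe, several of its rows are unreachable but they
are kept for fidelity to the source table. Simultaneous pathogenic- and
benign-direction evidence is resolved conservatively to VUS.

The per-variant verdicts on real cohorts depend on curation inputs (LoF-gene
flags, predictor panels) and are not expected to reproduce any particular
published per-variant worksheet; the cohort accounting layer is exact
arithmetic over whatever verdicts are supplied.

## Cohort accounting

A family contributes at most once per gene and once per pathway regardless
of how many qualifying variants it carries. Percentages are
`100·count/total_families` rounded **half-up** to two decimals (7/30 →
23.33, 1/32 → 3.13 rather than banker's 3.12). The gene→pathway map is
editable data; the shipped map assigns PLEKHA5 to the epithelial-related
group and CREBBP to TGF-β — two assignments that published supplementary
material leaves ambiguous — and the test suite only asserts quantities that
are invariant under swapping them.

## The simulator

`simulate_family` emulates exactly the statistical structure the cascade
assumes: independent biallelic sites; founder genotypes in Hardy–Weinberg
equilibrium at each site's MAF; child alleles drawn uniformly from each
parent's two alleles; one planted causal variant per family whose genotype
configuration is constructed (not sampled) to satisfy the declared model,
with the minimal number of founder allele introductions the topology allows.
For the four-generation second-cousin AR template that minimum is three —
one ancestral lineage shared by the two affected branches plus the two
married-in carrier parents; a smaller number is topologically impossible
without consanguinity, which the template does not include.

Background variants default to 500 per family and are each assigned a
designated failure stage (rarity, consequence, segregation, or relevance,
uniformly), making the planted variant the unique expected survivor — this
is what gives recovery runs a defined precision of 1.0. Their MAFs span both
sides of the relevant threshold (log-uniform below it; 2% of sites placed
exactly on the boundary; 5% with the MAF absent), consequences mix
whitelisted and non-whitelisted terms, and gene symbols mix relevance-list
genes with synthetic out-of-list symbols. Set
`ensure_background_fails=False` for unconstrained backgrounds.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium and shared
haplotypes, genotyping error, sequencing coverage artifacts, population
stratification of MAFs, locus heterogeneity, annotation errors (wrong
transcript, wrong consequence), and phenocopies. Perfect recall on simulated
families shows the cascade implements its stated rules, not that the rules
capture every real causal variant.

Planted variants default to a rare (MAF 0.001) missense change in *ECPAS*
with a 4-of-5 damaging predictor consensus, matching the profile of a
recessive candidate in a proteasome-associated gene; all of this is
configurable per run. `penetrance < 1` introduces silent carriers (an
unaffected child of a carrier parent inherits the allele with the Mendelian
probability and stays unaffected with probability `1 − penetrance`),
which defeats the full-penetrance segregation rule as expected.

## Numerical and engineering choices

* Multiallelic VCF sites are split into biallelic records before filtering
  (the genotype rules are defined per alternate allele); per-sample total
  alt dosage is conserved across the split, and per-allele (`Number=A`)
  INFO fields are distributed positionally.
* VCF `Float` INFO values are single precision; on read, MAFs are snapped to
  six significant digits so that a value written as `0.05` compares equal to
  the 5% threshold after a file round trip.
* Candidate tables are sorted by (chromosome, position, ref, alt) with
  natural chromosome ordering, making reruns byte-identical; the run
  manifest records config hash and input SHA-256 checksums (timestamps live
  only in the manifest).
* Pedigree validation requires acyclic parentage, both-or-neither parents,
  within-family parent references, and ≥2 affected members (the multiplex
  inclusion criterion). All built-in templates — including the
  transmission trio, which pairs an affected parent with an affected child —
  satisfy it at the default setting; `min_affected` is exposed for
  single-proband pedigrees.
* The model-suggestion heuristic (`suggest_model`) is advisory only and
  never overrides the configured model: AD on any affected-parent→affected-
  child link; AR when every affected member has two non-affected parents and
  at least one parent is definitively unaffected; ambiguous otherwise.

## Problem sizes used in the shipped checks

Recovery runs use 100 seeded simulations per inheritance model at 500
background variants on the 7-member AD and 14-member AR templates;
gene-dropping statistics use 10⁴ drops (3σ binomial bands); segregation
oracle equivalence enumerates all 3⁵ genotype vectors on two 5-member
pedigrees under both models (972 decisions), with an additional 4⁵ sweep
including missing genotypes; the ACMG sweep covers all 2⁸ evidence subsets.
These sizes give the binomial checks adequate power while keeping the whole
suite fast enough to run habitually.

## Known limitations

* No compound-heterozygous, X-linked, or mitochondrial models; no de novo
  analysis (trio designs with single affected probands are a different
  study type).
* The relevance screen is a static curated list; it does not re-implement
  phenotype-driven gene ranking tools, whose output it stands in for.
* ACMG coverage is the annotation-derivable subset only; verdicts are
  conservative (a rare, damaging, co-segregating missense variant without a
  LoF mechanism remains a VUS).
* Upstream of the annotated VCF — alignment, variant calling, annotation —
  is out of scope; annotation quality bounds everything downstream.
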