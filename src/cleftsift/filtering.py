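"""The four-stage per-family variant prioritization cascade.

Stages, applied conjunctively and in a fixed order so attrition counts are
well defined:

1. **Rarity** — exclude variants whose population MAF strictly exceeds the
   model threshold (0.5% for AD families, 5% for AR families). A variant
   absent from the population database passes by default.
2. **Consequence** — keep protein-altering and splicing consequences only.
3. **Segregation** — genotypes must co-segregate with affection status under
   the family's inheritance model: AD requires every genotyped affected
   member heterozygous and every genotyped unaffected member homozygous
   reference; AR requires every genotyped affected member homozygous for the
   alternate allele, every obligate carrier heterozygous, and no genotyped
   unaffected member homozygous alternate.
4. **Phenotype relevance** — the gene must appear in a curated list of genes
   implicated in orofacial cleft or craniofacial development.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .formats_io import CohortConfig, DEFAULT_CONSEQUENCE_WHITELIST
from .pedigree import Affection, InheritanceModel, Pedigree, obligate_carriers
from .variants import Genotype, VariantRecord, is_autosome

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "maf_filter",
    "consequence_filter",
    "segregation_filter",
    "relevance_filter",
    "run_cascade",
]

# consequence vocabulary we know how to judge; anything else is dropped with a warning
KNOWN_CONSEQUENCES = DEFAULT_CONSEQUENCE_WHITELIST | frozenset(
    {
        "synonymous_variant",
        "intron_variant",
        "intergenic_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "non_coding_transcript_exon_variant",
        "stop_lost",
        "stop_retained_variant",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Resolved, file-free settings for one cascade run."""

    maf_threshold_ad: float = 0.005
    maf_threshold_ar: float = 0.05
    consequence_whitelist: frozenset = DEFAULT_CONSEQUENCE_WHITELIST
    relevance_genes: frozenset = frozenset()
    missing_maf_is_rare: bool = True
    missing_genotype_policy: str = "non_informative"
    ar_unaffected_policy: str = "obligate_only"
    autosomes_only: bool = True

    @classmethod
    def from_cohort_config(
        cls, cfg: CohortConfig, relevance_genes: frozenset
    ) -> "FilterConfig":
        return cls(
            maf_threshold_ad=cfg.maf_threshold_ad,
            maf_threshold_ar=cfg.maf_threshold_ar,
            consequence_whitelist=cfg.consequence_whitelist,
            relevance_genes=frozenset(g.upper() for g in relevance_genes),
            missing_maf_is_rare=cfg.missing_maf_is_rare,
            missing_genotype_policy=cfg.missing_genotype_policy,
            ar_unaffected_policy=cfg.ar_unaffected_policy,
            autosomes_only=cfg.autosomes_only,
        )

    def maf_threshold(self, model: InheritanceModel) -> float:
        return (
            self.maf_threshold_ad
            if model is InheritanceModel.AD
            else self.maf_threshold_ar
        )


@dataclass
class FilterTrace:
    """Per-stage attrition counts for one family (auditable screening record)."""

    family_id: str
    n_input: int = 0
    n_after_maf: int = 0
    n_after_consequence: int = 0
    n_after_segregation: int = 0
    n_after_relevance: int = 0

    def as_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "input": self.n_input,
            "after_maf": self.n_after_maf,
            "after_consequence": self.n_after_consequence,
            "after_segregation": self.n_after_segregation,
            "after_relevance": self.n_after_relevance,
        }


def maf_filter(
    v: VariantRecord, model: InheritanceModel, cfg: FilterConfig
) -> bool:
    """Keep unless the population MAF *strictly exceeds* the model threshold.

    Boundary values (exactly 0.5% / 5%) are retained. Absent MAF is treated
    as rare by default.
    """
    if v.population_maf is None:
        return cfg.missing_maf_is_rare
    return v.population_maf <= cfg.maf_threshold(model)


def consequence_filter(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Keep protein-altering / splicing consequences on the whitelist."""
    term = v.consequence
    if term is None:
        logger.warning("%s: no consequence term; dropped", v.hgvs_like())
        return False
    if term in cfg.consequence_whitelist:
        return True
    if term not in KNOWN_CONSEQUENCES:
        logger.warning("%s: unknown consequence term %r; dropped", v.hgvs_like(), term)
    return False


def _known_genotype(v: VariantRecord, iid: str) -> Optional[Genotype]:
    """Genotype of a member if genotyped with a non-missing call, else None."""
    gt = v.genotypes.get(iid)
    if gt is None or gt is Genotype.MISSING:
        return None
    return gt


def segregation_filter(
    v: VariantRecord,
    ped: Pedigree,
    missing_genotype_policy: str = "non_informative",
    ar_unaffected_policy: str = "obligate_only",
) -> bool:
    """Does the variant co-segregate with affection under the family's model?

    Members with unknown affection status are non-informative. Under the
    default ``non_informative`` policy a missing genotype neither constrains
    nor vetoes; under ``strict`` every constrained member must have a
    non-missing genotype. ``ar_unaffected_policy="all_het"`` additionally
    requires every genotyped unaffected member (not just obligate carriers)
    to be heterozygous in AR families.
    """
    if ped.model is None:
        raise ValueError(f"family {ped.family_id}: no inheritance model assigned")
    strict = missing_genotype_policy == "strict"

    affected = [m.id for m in ped.affected() if m.genotyped]
    unaffected = [m.id for m in ped.unaffected() if m.genotyped]

    aff_gts = {i: _known_genotype(v, i) for i in affected}
    if not any(g is not None for g in aff_gts.values()):
        logger.warning(
            "family %s %s: no genotyped affected member; dropped",
            ped.family_id,
            v.hgvs_like(),
        )
        return False

    if ped.model is InheritanceModel.AD:
        required = {i: Genotype.HET for i in affected}
        required.update({i: Genotype.HOM_REF for i in unaffected})
        for iid, want in required.items():
            gt = _known_genotype(v, iid)
            if gt is None:
                if strict:
                    return False
                continue
            if gt is not want:
                return False
        return True

    # AR
    carriers = obligate_carriers(ped)
    for iid in affected:
        gt = _known_genotype(v, iid)
        if gt is None:
            if strict:
                return False
            continue
        if gt is not Genotype.HOM_ALT:
            return False
    for iid in sorted(carriers):
        if not ped.members[iid].genotyped:
            if strict:
                return False
            continue
        gt = _known_genotype(v, iid)
        if gt is None:
            if strict:
                return False
            continue
        if gt is not Genotype.HET:
            return False
    for iid in unaffected:
        gt = _known_genotype(v, iid)
        if gt is None:
            if strict and ar_unaffected_policy == "all_het":
                return False
            continue
        if gt is Genotype.HOM_ALT:
            return False
        if ar_unaffected_policy == "all_het" and gt is not Genotype.HET:
            return False
    return True


def relevance_filter(v: VariantRecord, gene_set: frozenset) -> bool:
    """Keep iff the (case-folded) gene symbol is on the curated relevance list."""
    if not gene_set:
        raise ValueError("relevance gene set is empty; configuration error")
    if v.gene_symbol is None:
        return False
    return v.gene_symbol.upper() in gene_set


def run_cascade(
    records: Iterable[VariantRecord],
    ped: Pedigree,
    cfg: FilterConfig,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply rarity → consequence → segregation → relevance for one family.

    Returns surviving candidates in genomic order together with the
    per-stage attrition trace. Non-autosomal records are excluded before the
    cascade when ``cfg.autosomes_only`` (the models here are autosomal).
    """
    if ped.model is None:
        raise ValueError(f"family {ped.family_id}: no inheritance model assigned")
    records = list(records)
    if cfg.autosomes_only:
        records = [v for v in records if is_autosome(v.chrom)]
    trace = FilterTrace(family_id=ped.family_id, n_input=len(records))

    s1 = [v for v in records if maf_filter(v, ped.model, cfg)]
    trace.n_after_maf = len(s1)
    s2 = [v for v in s1 if consequence_filter(v, cfg)]
    trace.n_after_consequence = len(s2)
    s3 = [
        v
        for v in s2
        if segregation_filter(
            v, ped, cfg.missing_genotype_policy, cfg.ar_unaffected_policy
        )
    ]
    trace.n_after_segregation = len(s3)
    s4 = [v for v in s3 if relevance_filter(v, cfg.relevance_genes)]
    trace.n_after_relevance = len(s4)

    s4.sort(key=VariantRecord.sort_key)
    return s4, trace
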