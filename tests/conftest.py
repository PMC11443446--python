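from __future__ import annotations

import pytest

from cleftsift.formats_io import PedRow
from cleftsift.pedigree import (
    Affection,
    InheritanceModel,
    Pedigree,
    Sex,
    validate_pedigree,
)
from cleftsift.variants import Genotype, VariantRecord

AFF, UN, UNK = Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN


def make_ped(rows, model=None, genotyped=None, min_affected=2) -> Pedigree:
    """rows: (iid, father, mother, affection) tuples for one family."""
    ped_rows = [
        PedRow("FAM", iid, fa, mo, Sex.UNKNOWN, aff) for iid, fa, mo, aff in rows
    ]
    samples = (
        {r.individual_id for r in ped_rows} if genotyped is None else set(genotyped)
    )
    return validate_pedigree(
        ped_rows, vcf_samples=samples, model=model, min_affected=min_affected
    )


def make_variant(
    genotypes: dict[str, Genotype] | None = None,
    gene="ECPAS",
    consequence="missense_variant",
    maf=0.001,
    predictors=None,
    chrom="9",
    pos=1000,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="G",
        gene_symbol=gene,
        consequence=consequence,
        population_maf=maf,
        genotypes=genotypes or {},
        predictor_calls=predictors or {},
    )


@pytest.fixture
def ar_family30_like() -> Pedigree:
    """Four-generation AR family: affected second cousins D1/D2, unaffected
    parents C1/C2 (and C3/C4), great-grandparents shared through A1xA2."""
    from cleftsift.simulate import build_pedigree

    return build_pedigree("four_gen_ar", family_id="FAM30")


@pytest.fixture
def ad_three_gen() -> Pedigree:
    from cleftsift.simulate import build_pedigree

    return build_pedigree("three_gen_ad", family_id="FAMAD")


@pytest.fixture
def five_member_ad() -> Pedigree:
    # affected father -> affected child, plus unaffected members
    return make_ped(
        [
            ("F", None, None, AFF),
            ("M", None, None, UN),
            ("S1", "F", "M", AFF),
            ("S2", "F", "M", UN),
            ("S3", "F", "M", UN),
        ],
        model=InheritanceModel.AD,
    )


@pytest.fixture
def five_member_ar() -> Pedigree:
    # unaffected parents (obligate carriers), two affected + one unaffected child
    return make_ped(
        [
            ("F", None, None, UN),
            ("M", None, None, UN),
            ("S1", "F", "M", AFF),
            ("S2", "F", "M", AFF),
            ("S3", "F", "M", UN),
        ],
        model=InheritanceModel.AR,
    )
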