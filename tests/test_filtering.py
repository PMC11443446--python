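"""The four-stage cascade: unit rules, exhaustive segregation oracle, properties."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftsift.filtering import (
    FilterConfig,
    consequence_filter,
    maf_filter,
    relevance_filter,
    run_cascade,
    segregation_filter,
)
from cleftsift.pedigree import Affection, InheritanceModel
from cleftsift.variants import Genotype
from conftest import AFF, UN, UNK, make_ped, make_variant

CFG = FilterConfig(relevance_genes=frozenset({"ECPAS", "PTCH1", "IRF6"}))
AD, AR = InheritanceModel.AD, InheritanceModel.AR


# ---------------------------------------------------------------------------
# a1: rarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model, maf, keep",
    [
        (AD, 0.006, False),   # commoner than 0.5% excluded under AD
        (AD, 0.004, True),
        (AD, 0.005, True),    # boundary retained: exclusion is strictly 'higher than'
        (AR, 0.04, True),     # 4% passes the 5% AR threshold
        (AR, 0.06, False),
        (AR, 0.05, True),     # boundary retained
        (AR, None, True),     # novel variant absent from databases passes
        (AD, None, True),
        (AD, 0.0, True),
    ],
)
def test_maf_filter_model_aware_thresholds(model, maf, keep):
    v = make_variant(maf=maf)
    assert maf_filter(v, model, CFG) is keep


def test_missing_maf_policy_overridable():
    strict = FilterConfig(missing_maf_is_rare=False)
    assert maf_filter(make_variant(maf=None), AD, strict) is False


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    maf=st.one_of(st.none(), st.floats(0, 1)),
    t1=st.floats(0.001, 0.4),
    t2=st.floats(0.001, 0.4),
)
def test_maf_threshold_monotonicity(maf, t1, t2):
    # raising a threshold never removes a previously kept variant
    lo, hi = sorted((t1, t2))
    v = make_variant(maf=maf)
    cfg_lo = FilterConfig(maf_threshold_ad=lo, maf_threshold_ar=max(lo, hi))
    cfg_hi = FilterConfig(maf_threshold_ad=hi, maf_threshold_ar=max(lo, hi))
    if maf_filter(v, AD, cfg_lo):
        assert maf_filter(v, AD, cfg_hi)


# ---------------------------------------------------------------------------
# a2: consequence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "term, keep",
    [
        ("missense_variant", True),
        ("stop_gained", True),
        ("start_lost", True),
        ("frameshift_variant", True),
        ("inframe_deletion", True),
        ("splice_acceptor_variant", True),
        ("splice_region_variant", True),
        ("synonymous_variant", False),
        ("intron_variant", False),
        ("totally_made_up_term", False),  # unknown term dropped with warning
        (None, False),
    ],
)
def test_consequence_whitelist(term, keep):
    assert consequence_filter(make_variant(consequence=term), CFG) is keep


# ---------------------------------------------------------------------------
# a3: segregation — exhaustive oracle equivalence
# ---------------------------------------------------------------------------

def oracle_segregation(ped, genotypes, model, ar_unaffected_policy="obligate_only"):
    """Literal transliteration of the stated AD/AR co-segregation rules,
    written independently of the implementation (no shared helpers)."""
    known = {}
    for m in ped:
        if m.genotyped and genotypes.get(m.id, Genotype.MISSING) is not Genotype.MISSING:
            known[m.id] = genotypes[m.id]

    affected_known = [
        m.id for m in ped if m.affection is Affection.AFFECTED and m.id in known
    ]
    if not affected_known:
        return False

    if model is AD:
        for m in ped:
            if m.id not in known:
                continue
            if m.affection is Affection.AFFECTED and known[m.id] is not Genotype.HET:
                return False
            if m.affection is Affection.UNAFFECTED and known[m.id] is not Genotype.HOM_REF:
                return False
        return True

    # AR: obligate carriers found by direct parent-link scan
    carriers = set()
    for m in ped:
        if m.affection is not Affection.AFFECTED:
            continue
        for pid in (m.father, m.mother):
            if pid is not None and ped.members[pid].affection is Affection.UNAFFECTED:
                carriers.add(pid)
    for m in ped:
        if m.id not in known:
            continue
        gt = known[m.id]
        if m.affection is Affection.AFFECTED and gt is not Genotype.HOM_ALT:
            return False
        if m.id in carriers and gt is not Genotype.HET:
            return False
        if m.affection is Affection.UNAFFECTED:
            if gt is Genotype.HOM_ALT:
                return False
            if ar_unaffected_policy == "all_het" and gt is not Genotype.HET:
                return False
    return True


GT3 = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
GT4 = GT3 + (Genotype.MISSING,)


@pytest.mark.parametrize("model", [AD, AR])
@pytest.mark.parametrize("ped_fixture", ["five_member_ad", "five_member_ar"])
def test_segregation_matches_oracle_all_243_vectors(request, ped_fixture, model):
    """All 3^5 genotype assignments on 5-member pedigrees, both models."""
    ped = request.getfixturevalue(ped_fixture)
    ped.model = model
    ids = sorted(ped.members)
    for combo in itertools.product(GT3, repeat=len(ids)):
        gts = dict(zip(ids, combo))
        v = make_variant(genotypes=gts)
        assert segregation_filter(v, ped) == oracle_segregation(ped, gts, model), (
            model,
            gts,
        )


@pytest.mark.parametrize("model", [AD, AR])
@pytest.mark.parametrize("policy", ["obligate_only", "all_het"])
def test_segregation_with_missing_genotypes_matches_oracle(
    five_member_ar, model, policy
):
    """4^5 vectors including missing calls under the non-informative policy."""
    ped = five_member_ar
    ped.model = model
    ids = sorted(ped.members)
    for combo in itertools.product(GT4, repeat=len(ids)):
        gts = dict(zip(ids, combo))
        v = make_variant(genotypes=gts)
        got = segregation_filter(v, ped, ar_unaffected_policy=policy)
        assert got == oracle_segregation(ped, gts, model, policy)


def test_ar_family30_pattern_kept(ar_family30_like):
    """Affected second cousins hom-alt, their four parents het: the textbook keep."""
    gts = {m.id: Genotype.HOM_REF for m in ar_family30_like}
    gts.update({"D1": Genotype.HOM_ALT, "D2": Genotype.HOM_ALT})
    gts.update({c: Genotype.HET for c in ("C1", "C2", "C3", "C4")})
    assert segregation_filter(make_variant(genotypes=gts), ar_family30_like)


def test_ad_affected_homalt_dropped(five_member_ad):
    gts = {
        "F": Genotype.HOM_ALT,  # AD requires heterozygous affected carriers
        "M": Genotype.HOM_REF,
        "S1": Genotype.HET,
        "S2": Genotype.HOM_REF,
        "S3": Genotype.HOM_REF,
    }
    assert not segregation_filter(make_variant(genotypes=gts), five_member_ad)


def test_no_genotyped_affected_is_dropped(five_member_ad):
    gts = {
        "F": Genotype.MISSING,
        "M": Genotype.HOM_REF,
        "S1": Genotype.MISSING,
        "S2": Genotype.HOM_REF,
        "S3": Genotype.HOM_REF,
    }
    assert not segregation_filter(make_variant(genotypes=gts), five_member_ad)


def test_strict_policy_requires_constrained_members_genotyped(five_member_ad):
    gts = {
        "F": Genotype.HET,
        "M": Genotype.MISSING,
        "S1": Genotype.HET,
        "S2": Genotype.HOM_REF,
        "S3": Genotype.HOM_REF,
    }
    v = make_variant(genotypes=gts)
    assert segregation_filter(v, five_member_ad)  # default: non-informative
    assert not segregation_filter(v, five_member_ad, missing_genotype_policy="strict")


def test_unknown_affection_is_non_informative():
    ped = make_ped(
        [
            ("F", None, None, AFF),
            ("M", None, None, UNK),
            ("S1", "F", "M", AFF),
        ],
        model=AD,
    )
    gts = {"F": Genotype.HET, "M": Genotype.HOM_ALT, "S1": Genotype.HET}
    assert segregation_filter(make_variant(genotypes=gts), ped)


# ---------------------------------------------------------------------------
# a4: relevance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gene, keep",
    [("ECPAS", True), ("Ecpas", True), ("NOTAGENE", False), (None, False)],
)
def test_relevance_case_folded_membership(gene, keep):
    assert relevance_filter(make_variant(gene=gene), CFG.relevance_genes) is keep


def test_empty_gene_set_is_configuration_error():
    with pytest.raises(ValueError, match="empty"):
        relevance_filter(make_variant(), frozenset())


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def _cascade_inputs(five_member_ar):
    keep_gts = {
        "F": Genotype.HET,
        "M": Genotype.HET,
        "S1": Genotype.HOM_ALT,
        "S2": Genotype.HOM_ALT,
        "S3": Genotype.HOM_REF,
    }
    good = make_variant(genotypes=keep_gts, pos=100)
    too_common = make_variant(genotypes=keep_gts, maf=0.2, pos=200)
    synonymous = make_variant(
        genotypes=keep_gts, consequence="synonymous_variant", pos=300
    )
    bad_seg = make_variant(
        genotypes={**keep_gts, "S1": Genotype.HET}, pos=400
    )
    wrong_gene = make_variant(genotypes=keep_gts, gene="ZZZ9", pos=500)
    x_linked = make_variant(genotypes=keep_gts, chrom="X", pos=600)
    return [good, too_common, synonymous, bad_seg, wrong_gene, x_linked]


def test_cascade_stagewise_attrition(five_member_ar):
    records = _cascade_inputs(five_member_ar)
    cands, trace = run_cascade(records, five_member_ar, CFG)
    assert [v.pos for v in cands] == [100]
    assert trace.as_dict() == {
        "family_id": "FAM",
        "input": 5,  # X-chromosome record excluded before the cascade
        "after_maf": 4,
        "after_consequence": 3,
        "after_segregation": 2,
        "after_relevance": 1,
    }


def test_cascade_counts_non_increasing(five_member_ar):
    _, trace = run_cascade(_cascade_inputs(five_member_ar), five_member_ar, CFG)
    t = trace.as_dict()
    seq = [
        t["input"],
        t["after_maf"],
        t["after_consequence"],
        t["after_segregation"],
        t["after_relevance"],
    ]
    assert seq == sorted(seq, reverse=True)


def test_cascade_empty_input(five_member_ar):
    cands, trace = run_cascade([], five_member_ar, CFG)
    assert cands == [] and trace.n_input == 0 and trace.n_after_relevance == 0


def test_cascade_order_invariance(five_member_ar):
    records = _cascade_inputs(five_member_ar)
    base, _ = run_cascade(records, five_member_ar, CFG)
    for perm in itertools.permutations(records):
        cands, _ = run_cascade(list(perm), five_member_ar, CFG)
        assert [v.key for v in cands] == [v.key for v in base]


def test_cascade_stage_monotonicity_is_subset(five_member_ar):
    """Each stage's survivor set is a subset of the previous stage's."""
    records = _cascade_inputs(five_member_ar)
    ped = five_member_ar
    s0 = [v for v in records if v.chrom not in ("X", "Y")]
    s1 = [v for v in s0 if maf_filter(v, ped.model, CFG)]
    s2 = [v for v in s1 if consequence_filter(v, CFG)]
    s3 = [v for v in s2 if segregation_filter(v, ped)]
    s4 = [v for v in s3 if relevance_filter(v, CFG.relevance_genes)]
    keys = [{v.key for v in s} for s in (s0, s1, s2, s3, s4)]
    for earlier, later in zip(keys, keys[1:]):
        assert later <= earlier
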