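"""In-silico consensus and ACMG-style five-tier classification.

Only evidence derivable from the annotations and the pedigree is assigned:

* ``PVS1`` — null consequence (nonsense, frameshift, canonical splice,
  start-loss) in a gene where loss of function is a known disease mechanism;
* ``PM2`` — absent from population databases, or rarer than the rarity bound;
* ``PP1`` — co-segregation with disease across a configurable minimum number
  of informative meioses;
* ``PP3`` — majority of in-silico predictors call the variant damaging;
* ``BA1`` — MAF above 5% (stand-alone benign);
* ``BS1`` / ``BP4`` — benign mirrors of PM2 / PP3.

Criteria requiring case–control or functional databases (PS1, PS4, PM5, …)
are out of scope; a generic strong slot (``PS_any``) is accepted from
external curation but never auto-assigned. The combining table is the
published ACMG scheme, shipped as a YAML fixture next to this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import yaml

from .filtering import FilterConfig, segregation_filter
from .pedigree import InheritanceModel, Pedigree
from .variants import Genotype, VariantRecord

__all__ = [
    "EVIDENCE_STRENGTH",
    "EvidenceSet",
    "Classification",
    "insilico_consensus",
    "informative_meioses",
    "assign_evidence",
    "combine_acmg",
    "classify_variant",
    "load_combining_rules",
]

# evidence code -> (direction, strength category of the combining table)
EVIDENCE_STRENGTH: dict[str, tuple[str, str]] = {
    "PVS1": ("pathogenic", "PVS"),
    "PS_any": ("pathogenic", "PS"),
    "PM2": ("pathogenic", "PM"),
    "PP1": ("pathogenic", "PP"),
    "PP3": ("pathogenic", "PP"),
    "BA1": ("benign", "BA"),
    "BS1": ("benign", "BS"),
    "BP4": ("benign", "BP"),
}

LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "start_lost",
    }
)

VERDICTS = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")


@dataclass(frozen=True)
class EvidenceSet:
    """A set of ACMG evidence codes (each at most once)."""

    codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.codes) - set(EVIDENCE_STRENGTH)
        if unknown:
            raise ValueError(f"unknown evidence code(s): {sorted(unknown)}")

    def __iter__(self):
        return iter(sorted(self.codes))

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def counts(self) -> dict[str, int]:
        """Counts per strength category (PVS/PS/PM/PP/BA/BS/BP)."""
        c = {k: 0 for k in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")}
        for code in self.codes:
            c[EVIDENCE_STRENGTH[code][1]] += 1
        return c

    def has_pathogenic(self) -> bool:
        return any(EVIDENCE_STRENGTH[c][0] == "pathogenic" for c in self.codes)

    def has_benign(self) -> bool:
        return any(EVIDENCE_STRENGTH[c][0] == "benign" for c in self.codes)


@dataclass(frozen=True)
class Classification:
    verdict: str
    evidence: EvidenceSet
    rationale: str

    @property
    def is_plp(self) -> bool:
        return self.verdict in ("Pathogenic", "Likely pathogenic")


def insilico_consensus(predictor_calls: Mapping[str, str]) -> str:
    """Majority vote over the non-absent predictor calls.

    Returns ``possibly_pathogenic`` if strictly more than half of the calls
    are damaging, ``possibly_benign`` if strictly more than half are
    tolerated, ``inconclusive`` otherwise (including exact ties).
    """
    calls = [c for c in predictor_calls.values() if c in ("damaging", "tolerated")]
    if not calls:
        raise ValueError("no predictor calls present; consensus undefined")
    n = len(calls)
    damaging = sum(1 for c in calls if c == "damaging")
    if damaging * 2 > n:
        return "possibly_pathogenic"
    if (n - damaging) * 2 > n:
        return "possibly_benign"
    return "inconclusive"


def informative_meioses(v: VariantRecord, ped: Pedigree) -> int:
    """Parent→child transmissions usable as segregation evidence.

    Counted as edges where both parent and child carry a non-missing
    genotype for this variant and the child's affection status is known.
    """
    n = 0
    for child in ped:
        if child.affection.value == "unknown":
            continue
        if v.genotypes.get(child.id, Genotype.MISSING) is Genotype.MISSING:
            continue
        for parent_id in (child.father, child.mother):
            if parent_id is None:
                continue
            if v.genotypes.get(parent_id, Genotype.MISSING) is not Genotype.MISSING:
                n += 1
    return n


def assign_evidence(
    v: VariantRecord,
    ped: Pedigree,
    cfg: FilterConfig,
    lof_mechanism_genes: frozenset = frozenset(),
    pm2_bound: Optional[float] = None,
    pp1_min_meioses: int = 2,
    ba1_threshold: float = 0.05,
    extra_codes: frozenset = frozenset(),
) -> EvidenceSet:
    """Derive the annotation-based evidence codes for a cascade survivor.

    ``pm2_bound`` defaults to the cascade's own model-specific MAF threshold.
    ``extra_codes`` lets external curation inject codes (e.g. ``PS_any``).
    """
    if ped.model is None:
        raise ValueError("pedigree has no inheritance model")
    if pm2_bound is None:
        pm2_bound = cfg.maf_threshold(ped.model)
    codes: set[str] = set(extra_codes)

    gene = (v.gene_symbol or "").upper()
    if v.consequence in LOF_CONSEQUENCES and gene in lof_mechanism_genes:
        codes.add("PVS1")

    maf = v.population_maf
    if maf is None or maf < pm2_bound:
        codes.add("PM2")
    if maf is not None and maf > ba1_threshold:
        codes.add("BA1")
    if maf is not None and maf > pm2_bound:
        codes.add("BS1")

    if v.predictor_calls:
        consensus = insilico_consensus(v.predictor_calls)
        if consensus == "possibly_pathogenic":
            codes.add("PP3")
        elif consensus == "possibly_benign":
            codes.add("BP4")

    segregates = segregation_filter(
        v, ped, cfg.missing_genotype_policy, cfg.ar_unaffected_policy
    )
    if segregates and informative_meioses(v, ped) >= pp1_min_meioses:
        codes.add("PP1")

    return EvidenceSet(frozenset(codes))


_RULES_CACHE: Optional[dict] = None


def load_combining_rules() -> dict:
    """The ACMG combining-rule table from the packaged YAML fixture."""
    global _RULES_CACHE
    if _RULES_CACHE is None:
        text = (
            resources.files("cleftsift")
            .joinpath("data/acmg_combining_rules.yaml")
            .read_text()
        )
        _RULES_CACHE = yaml.safe_load(text)
    return _RULES_CACHE


def _any_rule_satisfied(rules: list[dict], counts: dict[str, int]) -> bool:
    return any(
        all(counts.get(cat, 0) >= need for cat, need in rule.items())
        for rule in rules
    )


def combine_acmg(evidence: EvidenceSet) -> Classification:
    """Five-tier verdict from an evidence set, per the combining-rule fixture.

    Simultaneous pathogenic- and benign-direction evidence is treated as a
    conflict and resolved conservatively to VUS.
    """
    if evidence.has_pathogenic() and evidence.has_benign():
        return Classification(
            verdict="VUS",
            evidence=evidence,
            rationale="conflicting pathogenic and benign evidence",
        )
    rules = load_combining_rules()
    counts = evidence.counts()
    for verdict_key, verdict in (
        ("pathogenic", "Pathogenic"),
        ("likely_pathogenic", "Likely pathogenic"),
        ("benign", "Benign"),
        ("likely_benign", "Likely benign"),
    ):
        if _any_rule_satisfied(rules.get(verdict_key, []), counts):
            codes = ", ".join(evidence) or "none"
            return Classification(
                verdict=verdict,
                evidence=evidence,
                rationale=f"rule set {verdict_key!r} satisfied by [{codes}]",
            )
    return Classification(
        verdict="VUS",
        evidence=evidence,
        rationale="evidence insufficient for any combining rule",
    )


def classify_variant(
    v: VariantRecord,
    ped: Pedigree,
    cfg: FilterConfig,
    **evidence_kwargs,
) -> Classification:
    """Convenience: assign evidence then combine."""
    return combine_acmg(assign_evidence(v, ped, cfg, **evidence_kwargs))
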