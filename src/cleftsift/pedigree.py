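"""Pedigree graphs and the role sets the segregation filter needs.

A family is a directed acyclic graph of individuals with sex, affection
status and parental links. Only multiplex families (at least two affected
members) are accepted by default, mirroring the usual inclusion criterion
for hereditary-cohort studies of nonsyndromic orofacial clefts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "Sex",
    "Affection",
    "InheritanceModel",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "validate_pedigree",
    "obligate_carriers",
    "suggest_model",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(str, Enum):
    """Autosomal dominant / autosomal recessive single-gene models."""

    AD = "AD"
    AR = "AR"


class PedigreeError(ValueError):
    """Structural or inclusion-criterion violation in a pedigree."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]  # None = founder
    mother: Optional[str]
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Validated family graph plus the inheritance model assigned to it."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    model: Optional[InheritanceModel] = None

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def affected(self) -> list[Individual]:
        return [m for m in self if m.affection is Affection.AFFECTED]

    def unaffected(self) -> list[Individual]:
        return [m for m in self if m.affection is Affection.UNAFFECTED]

    def founders(self) -> list[Individual]:
        return [m for m in self if m.is_founder]

    def parents_of(self, individual_id: str) -> list[Individual]:
        ind = self.members[individual_id]
        return [self.members[p] for p in (ind.father, ind.mother) if p is not None]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [m for m in self if individual_id in (m.father, m.mother)]

    def topological_order(self) -> list[Individual]:
        """Members ordered founders-first (parents always precede children)."""
        order: list[Individual] = []
        placed: set[str] = set()
        pending = dict(self.members)
        while pending:
            progress = False
            for iid in list(pending):
                ind = pending[iid]
                deps = [p for p in (ind.father, ind.mother) if p is not None]
                if all(d in placed for d in deps):
                    order.append(ind)
                    placed.add(iid)
                    del pending[iid]
                    progress = True
            if not progress:  # pragma: no cover - guarded by validate_pedigree
                raise PedigreeError(
                    f"family {self.family_id}: cycle in parentage among {sorted(pending)}"
                )
        return order


def _check_acyclic(members: dict[str, Individual], family_id: str) -> None:
    # iterative DFS with colouring; a back edge means someone is their own ancestor
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {iid: WHITE for iid in members}

    for root in members:
        if colour[root] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        while stack:
            iid, state = stack.pop()
            if state == 0:
                if colour[iid] == GREY:
                    raise PedigreeError(
                        f"family {family_id}: individual {iid!r} is their own ancestor"
                    )
                if colour[iid] == BLACK:
                    continue
                colour[iid] = GREY
                stack.append((iid, 1))
                ind = members[iid]
                for p in (ind.father, ind.mother):
                    if p is not None:
                        if colour[p] == GREY:
                            raise PedigreeError(
                                f"family {family_id}: individual {p!r} is their own ancestor"
                            )
                        if colour[p] == WHITE:
                            stack.append((p, 0))
            else:
                colour[iid] = BLACK


def validate_pedigree(
    rows: Iterable,
    vcf_samples: Iterable[str] = (),
    model: Optional[InheritanceModel] = None,
    min_affected: int = 2,
) -> Pedigree:
    """Build a validated :class:`Pedigree` from parsed PED rows.

    ``vcf_samples`` marks which members have a genotype column; the
    intersection sets each member's ``genotyped`` flag. Families with fewer
    than ``min_affected`` affected members are rejected (study inclusion
    criterion: multiplex families only).
    """
    rows = list(rows)
    if not rows:
        raise PedigreeError("no pedigree rows supplied")
    family_ids = {r.family_id for r in rows}
    if len(family_ids) != 1:
        raise PedigreeError(f"rows span multiple families: {sorted(family_ids)}")
    family_id = rows[0].family_id

    samples = set(vcf_samples)
    members: dict[str, Individual] = {}
    for r in rows:
        if r.individual_id in members:
            raise PedigreeError(
                f"family {family_id}: duplicate individual id {r.individual_id!r}"
            )
        if (r.father_id is None) != (r.mother_id is None):
            raise PedigreeError(
                f"family {family_id}: individual {r.individual_id!r} has exactly one "
                "known parent; both or neither must be specified"
            )
        members[r.individual_id] = Individual(
            id=r.individual_id,
            father=r.father_id,
            mother=r.mother_id,
            sex=r.sex,
            affection=r.affection,
            genotyped=r.individual_id in samples,
        )

    for ind in members.values():
        for p in (ind.father, ind.mother):
            if p is not None and p not in members:
                raise PedigreeError(
                    f"family {family_id}: parent {p!r} of {ind.id!r} not in family"
                )
    _check_acyclic(members, family_id)

    ped = Pedigree(family_id=family_id, members=members, model=model)
    n_affected = len(ped.affected())
    if n_affected < min_affected:
        raise PedigreeError(
            f"family {family_id}: {n_affected} affected member(s); "
            f"at least {min_affected} required (multiplex inclusion criterion)"
        )
    return ped


def obligate_carriers(ped: Pedigree) -> set[str]:
    """Unaffected parents of affected individuals under an AR model.

    Under full penetrance an affected child is homozygous for the causal
    allele, so each unaffected parent must carry exactly one copy.
    """
    if ped.model is not InheritanceModel.AR:
        raise ValueError("obligate carriers are defined for AR pedigrees only")
    out: set[str] = set()
    for aff in ped.affected():
        for parent in ped.parents_of(aff.id):
            if parent.affection is Affection.UNAFFECTED:
                out.add(parent.id)
    return out


def suggest_model(ped: Pedigree) -> str:
    """Heuristic AD/AR call from affection topology; never overrides config.

    AD if any affected individual has an affected parent (vertical
    transmission); AR if every affected individual has two unaffected or
    unknown-status parents that are present in the family; ambiguous
    otherwise (e.g. affected founders with no parental information).
    """
    affected = ped.affected()
    any_affected_parent = False
    parents_compatible_ar = True  # both parents present, none affected
    any_definite_unaffected_parent = False
    for aff in affected:
        parents = ped.parents_of(aff.id)
        if any(p.affection is Affection.AFFECTED for p in parents):
            any_affected_parent = True
        if len(parents) != 2 or any(
            p.affection is Affection.AFFECTED for p in parents
        ):
            parents_compatible_ar = False
        if any(p.affection is Affection.UNAFFECTED for p in parents):
            any_definite_unaffected_parent = True
    if any_affected_parent:
        return InheritanceModel.AD.value
    if parents_compatible_ar and any_definite_unaffected_parent:
        return InheritanceModel.AR.value
    return "ambiguous"
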