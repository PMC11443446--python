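"""Normalized biallelic variant records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

__all__ = ["Genotype", "VariantRecord", "AUTOSOMES", "is_autosome"]


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def dosage(self) -> Optional[int]:
        """Alternate-allele dosage; None when the genotype is missing."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]

    @classmethod
    def from_dosage(cls, d: Optional[int]) -> "Genotype":
        if d is None:
            return cls.MISSING
        return (cls.HOM_REF, cls.HET, cls.HOM_ALT)[d]


class PredictorCall(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"


AUTOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
)


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


@dataclass
class VariantRecord:
    """One biallelic variant with the annotations the filtering cascade consumes.

    Coordinates are 1-based and REF-anchored (VCF convention).
    ``population_maf`` is ``None`` when the variant is absent from the
    population database — distinct from an observed frequency of 0.0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: Optional[str] = None
    consequence: Optional[str] = None
    population_maf: Optional[float] = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    predictor_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.population_maf is not None and not (0.0 <= self.population_maf <= 1.0):
            raise ValueError(f"population MAF out of [0,1]: {self.population_maf}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def hgvs_like(self) -> str:
        return f"{self.chrom}:g.{self.pos}{self.ref}>{self.alt}"

    def sort_key(self) -> tuple:
        c = self.chrom.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c), self.pos, self.ref, self.alt
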