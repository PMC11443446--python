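"""Readers/writers for the interchange formats: annotated VCF, PLINK PED, YAML config.

The VCF reader is a thin normalization layer over :mod:`pysam`. Annotations
(gene symbol, consequence term, population MAF, in-silico predictor calls)
arrive as INFO fields; nothing here calls an annotator. A missing MAF is kept
as *absent* (``None``), never coerced to 0.0 — novel variants absent from
population databases are first-class citizens of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam
import yaml

from .pedigree import Affection, InheritanceModel, Sex
from .variants import Genotype, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PedRow",
    "RawVariantSite",
    "CohortConfig",
    "FormatError",
    "read_ped",
    "write_ped",
    "read_annotated_vcf",
    "split_multiallelic",
    "site_to_record",
    "read_variant_records",
    "load_cohort_config",
    "load_gene_list",
    "load_pathway_map",
]

FOUNDER_MARKER = "0"

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTION_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFFECTION_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class PedRow:
    """One line of a 6-column PLINK pedigree file."""

    family_id: str
    individual_id: str
    father_id: Optional[str]  # None = founder / unknown parent ("0" on disk)
    mother_id: Optional[str]
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN


@dataclass
class RawVariantSite:
    """A VCF record upstream of normalization; possibly multiallelic.

    ``genotypes`` maps sample id to a pair of allele indices (0 = REF,
    k = k-th ALT) or ``None`` for a missing call.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    info: dict = field(default_factory=dict)
    genotypes: dict[str, Optional[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        n = len(self.alts)
        for sample, gt in self.genotypes.items():
            if gt is None:
                continue
            if any(a is None or not (0 <= a <= n) for a in gt):
                raise FormatError(
                    f"{self.chrom}:{self.pos} sample {sample}: allele index out of "
                    f"range for {n} alt allele(s): {gt}"
                )


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: Union[str, Path]) -> list[PedRow]:
    """Parse a whitespace-delimited 6+ column PED file.

    Coding: sex 1=male, 2=female, other=unknown; affection 2=affected,
    1=unaffected, 0/-9=unknown; parent id "0" = founder. Parent references
    must resolve within the same family.
    """
    rows: list[PedRow] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex_code, aff_code = fields[:6]
            key = (fam, iid)
            if key in seen:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate individual {iid!r} in family {fam!r}"
                )
            seen.add(key)
            rows.append(
                PedRow(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid == FOUNDER_MARKER else fid,
                    mother_id=None if mid == FOUNDER_MARKER else mid,
                    sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
                    affection=_AFFECTION_CODES.get(aff_code, Affection.UNKNOWN),
                )
            )
    # referential integrity per family
    by_family: dict[str, set[str]] = {}
    for r in rows:
        by_family.setdefault(r.family_id, set()).add(r.individual_id)
    for r in rows:
        for parent in (r.father_id, r.mother_id):
            if parent is not None and parent not in by_family[r.family_id]:
                raise FormatError(
                    f"{path}: parent {parent!r} of individual {r.individual_id!r} "
                    f"absent from family {r.family_id!r}"
                )
    return rows


def write_ped(rows: Iterable[PedRow], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        r.individual_id,
                        r.father_id or FOUNDER_MARKER,
                        r.mother_id or FOUNDER_MARKER,
                        _SEX_OUT[r.sex],
                        _AFFECTION_OUT[r.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_annotated_vcf(
    path: Union[str, Path],
    required_fields: Sequence[str] = (),
    on_missing: str = "error",
) -> Iterator[RawVariantSite]:
    """Stream :class:`RawVariantSite` from a VCF 4.x file (plain or bgzipped).

    ``required_fields`` are INFO keys that must be present on every record;
    ``on_missing`` is ``"error"`` (raise) or ``"skip"`` (drop the record with
    a log message). Genotypes ``./.`` map to ``None``.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError(f"on_missing must be 'error' or 'skip', got {on_missing!r}")
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = {}
            for k, v in rec.info.items():
                info[k] = list(v) if isinstance(v, tuple) else v
            missing = [k for k in required_fields if k not in info]
            if missing:
                msg = f"{rec.chrom}:{rec.pos}: missing required INFO field(s) {missing}"
                if on_missing == "error":
                    raise FormatError(msg)
                logger.warning("skipping %s", msg)
                continue
            genotypes: dict[str, Optional[tuple[int, int]]] = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes[s] = None
                else:
                    genotypes[s] = (gt[0], gt[1])
            yield RawVariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=list(rec.alts or ()),
                info=info,
                genotypes=genotypes,
            )


def split_multiallelic(site: RawVariantSite) -> list[RawVariantSite]:
    """Decompose a multiallelic site into one biallelic site per ALT.

    For the split record of ALT *k*, allele index *k* recodes to 1 and every
    other allele (REF or another ALT) recodes to 0, so that per-sample total
    alt dosage is conserved across the split set. List-valued INFO fields of
    length ``len(alts)`` are distributed positionally; scalars are copied.
    """
    n = len(site.alts)
    if n <= 1:
        return [site]
    for key, val in site.info.items():
        if isinstance(val, list) and len(val) not in (1, n):
            raise FormatError(
                f"{site.chrom}:{site.pos}: INFO field {key!r} has {len(val)} "
                f"value(s) for {n} alt alleles"
            )
    out: list[RawVariantSite] = []
    for k in range(1, n + 1):
        info = {}
        for key, val in site.info.items():
            if isinstance(val, list):
                info[key] = val[k - 1] if len(val) == n else val[0]
            else:
                info[key] = val
        genotypes = {}
        for s, gt in site.genotypes.items():
            if gt is None:
                genotypes[s] = None
            else:
                genotypes[s] = (1 if gt[0] == k else 0, 1 if gt[1] == k else 0)
        out.append(
            RawVariantSite(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alts=[site.alts[k - 1]],
                info=info,
                genotypes=genotypes,
            )
        )
    return out


_PREDICTOR_CODES = {
    "D": "damaging",
    "damaging": "damaging",
    "T": "tolerated",
    "tolerated": "tolerated",
}


def site_to_record(
    site: RawVariantSite,
    gene_field: str = "GENE",
    consequence_field: str = "CSQ",
    maf_field: str = "MAF",
    predictor_prefix: str = "PRED_",
) -> VariantRecord:
    """Normalize a biallelic :class:`RawVariantSite` into a :class:`VariantRecord`."""
    if len(site.alts) != 1:
        raise ValueError("site_to_record requires a biallelic site; split first")
    maf = site.info.get(maf_field)
    if isinstance(maf, list):
        maf = maf[0]
    if maf is not None:
        # VCF Float is single precision; restore the printed decimal value so
        # threshold boundaries (e.g. exactly 0.05) survive a file round trip
        maf = float(f"{float(maf):.6g}")
    gene = site.info.get(gene_field)
    csq = site.info.get(consequence_field)
    predictors = {}
    for key, val in site.info.items():
        if key.startswith(predictor_prefix) and val is not None:
            call = _PREDICTOR_CODES.get(str(val))
            if call is not None:
                predictors[key[len(predictor_prefix):]] = call
    genotypes = {}
    for s, gt in site.genotypes.items():
        if gt is None:
            genotypes[s] = Genotype.MISSING
        else:
            genotypes[s] = Genotype.from_dosage(gt[0] + gt[1])
    return VariantRecord(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alts[0],
        gene_symbol=str(gene) if gene is not None else None,
        consequence=str(csq) if csq is not None else None,
        population_maf=float(maf) if maf is not None else None,
        genotypes=genotypes,
        predictor_calls=predictors,
    )


def read_variant_records(
    path: Union[str, Path],
    required_fields: Sequence[str] = (),
    on_missing: str = "error",
    **field_names,
) -> list[VariantRecord]:
    """Read, split and normalize an annotated VCF in one call."""
    out: list[VariantRecord] = []
    for site in read_annotated_vcf(path, required_fields, on_missing):
        for bi in split_multiallelic(site):
            out.append(site_to_record(bi, **field_names))
    return out


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

DEFAULT_CONSEQUENCE_WHITELIST = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "start_lost",
        "inframe_insertion",
        "inframe_deletion",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "splice_region_variant",
    }
)


@dataclass
class CohortConfig:
    """Cohort-level settings: per-family inheritance model, thresholds, policies.

    MAF exclusion is model-aware: variants commoner than 0.5% are excluded
    under AD, commoner than 5% under AR (strict inequality — boundary values
    are retained). A missing MAF passes by default (novel variants are of
    interest); set ``missing_maf_is_rare=False`` to drop them instead.
    """

    families: dict[str, InheritanceModel] = field(default_factory=dict)
    maf_threshold_ad: float = 0.005
    maf_threshold_ar: float = 0.05
    consequence_whitelist: frozenset = DEFAULT_CONSEQUENCE_WHITELIST
    relevance_gene_list_path: Optional[str] = None
    gene_pathway_map_path: Optional[str] = None
    missing_maf_is_rare: bool = True
    missing_genotype_policy: str = "non_informative"  # or "strict"
    ar_unaffected_policy: str = "obligate_only"  # or "all_het"
    autosomes_only: bool = True
    gene_field: str = "GENE"
    consequence_field: str = "CSQ"
    maf_field: str = "MAF"
    lof_mechanism_genes: frozenset = frozenset()
    pp1_min_meioses: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold_ad <= self.maf_threshold_ar < 1):
            raise ValueError(
                "require 0 < maf_threshold_ad <= maf_threshold_ar < 1, got "
                f"{self.maf_threshold_ad} / {self.maf_threshold_ar}"
            )
        if self.missing_genotype_policy not in ("non_informative", "strict"):
            raise ValueError(f"bad missing_genotype_policy {self.missing_genotype_policy!r}")
        if self.ar_unaffected_policy not in ("obligate_only", "all_het"):
            raise ValueError(f"bad ar_unaffected_policy {self.ar_unaffected_policy!r}")
        self.families = {
            k: InheritanceModel(v) for k, v in self.families.items()
        }
        self.consequence_whitelist = frozenset(self.consequence_whitelist)
        self.lof_mechanism_genes = frozenset(
            g.upper() for g in self.lof_mechanism_genes
        )

    def maf_threshold(self, model: InheritanceModel) -> float:
        return (
            self.maf_threshold_ad
            if model is InheritanceModel.AD
            else self.maf_threshold_ar
        )


def load_cohort_config(path: Union[str, Path]) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return CohortConfig(**raw)


def load_gene_list(path: Union[str, Path]) -> frozenset[str]:
    """One upper-cased gene symbol per line; '#' comments and blanks ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.upper())
    return frozenset(genes)


def load_pathway_map(path: Union[str, Path]) -> dict[str, str]:
    """Two-column TSV gene→pathway; '#' comments and blanks ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            out[parts[0].strip().upper()] = parts[1].strip()
    return out
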