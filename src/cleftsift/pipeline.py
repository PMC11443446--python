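"""End-to-end per-family and cohort runs with manifests and TSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .classification import Classification, assign_evidence, combine_acmg
from .filtering import FilterConfig, FilterTrace, run_cascade
from .formats_io import (
    CohortConfig,
    load_gene_list,
    load_pathway_map,
    read_ped,
    read_variant_records,
)
from .pedigree import Affection, InheritanceModel, Pedigree, validate_pedigree
from .reporting import CohortSummary, summarize_cohort
from .variants import VariantRecord

__all__ = ["RunManifest", "FamilyResult", "run_family", "run_cohort"]

CANDIDATE_COLUMNS = [
    "family_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf",
    "hgvs",
    "de_novo_like",
    "evidence",
    "verdict",
]


def _sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: CohortConfig) -> str:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, frozenset):
            d[k] = sorted(v)
        elif isinstance(v, dict):
            d[k] = {str(kk): getattr(vv, "value", vv) for kk, vv in v.items()}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: dict
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FamilyResult:
    family_id: str
    pedigree: Pedigree
    candidates: list[VariantRecord]
    classifications: list[Optional[Classification]]
    trace: FilterTrace
    manifest: RunManifest

    def plp_genes(self) -> set[str]:
        return {
            v.gene_symbol.upper()
            for v, c in zip(self.candidates, self.classifications)
            if c is not None and c.is_plp and v.gene_symbol
        }

    def table(self) -> pd.DataFrame:
        de_novo_like = _de_novo_like(self.pedigree)
        rows = []
        for v, c in zip(self.candidates, self.classifications):
            rows.append(
                {
                    "family_id": self.family_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene_symbol,
                    "consequence": v.consequence,
                    "maf": "" if v.population_maf is None else f"{v.population_maf:.6g}",
                    "hgvs": v.hgvs_like(),
                    "de_novo_like": de_novo_like,
                    "evidence": "" if c is None else ",".join(c.evidence),
                    "verdict": "" if c is None else c.verdict,
                }
            )
        return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def _de_novo_like(ped: Pedigree) -> bool:
    """AD pattern with no affected parent anywhere: cannot reflect transmission."""
    if ped.model is not InheritanceModel.AD:
        return False
    for aff in ped.affected():
        if any(
            p.affection is Affection.AFFECTED for p in ped.parents_of(aff.id)
        ):
            return False
    return True


def _packaged(name: str) -> Path:
    return Path(str(resources.files("cleftsift").joinpath("data", name)))


def resolve_relevance_genes(cfg: CohortConfig) -> frozenset:
    path = cfg.relevance_gene_list_path or _packaged("ofc_relevance_genes.txt")
    return load_gene_list(path)


def resolve_pathway_map(cfg: CohortConfig) -> dict[str, str]:
    path = cfg.gene_pathway_map_path or _packaged("gene_pathway_map.tsv")
    return load_pathway_map(path)


def run_family(
    vcf_path: Union[str, Path],
    ped_path: Union[str, Path],
    cfg: CohortConfig,
    family_id: Optional[str] = None,
    outdir: Optional[Union[str, Path]] = None,
    classify: bool = True,
) -> FamilyResult:
    """Cascade (and optionally classify) one family's annotated VCF.

    The family's inheritance model comes from ``cfg.families``; ``family_id``
    defaults to the single family present in the PED file. When ``outdir``
    is given, writes ``<family>.candidates.tsv``, ``<family>.trace.tsv`` and
    ``<family>.manifest.json``.
    """
    rows = read_ped(ped_path)
    if family_id is None:
        fams = {r.family_id for r in rows}
        if len(fams) != 1:
            raise ValueError(
                f"PED file has families {sorted(fams)}; pass family_id explicitly"
            )
        family_id = rows[0].family_id
    rows = [r for r in rows if r.family_id == family_id]
    if family_id not in cfg.families:
        raise ValueError(f"no inheritance model configured for family {family_id!r}")
    model = cfg.families[family_id]

    records = read_variant_records(
        vcf_path,
        gene_field=cfg.gene_field,
        consequence_field=cfg.consequence_field,
        maf_field=cfg.maf_field,
    )
    sample_ids = set(records[0].genotypes) if records else set()
    ped = validate_pedigree(rows, vcf_samples=sample_ids, model=model)

    fc = FilterConfig.from_cohort_config(cfg, resolve_relevance_genes(cfg))
    candidates, trace = run_cascade(records, ped, fc)

    classifications: list[Optional[Classification]] = []
    for v in candidates:
        if classify:
            ev = assign_evidence(
                v,
                ped,
                fc,
                lof_mechanism_genes=cfg.lof_mechanism_genes,
                pp1_min_meioses=cfg.pp1_min_meioses,
            )
            classifications.append(combine_acmg(ev))
        else:
            classifications.append(None)

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash(cfg),
        input_checksums={
            str(vcf_path): _sha256_file(vcf_path),
            str(ped_path): _sha256_file(ped_path),
        },
        stage_counts=trace.as_dict(),
    )
    result = FamilyResult(family_id, ped, candidates, classifications, trace, manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.table().to_csv(outdir / f"{family_id}.candidates.tsv", sep="\t", index=False)
        pd.DataFrame([trace.as_dict()]).to_csv(
            outdir / f"{family_id}.trace.tsv", sep="\t", index=False
        )
        (outdir / f"{family_id}.manifest.json").write_text(
            json.dumps(manifest.as_dict(), indent=2, sort_keys=True) + "\n"
        )
    return result


def run_cohort(
    family_specs: Sequence[dict],
    cfg: CohortConfig,
    outdir: Optional[Union[str, Path]] = None,
) -> tuple[CohortSummary, list[FamilyResult]]:
    """Run every family then aggregate P/LP hits into the cohort summary.

    ``family_specs`` is a sequence of ``{"family_id":…, "vcf":…, "ped":…}``.
    """
    if not family_specs:
        raise ValueError("at least one family required")
    results = [
        run_family(spec["vcf"], spec["ped"], cfg, spec.get("family_id"), outdir)
        for spec in family_specs
    ]
    hits = {r.family_id: sorted(r.plp_genes()) for r in results}
    summary = summarize_cohort(hits, resolve_pathway_map(cfg), len(family_specs))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "cohort_summary.json").write_text(
            json.dumps(summary.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        summary.gene_frame().to_csv(outdir / "cohort_genes.tsv", sep="\t", index=False)
        summary.pathway_frame().to_csv(
            outdir / "cohort_pathways.tsv", sep="\t", index=False
        )
    return summary, results
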