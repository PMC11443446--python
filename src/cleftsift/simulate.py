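"""Gene-dropping pedigree simulator with planted causal variants.

Generates families, genotypes and annotated VCF/PED files with the
statistical structure the prioritization cascade assumes: founder genotypes
drawn from Hardy–Weinberg equilibrium at a site's population MAF, Mendelian
transmission down the pedigree, one planted causal variant whose genotype
configuration satisfies the family's inheritance model by construction, and
background variants spanning both sides of the MAF thresholds with a mix of
whitelisted/non-whitelisted consequences and in/out-of-relevance-list genes.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .formats_io import DEFAULT_CONSEQUENCE_WHITELIST, PedRow, write_ped
from .pedigree import (
    Affection,
    InheritanceModel,
    Pedigree,
    Sex,
    validate_pedigree,
)
from .variants import Genotype, VariantRecord

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedFamily",
    "SimulationError",
    "PEDIGREE_TEMPLATES",
    "build_pedigree",
    "gene_drop",
    "plant_causal",
    "mendelian_consistent",
    "simulate_family",
    "emit_dataset",
]


class SimulationError(RuntimeError):
    """Pedigree topology incompatible with the requested genotype configuration."""


# ---------------------------------------------------------------------------
# Pedigree templates
# ---------------------------------------------------------------------------

_M, _F = Sex.MALE, Sex.FEMALE
_AFF, _UN = Affection.AFFECTED, Affection.UNAFFECTED

# (id, father, mother, sex, affection)
_TRIO_AD = [
    ("F1", None, None, _M, _AFF),
    ("M1", None, None, _F, _UN),
    ("C1", "F1", "M1", _M, _AFF),
]

_THREE_GEN_AD = [
    ("G1", None, None, _M, _AFF),
    ("G2", None, None, _F, _UN),
    ("P1", "G1", "G2", _F, _AFF),
    ("P2", None, None, _M, _UN),
    ("P3", "G1", "G2", _M, _UN),
    ("K1", "P2", "P1", _M, _AFF),
    ("K2", "P2", "P1", _F, _UN),
]

# Four generations; D1 and D2 are affected second cousins (shared
# great-grandparents A1×A2); each has two unaffected parents — the obligate
# carriers C1–C4. Mirrors the structure of a multiplex AR family in which
# the only affected members sit two meioses below unrelated married-in
# carriers.
_FOUR_GEN_AR = [
    ("A1", None, None, _M, _UN),
    ("A2", None, None, _F, _UN),
    ("B1", None, None, _M, _UN),
    ("B2", "A1", "A2", _F, _UN),
    ("B3", "A1", "A2", _M, _UN),
    ("B4", None, None, _F, _UN),
    ("B5", "A1", "A2", _F, _UN),
    ("C1", "B1", "B2", _M, _UN),
    ("C2", None, None, _F, _UN),
    ("C3", "B3", "B4", _F, _UN),
    ("C4", None, None, _M, _UN),
    ("D1", "C1", "C2", _M, _AFF),
    ("D2", "C4", "C3", _F, _AFF),
    ("D3", "C1", "C2", _F, _UN),
]

PEDIGREE_TEMPLATES: dict[str, tuple[list, InheritanceModel]] = {
    "trio": (_TRIO_AD, InheritanceModel.AD),
    "three_gen_ad": (_THREE_GEN_AD, InheritanceModel.AD),
    "four_gen_ar": (_FOUR_GEN_AR, InheritanceModel.AR),
}


def build_pedigree(
    template: str, family_id: Optional[str] = None
) -> Pedigree:
    """Instantiate a named template as a validated, fully genotyped pedigree."""
    if template not in PEDIGREE_TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; choose from {sorted(PEDIGREE_TEMPLATES)}"
        )
    rows, model = PEDIGREE_TEMPLATES[template]
    fam = family_id or f"SIM-{template}"
    ped_rows = [
        PedRow(fam, iid, fa, mo, sex, aff) for iid, fa, mo, sex, aff in rows
    ]
    return validate_pedigree(
        ped_rows, vcf_samples={r.individual_id for r in ped_rows}, model=model
    )


def template_ped_rows(template: str, family_id: str) -> list[PedRow]:
    rows, _ = PEDIGREE_TEMPLATES[template]
    return [PedRow(family_id, iid, fa, mo, sex, aff) for iid, fa, mo, sex, aff in rows]


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def gene_drop(
    ped: Pedigree, maf: float, seed: Union[int, np.random.Generator] = 0
) -> dict[str, int]:
    """Drop one biallelic site down the pedigree; returns alt-allele dosages.

    Founders draw two independent alleles Bernoulli(maf) (Hardy–Weinberg:
    hom-alt maf², het 2·maf·(1−maf)); each child allele is a uniform draw
    from the corresponding parent's two alleles.
    """
    if not (0 < maf < 1):
        raise ValueError(f"maf must be in (0,1), got {maf}")
    rng = _rng(seed)
    alleles: dict[str, tuple[int, int]] = {}
    for ind in ped.topological_order():
        if ind.is_founder:
            a = int(rng.random() < maf)
            b = int(rng.random() < maf)
        else:
            pa = alleles[ind.father]
            ma = alleles[ind.mother]
            a = pa[int(rng.integers(2))]
            b = ma[int(rng.integers(2))]
        alleles[ind.id] = (a, b)
    return {iid: a + b for iid, (a, b) in alleles.items()}


def mendelian_consistent(ped: Pedigree, dosages: dict[str, int]) -> bool:
    """Can every child's genotype be produced by one allele from each parent?"""
    for ind in ped:
        if ind.is_founder:
            continue
        c = dosages[ind.id]
        f, m = dosages[ind.father], dosages[ind.mother]
        if c == 2 and (f == 0 or m == 0):
            return False
        if c == 0 and (f == 2 or m == 2):
            return False
        if c == 1:
            # need alt from one parent and ref from the other
            if not ((f >= 1 and m <= 1) or (m >= 1 and f <= 1)):
                return False
    return True


def plant_causal(
    ped: Pedigree,
    model: InheritanceModel,
    seed: Union[int, np.random.Generator] = 0,
    penetrance: float = 1.0,
) -> dict[str, int]:
    """Genotype configuration of a fully penetrant causal variant.

    AD: every affected member heterozygous, every other member homozygous
    reference. AR: every affected member homozygous alternate, obligate
    carriers heterozygous, and the remaining carriers needed for a
    Mendelian-consistent transmission path chosen deterministically with as
    few founder introductions as the topology allows.

    With ``penetrance`` < 1, unaffected members may additionally become
    silent carriers (AD: het with probability (1−penetrance)/2 given a
    carrier parent; AR: hom-alt with probability (1−penetrance)/4 given two
    carrier parents), demonstrating how incomplete penetrance defeats a
    full-penetrance segregation rule.
    """
    if ped.model is not None and ped.model is not model:
        raise ValueError(f"model {model.value} does not match pedigree ({ped.model.value})")
    if not (0 < penetrance <= 1):
        raise ValueError("penetrance must be in (0, 1]")
    rng = _rng(seed)
    topo = ped.topological_order()
    dosages: dict[str, int] = {ind.id: 0 for ind in topo}

    if model is InheritanceModel.AD:
        for ind in topo:
            if ind.affection is Affection.AFFECTED:
                dosages[ind.id] = 1
        for ind in topo:
            if ind.affection is Affection.AFFECTED and not ind.is_founder:
                parents = ped.parents_of(ind.id)
                if not any(dosages[p.id] >= 1 for p in parents):
                    raise SimulationError(
                        f"family {ped.family_id}: affected {ind.id!r} has no affected "
                        "parent; an AD variant cannot be transmitted without a "
                        "carrier parent (de novo events are not simulated)"
                    )
    else:
        for ind in topo:
            if ind.affection is Affection.AFFECTED:
                dosages[ind.id] = 2
        # unaffected parents of affected members are obligate heterozygotes
        for ind in topo:
            if ind.affection is Affection.AFFECTED:
                for p in ped.parents_of(ind.id):
                    if p.affection is not Affection.AFFECTED:
                        dosages[p.id] = max(dosages[p.id], 1)
        # trace each required carrier allele up to a founder, preferring
        # non-founder parents so lineages share a single ancestral introduction
        for ind in reversed(topo):
            if dosages[ind.id] >= 1 and not ind.is_founder:
                parents = ped.parents_of(ind.id)
                if dosages[ind.id] == 2:
                    for p in parents:
                        dosages[p.id] = max(dosages[p.id], 1)
                elif not any(dosages[p.id] >= 1 for p in parents):
                    nonfounders = [p for p in parents if not p.is_founder]
                    chosen = nonfounders[0] if nonfounders else parents[0]
                    dosages[chosen.id] = 1
        # children of homozygous carriers necessarily inherit one allele
        for ind in topo:
            if ind.is_founder:
                continue
            if any(dosages[p.id] == 2 for p in ped.parents_of(ind.id)):
                dosages[ind.id] = max(dosages[ind.id], 1)

    if penetrance < 1.0:
        for ind in topo:
            if ind.affection is not Affection.UNAFFECTED or dosages[ind.id] != 0:
                continue
            parents = ped.parents_of(ind.id)
            if model is InheritanceModel.AD:
                if any(dosages[p.id] >= 1 for p in parents):
                    if rng.random() < (1 - penetrance) / 2:
                        dosages[ind.id] = 1
            else:
                if len(parents) == 2 and all(dosages[p.id] >= 1 for p in parents):
                    if rng.random() < (1 - penetrance) / 4:
                        dosages[ind.id] = 2

    if not mendelian_consistent(ped, dosages):
        raise SimulationError(
            f"family {ped.family_id}: no Mendelian-consistent {model.value} "
            "configuration exists for this topology"
        )
    return dosages


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

_NON_WHITELIST_CONSEQUENCES = (
    "synonymous_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
)
_PREDICTORS = ("SIFT", "POLYPHEN2", "MUTATIONTASTER", "PROVEAN", "REVEL")
_BASES = ("A", "C", "G", "T")
_STAGES = ("maf", "consequence", "segregation", "relevance")


@dataclass
class SimulationConfig:
    """All knobs of one simulated family dataset; the seed fixes everything."""

    seed: int = 0
    template: str = "four_gen_ar"
    family_id: Optional[str] = None
    n_background_variants: int = 500
    background_maf_range: tuple[float, float] = (1e-4, 0.2)
    missing_maf_fraction: float = 0.05
    boundary_maf_fraction: float = 0.02  # planted exactly at the model threshold
    planted_gene: str = "ECPAS"
    planted_consequence: str = "missense_variant"
    planted_maf: Optional[float] = 0.001
    penetrance: float = 1.0
    relevance_fraction: float = 0.5
    genotype_missingness: float = 0.0
    ensure_background_fails: bool = True

    def __post_init__(self) -> None:
        if self.template not in PEDIGREE_TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if not (0 < self.penetrance <= 1):
            raise ValueError("penetrance must be in (0, 1]")
        lo, hi = self.background_maf_range
        if not (0 < lo < hi < 1):
            raise ValueError("background_maf_range must satisfy 0 < lo < hi < 1")

    @property
    def model(self) -> InheritanceModel:
        return PEDIGREE_TEMPLATES[self.template][1]


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset, for recovery scoring."""

    planted_key: Optional[tuple[str, int, str, str]]
    planted_gene: Optional[str]
    carrier_dosage: dict[str, int] = field(default_factory=dict)

    def is_planted_causal(self, v: VariantRecord) -> bool:
        return self.planted_key is not None and v.key == self.planted_key

    def as_dict(self) -> dict:
        key = None
        if self.planted_key is not None:
            chrom, pos, ref, alt = self.planted_key
            key = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        return {
            "planted_variant": key,
            "planted_gene": self.planted_gene,
            "carrier_dosage": self.carrier_dosage,
        }


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    pedigree: Pedigree
    ped_rows: list[PedRow]
    records: list[VariantRecord]
    truth: TruthTable


def _relevance_pool(planted_gene: str) -> list[str]:
    text = (
        resources.files("cleftsift")
        .joinpath("data/ofc_relevance_genes.txt")
        .read_text()
    )
    genes = sorted(
        {
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        }
        - {planted_gene.upper()}
    )
    return genes


def _draw_background_maf(
    rng: np.random.Generator, cfg: SimulationConfig, threshold: float, fail: bool
) -> Optional[float]:
    lo, hi = cfg.background_maf_range
    if fail:
        # strictly above the exclusion threshold
        return float(rng.uniform(threshold * 1.2, max(hi, threshold * 3)))
    u = rng.random()
    if u < cfg.missing_maf_fraction:
        return None  # novel variant, absent from population databases
    if u < cfg.missing_maf_fraction + cfg.boundary_maf_fraction:
        return threshold  # boundary value: retained under strict '>' exclusion
    # log-uniform below the threshold
    log_lo, log_hi = np.log(lo), np.log(min(threshold, hi))
    return float(np.exp(rng.uniform(log_lo, log_hi)))


def _perturb_to_fail_segregation(
    dosages: dict[str, int], ped: Pedigree, model: InheritanceModel
) -> dict[str, int]:
    """Force a genotype vector to violate the model's segregation rule."""
    affected = sorted(m.id for m in ped.affected() if m.genotyped)
    target = affected[0]
    bad = 0 if model is InheritanceModel.AD else 1  # AD needs het, AR needs hom-alt
    out = dict(dosages)
    out[target] = bad
    return out


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Simulate one family: pedigree, planted causal variant, background variants.

    Background variants are (by default) each constructed to fail at least
    one cascade stage, so the planted variant is the unique true positive;
    their MAFs, consequences and gene symbols still span both sides of every
    decision boundary.
    """
    from .filtering import FilterConfig, segregation_filter  # cycle-free local import

    rng = np.random.default_rng(cfg.seed)
    model = cfg.model
    family_id = cfg.family_id or f"SIM{cfg.seed:05d}"
    ped = build_pedigree(cfg.template, family_id)
    ped_rows = template_ped_rows(cfg.template, family_id)
    sample_ids = [r.individual_id for r in ped_rows]

    fc = FilterConfig()
    threshold = fc.maf_threshold(model)
    relevance_pool = _relevance_pool(cfg.planted_gene)
    records: list[VariantRecord] = []

    # planted causal variant
    planted_dosages = plant_causal(ped, model, rng, cfg.penetrance)
    planted = VariantRecord(
        chrom="9",
        pos=99_000_000,
        ref="C",
        alt="G",
        gene_symbol=cfg.planted_gene,
        consequence=cfg.planted_consequence,
        population_maf=cfg.planted_maf,
        genotypes={s: Genotype.from_dosage(planted_dosages[s]) for s in sample_ids},
        predictor_calls={
            "SIFT": "damaging",
            "POLYPHEN2": "damaging",
            "MUTATIONTASTER": "damaging",
            "PROVEAN": "damaging",
            "REVEL": "tolerated",
        },
    )
    records.append(planted)

    whitelist = sorted(DEFAULT_CONSEQUENCE_WHITELIST)
    chroms = [str(c) for c in range(1, 23)]
    for i in range(cfg.n_background_variants):
        fail_stage = (
            _STAGES[int(rng.integers(len(_STAGES)))]
            if cfg.ensure_background_fails
            else None
        )
        maf = _draw_background_maf(rng, cfg, threshold, fail_stage == "maf")
        if fail_stage == "consequence":
            csq = _NON_WHITELIST_CONSEQUENCES[
                int(rng.integers(len(_NON_WHITELIST_CONSEQUENCES)))
            ]
        else:
            csq = whitelist[int(rng.integers(len(whitelist)))]
        if fail_stage == "relevance":
            gene = f"BG{i:05d}"
        elif rng.random() < cfg.relevance_fraction:
            gene = relevance_pool[int(rng.integers(len(relevance_pool)))]
        else:
            gene = f"BG{i:05d}"
        drop_maf = maf if maf is not None else 0.01
        dosages = gene_drop(ped, max(min(drop_maf, 0.99), 1e-6), rng)
        if fail_stage == "segregation":
            probe = VariantRecord(
                chrom="1",
                pos=1,
                ref="A",
                alt="T",
                genotypes={s: Genotype.from_dosage(dosages[s]) for s in sample_ids},
            )
            if segregation_filter(probe, ped):
                dosages = _perturb_to_fail_segregation(dosages, ped, model)
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        predictors = {
            p: ("damaging" if rng.random() < 0.5 else "tolerated")
            for p in _PREDICTORS
            if rng.random() < 0.8
        }
        records.append(
            VariantRecord(
                chrom=chroms[i % len(chroms)],
                pos=1_000_000 + 1_000 * i,
                ref=ref,
                alt=alt,
                gene_symbol=gene,
                consequence=csq,
                population_maf=maf,
                genotypes={s: Genotype.from_dosage(dosages[s]) for s in sample_ids},
                predictor_calls=predictors,
            )
        )

    if cfg.genotype_missingness > 0:
        for v in records:
            for s in sample_ids:
                if rng.random() < cfg.genotype_missingness:
                    v.genotypes[s] = Genotype.MISSING

    records.sort(key=VariantRecord.sort_key)
    truth = TruthTable(
        planted_key=planted.key,
        planted_gene=cfg.planted_gene,
        carrier_dosage=planted_dosages,
    )
    return SimulatedFamily(cfg, ped, ped_rows, records, truth)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

_GT_OUT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _vcf_header(samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=cleftsift-simulate"]
    lines += [f"##contig=<ID={c}>" for c in range(1, 23)]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term (Sequence Ontology)">',
        '##INFO=<ID=MAF,Number=A,Type=Float,Description="Population minor allele frequency">',
    ]
    for p in _PREDICTORS:
        lines.append(
            f'##INFO=<ID=PRED_{p},Number=1,Type=String,'
            'Description="In-silico predictor call (D=damaging, T=tolerated)">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_vcf(
    records: list[VariantRecord], samples: list[str], path: Union[str, Path]
) -> None:
    """Write records as a plain-text annotated VCF (v4.2)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples))
        for v in records:
            info = []
            if v.gene_symbol is not None:
                info.append(f"GENE={v.gene_symbol}")
            if v.consequence is not None:
                info.append(f"CSQ={v.consequence}")
            if v.population_maf is not None:
                info.append(f"MAF={v.population_maf:.6g}")
            for pred, call in sorted(v.predictor_calls.items()):
                info.append(f"PRED_{pred}={'D' if call == 'damaging' else 'T'}")
            gts = "\t".join(
                _GT_OUT[v.genotypes.get(s, Genotype.MISSING)] for s in samples
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def emit_dataset(
    cfg: SimulationConfig, outdir: Union[str, Path]
) -> tuple[Path, Path, TruthTable]:
    """Write family.vcf / family.ped / truth.json for one simulated family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_family(cfg)
    samples = [r.individual_id for r in sim.ped_rows]
    vcf_path = outdir / f"{sim.pedigree.family_id}.vcf"
    ped_path = outdir / f"{sim.pedigree.family_id}.ped"
    truth_path = outdir / f"{sim.pedigree.family_id}.truth.json"
    write_vcf(sim.records, samples, vcf_path)
    write_ped(sim.ped_rows, ped_path)
    truth_payload = dict(sim.truth.as_dict())
    truth_payload["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(cfg).items()
    }
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return vcf_path, ped_path, sim.truth
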