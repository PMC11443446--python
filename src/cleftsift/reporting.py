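"""Cohort-level accounting: per-gene and per-pathway family contributions.

Each family is counted at most once per gene and once per pathway, however
many qualifying variants it carries; percentages are of the total cohort
size, rounded half-up to two decimals (so 7/30 prints as 23.33).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Collection, Mapping

import pandas as pd

__all__ = ["CohortSummary", "percent", "summarize_cohort", "pathway_rollup"]


def percent(count: int, total: int) -> float:
    """100·count/total rounded half-up to 2 decimals; 0.00 for an empty cohort."""
    if total == 0:
        return 0.0
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class CohortSummary:
    total_families: int
    families_with_plp: int
    families_with_plp_percent: float
    per_gene: dict[str, tuple[int, float]] = field(default_factory=dict)
    per_pathway: dict[str, tuple[int, float]] = field(default_factory=dict)

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, c, p) for g, (c, p) in sorted(self.per_gene.items())],
            columns=["gene", "n_families", "percent"],
        )

    def pathway_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, c, p) for g, (c, p) in sorted(self.per_pathway.items())],
            columns=["pathway", "n_families", "percent"],
        )

    def as_dict(self) -> dict:
        return {
            "total_families": self.total_families,
            "families_with_plp": self.families_with_plp,
            "families_with_plp_percent": self.families_with_plp_percent,
            "per_gene": {g: {"n_families": c, "percent": p} for g, (c, p) in self.per_gene.items()},
            "per_pathway": {
                w: {"n_families": c, "percent": p} for w, (c, p) in self.per_pathway.items()
            },
        }


def pathway_rollup(
    family_gene_hits: Mapping[str, Collection[str]],
    gene_pathway_map: Mapping[str, str],
) -> dict[str, int]:
    """Distinct-family count per pathway from per-family P/LP gene hits."""
    families_per_pathway: dict[str, set[str]] = {}
    missing = sorted(
        {
            g.upper()
            for genes in family_gene_hits.values()
            for g in genes
            if g.upper() not in gene_pathway_map
        }
    )
    if missing:
        raise KeyError(
            f"gene(s) missing from the gene→pathway map: {missing}"
        )
    for fam, genes in family_gene_hits.items():
        for g in genes:
            families_per_pathway.setdefault(gene_pathway_map[g.upper()], set()).add(fam)
    return {w: len(fams) for w, fams in families_per_pathway.items()}


def summarize_cohort(
    family_gene_hits: Mapping[str, Collection[str]],
    gene_pathway_map: Mapping[str, str],
    total_families: int,
) -> CohortSummary:
    """Aggregate per-family pathogenic/likely-pathogenic gene hits.

    ``family_gene_hits`` maps family id → gene symbols with at least one
    P/LP variant in that family (families with none may be omitted or map to
    an empty collection).
    """
    if total_families < 1:
        raise ValueError("total_families must be >= 1")
    hits = {
        fam: {g.upper() for g in genes}
        for fam, genes in family_gene_hits.items()
        if genes
    }
    if len(hits) > total_families:
        raise ValueError(
            f"{len(hits)} families with hits exceeds cohort size {total_families}"
        )
    families_per_gene: dict[str, set[str]] = {}
    for fam, genes in hits.items():
        for g in genes:
            families_per_gene.setdefault(g, set()).add(fam)

    per_gene = {
        g: (len(fams), percent(len(fams), total_families))
        for g, fams in families_per_gene.items()
    }
    pathway_counts = pathway_rollup(hits, gene_pathway_map)
    per_pathway = {
        w: (c, percent(c, total_families)) for w, c in pathway_counts.items()
    }
    n_plp = len(hits)
    return CohortSummary(
        total_families=total_families,
        families_with_plp=n_plp,
        families_with_plp_percent=percent(n_plp, total_families),
        per_gene=per_gene,
        per_pathway=per_pathway,
    )
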