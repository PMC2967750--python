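"""Variant-to-gene assignment within a symmetric window around each gene.

A variant maps to a gene iff the chromosome matches and its 0-based position
falls in ``[start - window_bp, end + window_bp)``.  Manual overrides add
assignments unconditionally.  A variant may map to several genes; genes with
no assigned variant are dropped from the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genotype_io import GeneInterval, OverrideEntry, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class SNPGeneMap:
    """Many-to-many variant/gene assignment with per-gene variant lists in
    positional order."""

    gene_variants: dict[str, list[str]]

    @property
    def assignments(self) -> set[tuple[str, str]]:
        return {
            (vid, gene) for gene, vids in self.gene_variants.items() for vid in vids
        }

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.gene_variants)

    @property
    def variant_ids(self) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        for vids in self.gene_variants.values():
            for vid in vids:
                if vid not in seen:
                    seen.add(vid)
                    out.append(vid)
        return out

    def n_snps(self, gene_symbol: str) -> int:
        return len(self.gene_variants[gene_symbol])


def in_window(
    variant: VariantRecord, gene: GeneInterval, window_bp: int
) -> bool:
    """Window predicate in 0-based half-open arithmetic; inclusive of exactly
    ``window_bp`` beyond each gene end."""
    if variant.chrom != gene.chrom:
        return False
    pos0 = variant.pos - 1
    return gene.start - window_bp <= pos0 < gene.end + window_bp


def assign_snps(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneInterval],
    window_bp: int = 5000,
    overrides: Iterable[OverrideEntry] = (),
) -> SNPGeneMap:
    """Assign variants to genes within ``window_bp`` of each gene boundary.

    Overrides must name known genes and variants; they add their assignment
    regardless of position.  Genes left with zero variants are dropped.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be >= 0, got {window_bp}")
    by_vid = {v.variant_id: v for v in variants}
    gene_symbols = {g.symbol for g in genes}
    gene_variants: dict[str, list[VariantRecord]] = {g.symbol: [] for g in genes}
    for g in genes:
        for v in variants:
            if in_window(v, g, window_bp):
                gene_variants[g.symbol].append(v)
    for ov in overrides:
        if ov.symbol not in gene_symbols:
            raise ValueError(f"override names unknown gene '{ov.symbol}'")
        if ov.variant_id not in by_vid:
            raise ValueError(f"override names unknown variant '{ov.variant_id}'")
        v = by_vid[ov.variant_id]
        if v not in gene_variants[ov.symbol]:
            gene_variants[ov.symbol].append(v)
    result: dict[str, list[str]] = {}
    n_dropped = 0
    for g in genes:
        vs = gene_variants[g.symbol]
        if not vs:
            n_dropped += 1
            continue
        vs_sorted = sorted(vs, key=lambda v: (v.chrom, v.pos, v.variant_id))
        result[g.symbol] = [v.variant_id for v in vs_sorted]
    if n_dropped:
        logger.info("dropped %d genes with no assigned variants", n_dropped)
    return SNPGeneMap(gene_variants=result)


def write_map(snp_map: SNPGeneMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tgene_symbol\n")
        for gene, vids in snp_map.gene_variants.items():
            for vid in vids:
                fh.write(f"{vid}\t{gene}\n")


def read_map(path) -> SNPGeneMap:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_variants: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        gene_variants.setdefault(row.gene_symbol, []).append(row.variant_id)
    return SNPGeneMap(gene_variants=gene_variants)
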