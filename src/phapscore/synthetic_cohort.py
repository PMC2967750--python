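"""Synthetic pharmacogenomic cohorts with known ground truth.

Genotypes are drawn per haplotype under Hardy-Weinberg equilibrium at
per-SNP minor allele frequencies sampled uniformly from a configurable
range.  Within a gene, each successive SNP copies the previous SNP's allele
on the same haplotype with probability ``ld_rho``, inducing local LD (and
none between genes).  Dose is a linear function of the minor-allele burden
of the planted effect genes plus Gaussian noise, floored at 0.5 mg/day to
stay physically plausible.  The effect operates through the burden — not
through the score itself — so score-based detection is a genuine test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import (
    GeneInterval,
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    write_dosage_table,
    write_phenotypes,
    write_vcf,
)

DOSE_FLOOR = 0.5  # mg/day
_GENE_SLOT_BP = 100_000
_GENES_PER_CHROM = 10


@dataclass
class SimConfig:
    n_samples: int = 100
    n_genes: int = 20
    snps_per_gene: tuple[int, int] = (3, 8)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    effect_genes: list[tuple[int, float]] = field(default_factory=list)
    baseline_dose: float = 5.0
    noise_sd: float = 1.0
    low_threshold: float = 3.0
    high_threshold: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_samples < 2:
            problems.append(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_genes < 1:
            problems.append(f"n_genes must be >= 1, got {self.n_genes}")
        lo, hi = self.snps_per_gene
        if not (1 <= lo <= hi):
            problems.append(f"snps_per_gene range invalid: {self.snps_per_gene}")
        flo, fhi = self.maf_range
        if not (0.0 < flo <= fhi <= 0.5):
            problems.append(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            problems.append(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not self.noise_sd > 0:
            problems.append(f"noise_sd must be > 0, got {self.noise_sd}")
        for g_idx, _beta in self.effect_genes:
            if not 0 <= g_idx < self.n_genes:
                problems.append(f"effect gene index {g_idx} out of range")
        if not self.baseline_dose > 0:
            problems.append(f"baseline_dose must be > 0, got {self.baseline_dose}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class TruthRecord:
    symbol: str
    beta: float
    variance_explained: float


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    genes: list[GeneInterval]
    phenotypes: PhenotypeTable
    candidate_genes: list[str]
    truth: list[TruthRecord]
    gene_variants: dict[str, list[str]]


def _gene_interval(g: int) -> GeneInterval:
    chrom = f"sim{g // _GENES_PER_CHROM + 1}"
    slot_start = (g % _GENES_PER_CHROM) * _GENE_SLOT_BP
    # gene body occupies the middle 20 kbp of its 100 kbp slot
    return GeneInterval(
        symbol=f"G{g + 1:04d}",
        chrom=chrom,
        start=slot_start + 40_000,
        end=slot_start + 60_000,
    )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a cohort, fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    genes: list[GeneInterval] = []
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    gene_variants: dict[str, list[str]] = {}
    burdens: dict[str, np.ndarray] = {}
    lo, hi = config.snps_per_gene
    for g in range(config.n_genes):
        gene = _gene_interval(g)
        genes.append(gene)
        n_snps = int(rng.integers(lo, hi + 1))
        mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
        # two haplotypes per sample; adjacent SNPs copy with prob ld_rho
        haps = np.empty((2 * n, n_snps), dtype=np.int8)
        haps[:, 0] = rng.random(2 * n) < mafs[0]
        for k in range(1, n_snps):
            fresh = (rng.random(2 * n) < mafs[k]).astype(np.int8)
            copy = rng.random(2 * n) < config.ld_rho
            haps[:, k] = np.where(copy, haps[:, k - 1], fresh)
        dosage = haps[0::2] + haps[1::2]
        positions = np.linspace(
            gene.start + 1, gene.end, num=n_snps, dtype=int
        )  # 1-based, inside the gene body
        vids = []
        for k in range(n_snps):
            vid = f"snp_{gene.symbol}_{k + 1}"
            vids.append(vid)
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    chrom=gene.chrom,
                    pos=int(positions[k]),
                    ref_allele="A",
                    alt_allele="G",
                )
            )
            columns.append(dosage[:, k].astype(float))
        gene_variants[gene.symbol] = vids
        burdens[gene.symbol] = dosage.sum(axis=1).astype(float)

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosages=np.column_stack(columns),
    )

    genetic = np.zeros(n)
    for g_idx, beta in config.effect_genes:
        genetic += beta * burdens[genes[g_idx].symbol]
    noise = rng.normal(0.0, config.noise_sd, size=n)
    dose = np.maximum(config.baseline_dose + genetic + noise, DOSE_FLOOR)
    phenotypes = PhenotypeTable(doses=dict(zip(sample_ids, dose.tolist())))

    dose_var = float(np.var(dose))
    truth = []
    for g_idx, beta in config.effect_genes:
        sym = genes[g_idx].symbol
        contrib = float(np.var(beta * burdens[sym]))
        truth.append(
            TruthRecord(
                symbol=sym,
                beta=beta,
                variance_explained=contrib / dose_var if dose_var > 0 else 0.0,
            )
        )
    return SimulatedCohort(
        matrix=matrix,
        genes=genes,
        phenotypes=phenotypes,
        candidate_genes=[g.symbol for g in genes],
        truth=truth,
        gene_variants=gene_variants,
    )


def effect_size_for_share(
    share: float, maf: float, n_snps: int, noise_sd: float
) -> float:
    """Beta making a planted gene explain roughly ``share`` of dose variance.

    Burden variance under HWE with independent SNPs at fixed ``maf`` is
    n_snps * 2 * maf * (1 - maf); solve share = b^2 V / (b^2 V + noise^2).
    """
    if not 0.0 < share < 1.0:
        raise ValueError("share must be in (0, 1)")
    v_burden = n_snps * 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(share / (1.0 - share) * noise_sd**2 / v_burden))


def write_cohort(
    cohort: SimulatedCohort, out_dir: str | Path, genotype_format: str = "vcf"
) -> dict[str, Path]:
    """Write the exact input formats the pipeline consumes, plus a truth TSV.

    Deterministic content: same cohort -> byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if genotype_format == "vcf":
        paths["genotypes"] = out / "genotypes.vcf"
        write_vcf(cohort.matrix, paths["genotypes"])
    elif genotype_format == "dosage":
        paths["genotypes"] = out / "dosages.tsv"
        paths["variant_metadata"] = out / "variants.tsv"
        write_dosage_table(
            cohort.matrix, paths["genotypes"], metadata_path=paths["variant_metadata"]
        )
    else:
        raise ValueError(f"genotype_format must be 'vcf' or 'dosage', got '{genotype_format}'")
    paths["bed"] = out / "genes.bed"
    with open(paths["bed"], "w") as fh:
        for g in cohort.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\n")
    paths["phenotypes"] = out / "phenotypes.tsv"
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    paths["gene_list"] = out / "candidate_genes.txt"
    with open(paths["gene_list"], "w") as fh:
        for sym in cohort.candidate_genes:
            fh.write(sym + "\n")
    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("gene_symbol\tbeta\tvariance_explained\n")
        for t in cohort.truth:
            fh.write(f"{t.symbol}\t{t.beta:.10g}\t{t.variance_explained:.10g}\n")
    return paths
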