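"""Readers and writers for genotypes, gene intervals, phenotypes and gene lists.

Genotypes are held as a dense samples x variants dosage grid (count of
alternate alleles per diploid call: 0, 1, 2) with ``NaN`` marking missing
calls.  Gene intervals follow the BED convention (0-based, half-open);
variant positions follow the VCF convention (1-based).  Conversion between
the two happens exactly once, at the variant-to-gene mapping boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan
_VALID_CODES = frozenset({0.0, 1.0, 2.0})


class GenotypeIOError(ValueError):
    """Raised on malformed genotype, interval, phenotype or list input."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant. ``pos`` is 1-based (VCF convention)."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeIOError(
                f"variant {self.variant_id}: pos must be >= 1, got {self.pos}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage grid with codes {0, 1, 2} and NaN for missing."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise GenotypeIOError(
                f"dosage grid shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeIOError("duplicate sample ids")
        vids = [v.variant_id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise GenotypeIOError("duplicate variant ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not set(np.unique(observed)) <= _VALID_CODES:
            bad = sorted(set(np.unique(observed)) - _VALID_CODES)
            raise GenotypeIOError(f"dosage codes outside {{0,1,2}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except AttributeError:
            self._vindex = {v.variant_id: i for i, v in enumerate(self.variants)}
            return self._vindex[variant_id]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus in BED coordinates (0-based half-open)."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenotypeIOError(
                f"gene {self.symbol}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class PhenotypeTable:
    """sample_id -> stable dose in mg/day."""

    doses: dict[str, float]

    def __post_init__(self) -> None:
        for sid, dose in self.doses.items():
            if not dose > 0:
                raise GenotypeIOError(f"sample {sid}: dose must be > 0, got {dose}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.doses)

    def doses_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.doses[s] for s in sample_ids], dtype=float)


@dataclass(frozen=True)
class OverrideEntry:
    """A manual variant -> gene assignment applied regardless of position."""

    variant_id: str
    symbol: str


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a diploid VCF (GT field) into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles per call; any call containing a
    missing allele becomes missing.  Phased and unphased separators are
    treated identically.  Multi-allelic records and non-diploid calls are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError(f"{path}: VCF has no samples")
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeIOError(
                f"{path}: multi-allelic site {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}) is not supported"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        col = np.empty(len(samples), dtype=float)
        for i, call in enumerate(rec.genotypes):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise GenotypeIOError(
                    f"{path}: non-diploid call for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        columns.append(col)
    if not variants:
        raise GenotypeIOError(f"{path}: VCF contains no variant records")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def read_dosage_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read the TSV dosage dialect: first column sample id, one column per
    variant, body of {0, 1, 2, NA}.

    An optional companion metadata TSV (columns ``variant_id``, ``chrom``,
    ``pos``, optionally ``ref_allele``/``alt_allele``) supplies variant
    coordinates; without it variants are placed on a pseudo-chromosome in
    column order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise GenotypeIOError(f"{path}: expected sample column plus >=1 variant column")
    sample_col = df.columns[0]
    sample_ids = df[sample_col].tolist()
    dup = df[sample_col][df[sample_col].duplicated()]
    if len(dup):
        raise GenotypeIOError(f"{path}: duplicate sample id '{dup.iloc[0]}'")
    variant_ids = list(df.columns[1:])
    dosages = np.empty((len(sample_ids), len(variant_ids)), dtype=float)
    for j, vid in enumerate(variant_ids):
        for i, raw in enumerate(df[vid]):
            value = raw.strip()
            if value in ("NA", ""):
                dosages[i, j] = MISSING
            elif value in ("0", "1", "2"):
                dosages[i, j] = float(value)
            else:
                raise GenotypeIOError(
                    f"{path}: invalid dosage '{raw}' at sample "
                    f"'{sample_ids[i]}', variant '{vid}'"
                )
    meta: Mapping[str, VariantRecord] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype={"chrom": str})
        meta = {
            str(row.variant_id): VariantRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(getattr(row, "ref_allele", "N")),
                alt_allele=str(getattr(row, "alt_allele", "N")),
            )
            for row in mdf.itertuples(index=False)
        }
    variants = []
    for j, vid in enumerate(variant_ids):
        if vid in meta:
            variants.append(meta[vid])
        else:
            variants.append(VariantRecord(variant_id=vid, chrom="un", pos=j + 1))
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def write_dosage_table(
    matrix: GenotypeMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a matrix in the dosage-table dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.variant_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "NA" if np.isnan(d) else str(int(d)) for d in matrix.dosages[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            fh.write("variant_id\tchrom\tpos\tref_allele\talt_allele\n")
            for v in matrix.variants:
                fh.write(
                    f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\n"
                )


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read BED4 gene intervals; duplicate symbols on the same chromosome are
    merged to their union interval, duplicates across chromosomes are an error."""
    by_symbol: dict[str, GeneInterval] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise GenotypeIOError(
                    f"{path}:{lineno}: BED needs >=4 columns (chrom, start, end, name)"
                )
            chrom, start_s, end_s, symbol = fields[:4]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise GenotypeIOError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            if symbol in by_symbol:
                prev = by_symbol[symbol]
                if prev.chrom != chrom:
                    raise GenotypeIOError(
                        f"{path}:{lineno}: gene {symbol} appears on both "
                        f"{prev.chrom} and {chrom}"
                    )
                by_symbol[symbol] = GeneInterval(
                    symbol, chrom, min(prev.start, start), max(prev.end, end)
                )
            else:
                by_symbol[symbol] = GeneInterval(symbol, chrom, start, end)
                order.append(symbol)
    return [by_symbol[s] for s in order]


def read_gene_list(
    path: str | Path, annotation_symbols: Iterable[str] | None = None
) -> list[str]:
    """Read a candidate-gene list (one symbol per line, '#' comments).

    Returns a deduplicated, order-preserving list.  If ``annotation_symbols``
    is given, symbols absent from it are dropped with a warning.  An empty
    result is an error.
    """
    seen: set[str] = set()
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym or sym in seen:
                continue
            seen.add(sym)
            symbols.append(sym)
    if annotation_symbols is not None:
        known = set(annotation_symbols)
        dropped = [s for s in symbols if s not in known]
        if dropped:
            logger.warning(
                "dropping %d gene symbols absent from the annotation: %s",
                len(dropped),
                ", ".join(dropped),
            )
        symbols = [s for s in symbols if s in known]
    if not symbols:
        raise GenotypeIOError(f"{path}: knowledge filter removed all genes")
    return symbols


def read_phenotypes(
    path: str | Path,
    known_samples: Iterable[str] | None = None,
    allow_extra: bool = False,
) -> PhenotypeTable:
    """Read the phenotype TSV (columns ``sample_id``, ``dose_mg_per_day``).

    Rows for samples absent from ``known_samples`` are rejected, or dropped
    with a warning when ``allow_extra`` is set.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "dose_mg_per_day"}
    if not required <= set(df.columns):
        raise GenotypeIOError(
            f"{path}: phenotype table needs columns {sorted(required)}"
        )
    doses = dict(zip(df["sample_id"].astype(str), df["dose_mg_per_day"].astype(float)))
    if len(doses) != len(df):
        raise GenotypeIOError(f"{path}: duplicate sample ids in phenotype table")
    if known_samples is not None:
        known = set(known_samples)
        extra = [s for s in doses if s not in known]
        if extra:
            if not allow_extra:
                raise GenotypeIOError(
                    f"{path}: phenotype rows for unknown samples: {', '.join(extra)}"
                )
            logger.warning(
                "dropping %d phenotype rows for samples not in the genotype "
                "matrix: %s", len(extra), ", ".join(extra),
            )
            doses = {s: d for s, d in doses.items() if s in known}
    return PhenotypeTable(doses=doses)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdose_mg_per_day\n")
        for sid, dose in table.doses.items():
            fh.write(f"{sid}\t{dose:.6g}\n")


def read_overrides(
    path: str | Path, annotation_symbols: Iterable[str] | None = None
) -> list[OverrideEntry]:
    """Read a TSV of manual (variant_id, gene_symbol) assignments."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "gene_symbol"}
    if not required <= set(df.columns):
        raise GenotypeIOError(f"{path}: override table needs columns {sorted(required)}")
    entries = [
        OverrideEntry(variant_id=row.variant_id, symbol=row.gene_symbol)
        for row in df.itertuples(index=False)
    ]
    if annotation_symbols is not None:
        known = set(annotation_symbols)
        for e in entries:
            if e.symbol not in known:
                raise GenotypeIOError(
                    f"{path}: override gene '{e.symbol}' not in the annotation"
                )
    return entries


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only calls (text, uncompressed)."""
    chroms: list[str] = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    code_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        order = sorted(
            range(matrix.n_variants),
            key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos),
        )
        for j in order:
            v = matrix.variants[j]
            gts = [
                "./." if np.isnan(d) else code_to_gt[d] for d in matrix.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
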