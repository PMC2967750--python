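"""Per-patient, per-gene scores from negative-log genotype (or allele)
frequencies.

For a gene with SNP set K, the score of patient i is

    genotype mode:  sum over k in K of -ln( freq of patient i's genotype at k )
    allele mode:    sum over k in K, over both alleles of patient i at k, of
                    -ln( freq of that allele )

Frequencies are estimated in-cohort over non-missing calls, with no
leave-one-out and no pseudocount, so a patient's own observed genotype always
has frequency >= 1/n and the score is finite.  Missing genotypes contribute 0
and are counted in a per-score missing tally.  Scores are in nats; the log
base only rescales scores and cannot change any downstream test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_mapping import SNPGeneMap
from .genotype_io import GenotypeMatrix

MODES = ("genotype", "allele")


class ScoringError(ValueError):
    pass


@dataclass
class FrequencyTable:
    """Per-variant genotype and allele frequencies over non-missing calls."""

    variant_ids: list[str]
    genotype_freqs: np.ndarray  # (V, 3): freq of codes 0, 1, 2
    allele_freqs: np.ndarray  # (V, 2): ref, alt
    n_observed: np.ndarray  # (V,)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def genotype_freq(self, variant_id: str, code: int) -> float:
        return float(self.genotype_freqs[self._index[variant_id], code])

    def allele_freq(self, variant_id: str, allele: int) -> float:
        return float(self.allele_freqs[self._index[variant_id], allele])


def estimate_frequencies(matrix: GenotypeMatrix) -> FrequencyTable:
    """Count-based genotype and allele frequencies per variant.

    genotype freq = count of that code / non-missing n; allele freq =
    allele count / (2 x non-missing n).  A variant with zero non-missing
    calls is an error.
    """
    V = matrix.n_variants
    gfreq = np.zeros((V, 3))
    afreq = np.zeros((V, 2))
    n_obs = np.zeros(V, dtype=int)
    for j in range(V):
        col = matrix.dosages[:, j]
        obs = col[~np.isnan(col)]
        n = obs.size
        if n == 0:
            raise ScoringError(
                f"variant {matrix.variants[j].variant_id} has zero non-missing calls"
            )
        n_obs[j] = n
        counts = np.array([(obs == c).sum() for c in (0.0, 1.0, 2.0)], dtype=float)
        gfreq[j] = counts / n
        alt_count = float(obs.sum())
        afreq[j, 1] = alt_count / (2 * n)
        afreq[j, 0] = 1.0 - afreq[j, 1]
    return FrequencyTable(
        variant_ids=matrix.variant_ids,
        genotype_freqs=gfreq,
        allele_freqs=afreq,
        n_observed=n_obs,
    )


def _term(code: float, freqs: FrequencyTable, vid: str, mode: str) -> float:
    if mode == "genotype":
        f = freqs.genotype_freq(vid, int(code))
        if f == 0.0:
            raise ScoringError(
                f"observed genotype {int(code)} at {vid} has estimated frequency 0; "
                "supply in-cohort frequencies or use a frequency floor"
            )
        return -float(np.log(f))
    # allele mode: a dosage d carries d copies of alt and 2-d copies of ref
    total = 0.0
    for allele, copies in ((1, int(code)), (0, 2 - int(code))):
        if copies == 0:
            continue
        f = freqs.allele_freq(vid, allele)
        if f == 0.0:
            raise ScoringError(
                f"observed allele {allele} at {vid} has estimated frequency 0; "
                "supply in-cohort frequencies or use a frequency floor"
            )
        total += -copies * float(np.log(f))
    return total


def phap_score(
    patient_dosages: Sequence[float],
    freqs: FrequencyTable,
    variant_set: Sequence[str],
    mode: str = "genotype",
) -> float:
    """Score one patient over one gene's variant set (nats, >= 0).

    ``patient_dosages`` is aligned with ``variant_set``; NaN entries
    (missing calls) contribute 0.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got '{mode}'")
    if not len(variant_set):
        raise ScoringError("variant_set must be non-empty")
    score = 0.0
    for code, vid in zip(patient_dosages, variant_set, strict=True):
        if np.isnan(code):
            continue
        score += _term(code, freqs, vid, mode)
    return score


@dataclass
class GeneScoreMatrix:
    """Patients x genes score grid (nats) with a per-cell missing-call tally."""

    sample_ids: list[str]
    gene_symbols: list[str]
    scores: np.ndarray
    mode: str
    missing_counts: np.ndarray

    def __post_init__(self) -> None:
        self._gindex = {g: i for i, g in enumerate(self.gene_symbols)}

    def column(self, gene_symbol: str) -> np.ndarray:
        return self.scores[:, self._gindex[gene_symbol]]

    def columns(self, gene_symbols: Sequence[str]) -> np.ndarray:
        return self.scores[:, [self._gindex[g] for g in gene_symbols]]


def score_matrix(
    matrix: GenotypeMatrix,
    snp_map: SNPGeneMap,
    freqs: FrequencyTable | None = None,
    mode: str = "genotype",
) -> GeneScoreMatrix:
    """One score per (patient, mapped gene); a variant shared by several
    genes contributes its term to each of them."""
    if not snp_map.gene_variants:
        raise ScoringError("SNP-to-gene map is empty")
    if freqs is None:
        freqs = estimate_frequencies(matrix)
    genes = snp_map.gene_symbols
    S = matrix.n_samples
    scores = np.zeros((S, len(genes)))
    missing = np.zeros((S, len(genes)), dtype=int)
    for g_idx, gene in enumerate(genes):
        vids = snp_map.gene_variants[gene]
        cols = [matrix.variant_index(v) for v in vids]
        sub = matrix.dosages[:, cols]
        for i in range(S):
            scores[i, g_idx] = phap_score(sub[i], freqs, vids, mode=mode)
            missing[i, g_idx] = int(np.isnan(sub[i]).sum())
    return GeneScoreMatrix(
        sample_ids=list(matrix.sample_ids),
        gene_symbols=list(genes),
        scores=scores,
        mode=mode,
        missing_counts=missing,
    )


def write_scores(gsm: GeneScoreMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode={gsm.mode}\n")
        fh.write("sample_id\t" + "\t".join(gsm.gene_symbols) + "\n")
        for i, sid in enumerate(gsm.sample_ids):
            fh.write(
                sid + "\t" + "\t".join(f"{v:.12g}" for v in gsm.scores[i]) + "\n"
            )


def read_scores(path: str | Path) -> GeneScoreMatrix:
    import pandas as pd

    mode = "genotype"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# mode="):
            mode = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = list(df.columns[1:])
    return GeneScoreMatrix(
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
        gene_symbols=genes,
        scores=df[genes].to_numpy(dtype=float),
        mode=mode,
        missing_counts=np.zeros((len(df), len(genes)), dtype=int),
    )


def write_frequencies(freqs: FrequencyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant_id\tfreq_g0\tfreq_g1\tfreq_g2\tfreq_ref\tfreq_alt\tn_observed\n"
        )
        for i, vid in enumerate(freqs.variant_ids):
            g = freqs.genotype_freqs[i]
            a = freqs.allele_freqs[i]
            fh.write(
                f"{vid}\t{g[0]:.12g}\t{g[1]:.12g}\t{g[2]:.12g}\t"
                f"{a[0]:.12g}\t{a[1]:.12g}\t{freqs.n_observed[i]}\n"
            )
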