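"""Univariate linear-regression screens with Bonferroni correction.

Each feature (single-SNP dosage or gene score) is regressed against the
continuous dose by ordinary least squares; the two-sided p-value comes from
the t distribution with n-2 degrees of freedom on the slope.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, PhenotypeTable
from .phap_scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)

MIN_P = float(np.nextafter(0, 1))  # degenerate perfect-fit p, flagged in output


class ZeroVariancePredictor(ValueError):
    """The predictor is constant on the pairwise-complete samples."""


class UnivariateFit(NamedTuple):
    slope: float
    intercept: float
    t_stat: float
    df: int
    p_value: float
    n_used: int


def fit_univariate(x: Sequence[float], y: Sequence[float]) -> UnivariateFit:
    """OLS of y on x over pairwise-complete observations.

    Requires n >= 3 complete pairs and non-constant x.  A perfect fit
    (zero residual variance) reports the smallest positive p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ZeroVariancePredictor("zero-variance predictor")
    sxy = float(xc @ (y - y.mean()))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    df = n - 2
    ss_resid = float(((y - intercept - slope * x) ** 2).sum())
    if ss_resid <= 0.0:
        return UnivariateFit(slope, intercept, np.inf, df, MIN_P, n)
    se = np.sqrt(ss_resid / df / sxx)
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    p = max(p, MIN_P)
    return UnivariateFit(slope, intercept, t, df, p, n)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m for family-wise error control."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    return alpha / m


def _association_table(
    rows: list[dict], m: int, alpha: float, feature_col: str
) -> pd.DataFrame:
    threshold = bonferroni_threshold(alpha, m)
    df = pd.DataFrame(
        rows,
        columns=[
            feature_col, "slope", "intercept", "t_stat", "df",
            "p_value", "n_used", "significant_after_correction",
        ],
    )
    if len(df):
        df["significant_after_correction"] = df["p_value"] <= threshold
        df = df.sort_values(
            ["p_value", feature_col], kind="mergesort"
        ).reset_index(drop=True)
    df.attrs.update({"m": m, "alpha": alpha, "threshold": threshold})
    return df


def run_snp_association(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    snp_set: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One OLS row per SNP in ``snp_set``, sorted ascending by p; Bonferroni
    m equals |snp_set|.  Zero-variance SNPs are skipped with a log record."""
    if not len(snp_set):
        raise ValueError("snp_set must be non-empty")
    samples = [s for s in matrix.sample_ids if s in phenotypes.doses]
    idx = [matrix.sample_ids.index(s) for s in samples]
    y = phenotypes.doses_for(samples)
    rows = []
    for vid in snp_set:
        x = matrix.column(vid)[idx]
        try:
            fit = fit_univariate(x, y)
        except ZeroVariancePredictor:
            logger.warning("zero-variance predictor: SNP %s skipped", vid)
            continue
        rows.append(dict(variant_id=vid, **fit._asdict()))
    return _association_table(rows, m=len(snp_set), alpha=alpha, feature_col="variant_id")


def run_gene_association(
    gene_scores: GeneScoreMatrix,
    phenotypes: PhenotypeTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One OLS row per gene-score column, sorted ascending by p; Bonferroni
    m equals the number of genes."""
    samples = [s for s in gene_scores.sample_ids if s in phenotypes.doses]
    idx = [gene_scores.sample_ids.index(s) for s in samples]
    y = phenotypes.doses_for(samples)
    rows = []
    for gene in gene_scores.gene_symbols:
        x = gene_scores.column(gene)[idx]
        try:
            fit = fit_univariate(x, y)
        except ZeroVariancePredictor:
            logger.warning("zero-variance gene-score: gene %s skipped", gene)
            continue
        rows.append(dict(gene_symbol=gene, **fit._asdict()))
    return _association_table(
        rows, m=len(gene_scores.gene_symbols), alpha=alpha, feature_col="gene_symbol"
    )


def write_association(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# m={table.attrs['m']} alpha={table.attrs['alpha']:.6g} "
            f"threshold={table.attrs['threshold']:.6g}\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
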