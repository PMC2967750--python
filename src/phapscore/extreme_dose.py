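"""Extreme-dose dichotomization and per-gene two-sample t-test screens.

Patients are split into an extreme class and its complement at an inclusive
dose threshold (low: dose <= t; high: dose >= t).  Gene-score distributions
of the two classes are compared with a pooled-variance Student's t-test
(two-sided), Bonferroni-corrected over the genes actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import MIN_P, bonferroni_threshold
from .genotype_io import PhenotypeTable
from .phap_scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("low", "high")


class GroupTooSmall(ValueError):
    pass


@dataclass
class DoseLabels:
    """sample_id -> positive (extreme) / negative class, plus the definition."""

    labels: dict[str, bool]
    threshold: float
    direction: str

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def vector_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids], dtype=bool)


def dichotomize(
    phenotypes: PhenotypeTable, threshold: float, direction: str
) -> DoseLabels:
    """Label each patient positive iff dose <= threshold (low) or
    dose >= threshold (high); both classes must be non-empty."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got '{direction}'")
    if direction == "low":
        labels = {s: d <= threshold for s, d in phenotypes.doses.items()}
    else:
        labels = {s: d >= threshold for s, d in phenotypes.doses.items()}
    n_pos = sum(labels.values())
    n_neg = len(labels) - n_pos
    if n_pos == 0:
        raise ValueError(f"empty positive class at {direction} threshold {threshold}")
    if n_neg == 0:
        raise ValueError(f"empty negative class at {direction} threshold {threshold}")
    logger.info(
        "%s-dose dichotomization at %g mg/day: %d positive, %d negative",
        direction, threshold, n_pos, n_neg,
    )
    return DoseLabels(labels=labels, threshold=threshold, direction=direction)


class TTestResult(NamedTuple):
    t_stat: float
    df: int
    p_value: float


def gene_ttest(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test of the positive vs negative score distributions.

    Default is the classic pooled-variance Student's t with df = n1+n2-2;
    ``welch`` switches to the unequal-variance form.  Zero pooled variance
    with equal means gives t = 0, p = 1.
    """
    a = np.asarray(scores_pos, dtype=float)
    b = np.asarray(scores_neg, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise GroupTooSmall(f"each group needs >= 2 scores, got {n1} and {n2}")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        # Welch-Satterthwaite df, rounded down for reporting
        v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
        df = int((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
        return TTestResult(float(t), df, float(p))
    df = n1 + n2 - 2
    pooled_var = (
        (n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)
    ) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf if diff > 0 else -np.inf, df, MIN_P)
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = max(2.0 * float(stats.t.sf(abs(t), df)), MIN_P)
    return TTestResult(float(t), df, p)


def discover_features(
    gene_scores: GeneScoreMatrix,
    labels: DoseLabels,
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Per-gene t-tests of positive vs negative score distributions.

    Returns (strict_set, nominal_set, table): strict_set holds genes passing
    Bonferroni at ``alpha`` over the m genes actually tested; nominal_set
    holds genes with raw p <= 0.05 (a superset of strict_set).  The table is
    sorted ascending by p.
    """
    samples = [s for s in gene_scores.sample_ids if s in labels.labels]
    idx = [gene_scores.sample_ids.index(s) for s in samples]
    is_pos = labels.vector_for(samples)
    rows = []
    for gene in gene_scores.gene_symbols:
        col = gene_scores.column(gene)[idx]
        pos, neg = col[is_pos], col[~is_pos]
        try:
            res = gene_ttest(pos, neg, welch=welch)
        except GroupTooSmall:
            logger.warning("gene %s skipped: a class has < 2 scores", gene)
            continue
        rows.append(
            dict(
                gene_symbol=gene,
                t_stat=res.t_stat,
                df=res.df,
                p_value=res.p_value,
                mean_positive=float(pos.mean()),
                mean_negative=float(neg.mean()),
            )
        )
    if not rows:
        raise ValueError("no testable genes")
    m = len(rows)
    threshold = bonferroni_threshold(alpha, m)
    table = pd.DataFrame(rows)
    table["significant_after_correction"] = table["p_value"] <= threshold
    table["nominal_significant"] = table["p_value"] <= 0.05
    table = table.sort_values(
        ["p_value", "gene_symbol"], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs.update({"m": m, "alpha": alpha, "threshold": threshold})
    strict = table.loc[table["significant_after_correction"], "gene_symbol"].tolist()
    nominal = table.loc[table["nominal_significant"], "gene_symbol"].tolist()
    logger.info(
        "%s-dose screen: m=%d, threshold=%.3g, %d strict, %d nominal",
        labels.direction, m, threshold, len(strict), len(nominal),
    )
    return strict, nominal, table


def write_ttest_table(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# m={table.attrs['m']} alpha={table.attrs['alpha']:.6g} "
            f"threshold={table.attrs['threshold']:.6g}\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
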