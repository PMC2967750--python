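"""Greedy pruning of variants by pairwise dosage r-squared.

r² is the squared Pearson correlation of dosage vectors (composite-genotype
LD, no phasing).  The pruner sweeps variants in (chrom, pos, variant_id)
order and keeps a variant iff its r² with every already-kept variant on the
same chromosome is at or below the ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PruneResult:
    """Outcome of an LD prune: kept ids plus a drop log of
    (dropped_id, blocking_kept_id, r2) triples."""

    kept_variant_ids: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def dropped_ids(self) -> list[str]:
        return [d[0] for d in self.dropped]


def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples.

    Returns ``None`` ("not computable") when fewer than 2 complete pairs
    remain or either vector is constant on the complete pairs.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        return None
    x = a[mask] - a[mask].mean()
    y = b[mask] - b[mask].mean()
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx == 0.0 or syy == 0.0:
        return None
    r2 = float(x @ y) ** 2 / (sxx * syy)
    return min(r2, 1.0)  # guard rounding past 1


def prune(
    matrix: GenotypeMatrix,
    max_r2: float = 0.2,
    window_bp: int | None = None,
) -> PruneResult:
    """Greedy first-kept-wins sweep in genomic order.

    ``window_bp`` optionally restricts r² checks to kept variants within that
    many base pairs (for large inputs); by default all same-chromosome pairs
    are checked.  Not-computable pairs are treated as r² = 0 (independence)
    and logged.
    """
    if matrix.n_variants == 0:
        raise ValueError("cannot prune an empty genotype matrix")
    if not 0.0 <= max_r2 <= 1.0:
        raise ValueError(f"max_r2 must be in [0, 1], got {max_r2}")
    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (
            matrix.variants[j].chrom,
            matrix.variants[j].pos,
            matrix.variants[j].variant_id,
        ),
    )
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    dropped: list[tuple[str, str, float]] = []
    n_not_computable = 0
    for j in order:
        vj = matrix.variants[j]
        blocker: tuple[str, float] | None = None
        for i in kept_by_chrom.get(vj.chrom, ()):
            vi = matrix.variants[i]
            if window_bp is not None and abs(vj.pos - vi.pos) > window_bp:
                continue
            r2 = pairwise_r2(matrix.dosages[:, i], matrix.dosages[:, j])
            if r2 is None:
                n_not_computable += 1
                continue  # treated as r2 = 0
            if r2 > max_r2:
                blocker = (vi.variant_id, r2)
                break
        if blocker is None:
            kept.append(j)
            kept_by_chrom.setdefault(vj.chrom, []).append(j)
        else:
            dropped.append((vj.variant_id, blocker[0], blocker[1]))
    if n_not_computable:
        logger.info(
            "%d variant pairs had no computable r2 (constant or <2 complete "
            "pairs); treated as independent", n_not_computable,
        )
    kept_ids = [matrix.variants[j].variant_id for j in sorted(kept)]
    return PruneResult(kept_variant_ids=kept_ids, dropped=dropped)
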