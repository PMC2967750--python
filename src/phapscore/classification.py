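"""Logistic-regression classification of extreme-dose classes from gene
scores: stratified k-fold cross-validation, ROC/AUROC on pooled out-of-fold
probabilities, and an empirical p-value from classifiers trained on random
gene sets.

The logistic fit is maximum likelihood with a tiny ridge penalty (default
1e-6, non-intercept weights only) to stabilize quasi-separated small-cohort
fits; set ``ridge=0`` for pure ML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .phap_scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6


class ConvergenceError(RuntimeError):
    pass


def fit_logistic(
    features: np.ndarray,
    labels: Sequence[bool],
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Newton-Raphson fit of a logistic model; returns [intercept, weights...].

    The ridge penalty 0.5 * ridge * ||w||^2 applies to non-intercept weights
    only.  Deterministic for fixed input.  Raises :class:`ConvergenceError`
    (with a separation diagnosis) if the iteration cap is reached.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("labels length must match feature rows")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    penalty = np.zeros(p + 1)
    penalty[1:] = ridge

    def neg_ll(b: np.ndarray) -> float:
        eta = Xd @ b
        # log(1 + exp(eta)) - y*eta, computed stably
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * (penalty * b * b).sum()
        )

    obj = neg_ll(beta)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (mu - y) + penalty * beta
        if np.max(np.abs(grad)) < tol:
            return beta
        hess = (Xd * w[:, None]).T @ Xd + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving line search on the penalized objective
        scale = 1.0
        for _ in range(40):
            new_beta = beta - scale * step
            new_obj = neg_ll(new_beta)
            if new_obj <= obj:
                break
            scale *= 0.5
        moved = np.max(np.abs(new_beta - beta))
        improved = obj - new_obj
        beta, obj = new_beta, new_obj
        # under quasi-separation the ridge optimum has huge weights and the
        # gradient criterion is unreachable at double precision; accept a
        # stalled, non-improving iterate as converged
        if moved < 1e-8 * (1.0 + np.max(np.abs(beta))) or improved < tol * (1.0 + abs(obj)):
            return beta
    # not converged: diagnose separation
    eta = Xd @ beta
    preds = eta > 0
    separated = bool(np.all(preds == (y == 1)))
    raise ConvergenceError(
        "logistic fit did not converge"
        + (
            "; the classes appear linearly separable (consider a larger ridge)"
            if separated
            else ""
        )
    )


def predict_proba(coef: np.ndarray, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = coef[0] + X @ coef[1:]
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def cross_validate(
    features: np.ndarray,
    labels: Sequence[bool],
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Stratified k-fold out-of-fold probabilities: every sample is scored
    exactly once, by a model never trained on it.

    If the rarer class has fewer than k members, k is lowered to that count
    (minimum 2) with a warning.  Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=bool)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    min_class = int(min(y.sum(), (~y).sum()))
    if min_class < 2:
        raise ValueError("need >= 2 samples per class")
    if min_class < k:
        logger.warning(
            "rarer class has %d members < k=%d folds; lowering k to %d",
            min_class, k, min_class,
        )
        k = max(2, min_class)
    probs = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        coef = fit_logistic(X[train], y[train], ridge=ridge)
        probs[test] = predict_proba(coef, X[test])
    assert not np.isnan(probs).any()
    return probs


def auroc(probs: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUROC: the fraction of (positive, negative) pairs ranked
    correctly, ties counted one half.  Equals the trapezoidal ROC area."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(p)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(probs: Sequence[float], labels: Sequence[bool]) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) points from (0,0) to (1,1), one step per
    distinct threshold."""
    from sklearn.metrics import roc_curve

    y = np.asarray(labels, dtype=int)
    fpr, tpr, _ = roc_curve(y, np.asarray(probs, dtype=float), drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


@dataclass
class ClassifierEval:
    """Cross-validated evaluation of one feature-gene set."""

    feature_genes: list[str]
    out_of_fold_probs: np.ndarray
    roc_points: list[tuple[float, float]]
    auroc: float
    cv_seed: int
    empirical_p: float | None = None


def evaluate_gene_classifier(
    gene_scores: GeneScoreMatrix,
    feature_genes: Sequence[str],
    labels: Sequence[bool],
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> ClassifierEval:
    X = gene_scores.columns(list(feature_genes))
    probs = cross_validate(X, labels, k=k, seed=seed, ridge=ridge)
    return ClassifierEval(
        feature_genes=list(feature_genes),
        out_of_fold_probs=probs,
        roc_points=roc_points(probs, labels),
        auroc=auroc(probs, labels),
        cv_seed=seed,
    )


def empirical_significance(
    observed_auroc: float,
    gene_scores: GeneScoreMatrix,
    gene_pool: Sequence[str],
    n_features: int,
    labels: Sequence[bool],
    B: int = 100,
    seed: int = 0,
    k: int = 10,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Empirical p of an observed AUROC against B classifiers trained on
    random gene subsets of the same size, drawn without replacement within a
    draw: p = (1 + #{null AUROC >= observed}) / (1 + B)."""
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    pool = list(gene_pool)
    if n_features > len(pool):
        raise ValueError(
            f"gene pool ({len(pool)}) smaller than n_features ({n_features})"
        )
    rng = np.random.default_rng(seed)
    count = 0
    for b in range(B):
        subset = [pool[i] for i in rng.choice(len(pool), size=n_features, replace=False)]
        X = gene_scores.columns(subset)
        probs = cross_validate(
            X, labels, k=k, seed=int(rng.integers(0, 2**31 - 1)), ridge=ridge
        )
        if auroc(probs, labels) >= observed_auroc:
            count += 1
    return (1 + count) / (1 + B)


def write_roc(points: Sequence[tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
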