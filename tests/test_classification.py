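import numpy as np
import pytest
from scipy import optimize

from phapscore.classification import (
    auroc,
    cross_validate,
    empirical_significance,
    evaluate_gene_classifier,
    fit_logistic,
    predict_proba,
    roc_points,
)
from phapscore.phap_scoring import GeneScoreMatrix


def _gsm(scores, genes):
    scores = np.asarray(scores, dtype=float)
    return GeneScoreMatrix(
        sample_ids=[f"s{i + 1}" for i in range(scores.shape[0])],
        gene_symbols=genes,
        scores=scores,
        mode="genotype",
        missing_counts=np.zeros(scores.shape, dtype=int),
    )


def oracle_logistic(X, y, ridge=1e-6):
    """Independent oracle: BFGS minimization of the penalized neg log-lik."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(X)), X])
    y = np.asarray(y, dtype=float)
    pen = np.zeros(Xd.shape[1])
    pen[1:] = ridge

    def f(b):
        eta = Xd @ b
        return np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * b * b)

    def grad(b):
        mu = 1.0 / (1.0 + np.exp(-(Xd @ b)))
        return Xd.T @ (mu - y) + pen * b

    res = optimize.minimize(f, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 2000})
    return res.x


class TestFitLogistic:
    def test_null_weights_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.random(200) < 0.5
        coef = fit_logistic(x, y)
        assert abs(coef[1]) < 0.1
        assert abs(coef[0]) < 0.3

    def test_separable_preserves_feature_ordering(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(2, 3, 10)])
        y = np.concatenate([np.zeros(10), np.ones(10)]).astype(bool)
        coef = fit_logistic(x, y)
        probs = predict_proba(coef, x)
        assert np.array_equal(np.argsort(probs), np.argsort(x))

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(30, 80))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            logits = X @ rng.normal(size=X.shape[1]) * 0.8
            y = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))
            if min(y.sum(), (~y).sum()) < 2:
                continue
            coef = fit_logistic(X, y)
            ref = oracle_logistic(X, y)
            np.testing.assert_allclose(coef, ref, atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            fit_logistic(rng.normal(size=10), np.ones(10, dtype=bool))


class TestCrossValidate:
    def test_every_sample_scored_deterministically(self, rng):
        x = rng.normal(size=20)
        y = np.array([True, False] * 10)
        p1 = cross_validate(x, y, k=10, seed=7)
        p2 = cross_validate(x, y, k=10, seed=7)
        assert not np.isnan(p1).any()
        np.testing.assert_array_equal(p1, p2)

    def test_seed_changes_folds(self, rng):
        x = rng.normal(size=30)
        y = rng.random(30) < 0.5
        if min(y.sum(), (~y).sum()) < 3:
            y[:3] = ~y[:3]
        p1 = cross_validate(x, y, k=3, seed=1)
        p2 = cross_validate(x, y, k=3, seed=2)
        assert not np.array_equal(p1, p2)

    def test_k_lowered_for_rare_class(self, rng, caplog):
        x = rng.normal(size=20)
        y = np.zeros(20, dtype=bool)
        y[:3] = True
        with caplog.at_level("WARNING"):
            probs = cross_validate(x, y, k=10, seed=0)
        assert "lowering k" in caplog.text
        assert not np.isnan(probs).any()

    def test_strong_separation_gives_high_auroc(self, rng):
        n = 60
        y = np.concatenate([np.ones(20), np.zeros(40)]).astype(bool)
        x = rng.normal(size=n)
        x[y] += 3.0  # 3 pooled SDs
        probs = cross_validate(x, y, k=10, seed=0)
        assert auroc(probs, y) > 0.95

    def test_bad_k_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            cross_validate(rng.normal(size=10), np.array([True] * 5 + [False] * 5), k=1)


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed_ordering(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_tie_counted_half(self):
        # pairs: (.9,.8)=1 (.9,.1)=1 (.8,.8)=.5 (.8,.1)=1 -> 3.5/4
        assert auroc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_label_flip_identity(self, rng):
        probs = rng.random(30)
        y = rng.random(30) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert auroc(probs, y) + auroc(probs, ~y) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        probs = rng.random(25)
        y = rng.random(25) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert auroc(np.exp(5 * probs), y) == pytest.approx(auroc(probs, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auroc([0.1, 0.9], [1, 1])

    def test_equals_trapezoidal_roc_area(self, rng):
        for _ in range(10):
            probs = rng.random(40)
            y = rng.random(40) < 0.5
            if y.all() or not y.any():
                y[0] = ~y[0]
            pts = roc_points(probs, y)
            fpr = np.array([p[0] for p in pts])
            tpr = np.array([p[1] for p in pts])
            area = float(np.trapezoid(tpr, fpr))
            assert auroc(probs, y) == pytest.approx(area, abs=1e-10)


class TestRocPoints:
    def test_endpoints_and_monotonicity(self, rng):
        probs = rng.random(30)
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        pts = roc_points(probs, y)
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr)
        assert tpr == sorted(tpr)


class TestEmpiricalSignificance:
    def _setup(self, rng, n=40, n_genes=8):
        scores = rng.normal(size=(n, n_genes))
        genes = [f"G{j}" for j in range(n_genes)]
        y = np.concatenate(
            [np.ones(n // 2), np.zeros(n - n // 2)]
        ).astype(bool)
        return _gsm(scores, genes), genes, y

    def test_floor_is_one_over_b_plus_one(self, rng):
        gsm, genes, y = self._setup(rng)
        # observed above any attainable AUROC -> count 0 -> p = 1/(B+1)
        p = empirical_significance(1.1, gsm, genes, 2, y, B=100, seed=0, k=4)
        assert p == pytest.approx(1 / 101)
        assert p < 0.01

    def test_observed_below_every_null_gives_one(self, rng):
        gsm, genes, y = self._setup(rng)
        p = empirical_significance(-0.1, gsm, genes, 2, y, B=25, seed=0, k=4)
        assert p == 1.0

    def test_pool_too_small_rejected(self, rng):
        gsm, genes, y = self._setup(rng)
        with pytest.raises(ValueError, match="pool"):
            empirical_significance(0.5, gsm, genes, 99, y, B=5, seed=0)

    def test_calibration_approximately_uniform(self, rng):
        # observed statistic drawn from the same null -> p uniform on the grid
        # {1/(B+1), ..., 1}; check the exact discrete moments
        gsm, genes, y = self._setup(rng, n=36, n_genes=10)
        B = 19
        reps = 60
        pvals = []
        for rep in range(reps):
            obs_gene = [genes[int(rng.integers(len(genes)))]]
            probs = cross_validate(
                gsm.columns(obs_gene), y, k=4, seed=int(rng.integers(1 << 30))
            )
            obs = auroc(probs, y)
            pvals.append(
                empirical_significance(
                    obs, gsm, genes, 1, y, B=B, seed=int(rng.integers(1 << 30)), k=4
                )
            )
        pvals = np.asarray(pvals)
        expected_mean = (B + 2) / (2 * (B + 1))  # 0.525 at B=19
        assert abs(pvals.mean() - expected_mean) < 0.10
        # lower-tail mass: P(p <= 0.25) would be 5/20 under exchangeability
        assert abs((pvals <= 0.25).mean() - 0.25) < 0.17


class TestEndToEndRecovery:
    def test_planted_separating_genes_beat_random_gene_null(self, rng):
        from phapscore.extreme_dose import dichotomize, discover_features
        from phapscore.genotype_io import PhenotypeTable

        B = 24
        wins = 0
        reps = 10
        for rep in range(reps):
            n, n_genes = 60, 12
            scores = np.abs(rng.normal(size=(n, n_genes)))
            doses = rng.uniform(3.5, 9.0, size=n)
            low = rng.random(n) < 0.35
            doses[low] = rng.uniform(1.0, 3.0, size=low.sum())
            scores[low, 0] += 2.5  # two planted low-dose-separating genes
            scores[low, 1] += 2.5
            gsm = _gsm(scores, [f"G{j}" for j in range(n_genes)])
            phenos = PhenotypeTable(
                doses=dict(zip(gsm.sample_ids, doses.tolist()))
            )
            labels = dichotomize(phenos, 3.0, "low")
            strict, nominal, _ = discover_features(gsm, labels)
            genes_used = strict or nominal
            if not genes_used:
                continue
            y = labels.vector_for(gsm.sample_ids)
            ev = evaluate_gene_classifier(gsm, genes_used, y, k=5, seed=rep)
            # null sets drawn from the non-planted genes: a small pool would
            # otherwise redraw the planted genes themselves in most batches
            null_pool = [g for g in gsm.gene_symbols if g not in ("G0", "G1")]
            p = empirical_significance(
                ev.auroc, gsm, null_pool, min(len(genes_used), len(null_pool)),
                y, B=B, seed=rep, k=5,
            )
            wins += int(p == pytest.approx(1 / (B + 1)))
        assert wins >= 0.7 * reps
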