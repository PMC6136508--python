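import numpy as np
import pytest
from sklearn.svm import SVC

from genefs import ParamPair, ranking_scores, rfe_rank, train_svm

from conftest import make_expr


def guyon_rfe_oracle(X, y, C=1.0):
    """Brute-force linear-kernel RFE: retrain, drop argmin(coef^2), repeat."""
    surviving = list(range(X.shape[1]))
    order = []
    while surviving:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X[:, surviving], y)
        scores = svc.coef_[0] ** 2
        k = int(np.argmin(scores))
        order.append(surviving.pop(k))
    return order


class TestRankingScores:
    def test_zero_feature_scores_zero_and_scores_non_negative(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        X[:, 2] = 0.0
        y = np.where(X[:, 0] > 0, 1, -1)
        model = train_svm(make_expr(X, y), kernel="linear", C=1.0)
        scores = ranking_scores(model)
        assert np.all(scores >= 0)
        assert scores[2] == 0.0

    def test_noise_scores_below_signal_on_separable_toy(self):
        # Feature 1 determines the class; feature 2 is pure noise.
        rng = np.random.default_rng(1)
        signal = np.concatenate([-np.ones(10), np.ones(10)])
        X = np.column_stack([signal + 0.1 * rng.normal(size=20),
                             rng.normal(size=20)])
        y = np.concatenate([-np.ones(10), np.ones(10)]).astype(int)
        model = train_svm(make_expr(X, y), kernel="linear", C=1.0)
        w_brute = model.dual_coefficients @ model.support_vectors
        scores = ranking_scores(model)
        assert np.allclose(scores, w_brute**2, atol=1e-10)
        assert scores[1] < scores[0]

    def test_kernel_criterion_also_ranks_signal_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = train_svm(make_expr(X, y), kernel="rbf", C=10.0, gamma=0.5)
        scores = ranking_scores(model, criterion="kernel")
        assert scores.shape == (3,)
        assert np.argmax(scores) == 0


class TestRfeRank:
    def test_single_gene_gets_rank_one(self):
        expr = make_expr([[0.0], [1.0], [2.0], [3.0]], [-1, -1, 1, 1])
        ranked = rfe_rank(expr, kernel="linear", fixed_params=ParamPair(1.0, 1.0))
        assert ranked.rank == {"G1": 1}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_and_bijection_invariants(self, seed):
        rng = np.random.default_rng(seed)
        expr = make_expr(rng.normal(size=(16, 7)), [-1] * 8 + [1] * 8)
        ranked = rfe_rank(expr, kernel="rbf", fixed_params=ParamPair(1.0, 0.1))
        assert sorted(ranked.elimination_order) == sorted(expr.gene_ids)
        assert sorted(ranked.rank.values()) == list(range(1, 8))

    def test_matches_guyon_oracle_linear_fixed_c(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 8))
        y = np.array([-1] * 10 + [1] * 10)
        X[y == 1, :2] += 1.5
        expr = make_expr(X, y)
        ranked = rfe_rank(
            expr, optimizer="none", kernel="linear", fixed_params=ParamPair(1.0, 1.0)
        )
        oracle = [f"G{j+1}" for j in guyon_rfe_oracle(X, y, C=1.0)]
        assert ranked.elimination_order == oracle

    def test_fully_deterministic_with_fixed_params(self, two_class_gaussian):
        kw = dict(optimizer="none", kernel="rbf", fixed_params=ParamPair(2.0, 0.05))
        r1 = rfe_rank(two_class_gaussian, **kw)
        r2 = rfe_rank(two_class_gaussian, **kw)
        assert r1.elimination_order == r2.elimination_order
        assert [rec.score for rec in r1.per_iteration] == [
            rec.score for rec in r2.per_iteration
        ]

    def test_duplicate_noise_genes_do_not_displace_planted_gene(self):
        # Planted gene at 3 sd; one noise gene duplicated several times.
        ranks = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 30
            y = np.array([-1] * 15 + [1] * 15)
            planted = rng.normal(size=n) + np.where(y == 1, 3.0, 0.0)
            noise = rng.normal(size=n)
            X = np.column_stack([planted, noise] + [noise] * 4
                                + [rng.normal(size=n) for _ in range(4)])
            expr = make_expr(X, y)
            ranked = rfe_rank(
                expr, kernel="rbf", fixed_params=ParamPair(1.0, 1.0 / X.shape[1])
            )
            ranks.append(ranked.rank["G1"])
        assert np.median(ranks) == 1

    def test_planted_gene_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 60, 50
            y = np.array([-1] * 30 + [1] * 30)
            X = rng.normal(size=(n, p))
            X[y == 1, 0] += 3.0
            ranked = rfe_rank(
                make_expr(X, y), kernel="rbf", fixed_params=ParamPair(1.0, 1.0 / p)
            )
            hits += ranked.rank["G1"] == 1
        assert hits >= 9

    def test_optimized_variant_records_params(self, two_class_gaussian):
        ranked = rfe_rank(
            two_class_gaussian, optimizer="pso", kernel="rbf",
            reoptimize_every=6, seed=0, cv_folds=4,
            optimizer_kwargs={"swarm_size": 3, "iterations": 2},
        )
        assert sorted(ranked.elimination_order) == sorted(two_class_gaussian.gene_ids)
        assert all(rec.params is not None for rec in ranked.per_iteration)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expr = make_expr(np.zeros((4, 0)), [-1, -1, 1, 1])
            rfe_rank(expr)

    def test_export_tsv(self, tmp_path, two_class_gaussian):
        ranked = rfe_rank(
            two_class_gaussian, kernel="rbf", fixed_params=ParamPair(1.0, 0.1)
        )
        path = ranked.to_tsv(tmp_path / "ranked.tsv")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == two_class_gaussian.n_genes + 1
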