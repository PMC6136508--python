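import numpy as np
import pytest

from genefs import (
    ParamPair,
    evaluate_subset,
    metrics_from_counts,
    rfe_rank,
    select_best_subset,
    stratified_split,
)

from conftest import auc_pair_counting, make_expr


def separated_expr(seed=0, n=40, p=6, delta=3.0):
    rng = np.random.default_rng(seed)
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    X = rng.normal(size=(n, p))
    X[y == 1, 0] += delta
    return make_expr(X, y)


class TestMetrics:
    def test_arithmetic_from_counts(self):
        acc, prec, rec, f = metrics_from_counts(3, 1, 1, 5)
        assert (acc, prec, rec, f) == (0.8, 0.75, 0.75, 0.75)

    def test_empty_denominators_zero(self):
        acc, prec, rec, f = metrics_from_counts(0, 0, 2, 8)
        assert prec == 0.0 and rec == 0.0 and f == 0.0


class TestEvaluateSubset:
    def test_report_invariants_on_separated_data(self):
        expr = separated_expr(n=120)
        train, test = stratified_split(expr, 0.5, seed=0)
        rep = evaluate_subset(train, test, ["G1"], kernel="rbf", C=1.0, gamma=1.0)
        assert rep.tp + rep.fp + rep.fn + rep.tn == test.n_samples
        acc, prec, rec, f = metrics_from_counts(rep.tp, rep.fp, rep.fn, rep.tn)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.precision == pytest.approx(prec)
        assert rep.f_score == pytest.approx(f)
        # separated at 3 sd on the informative gene -> near-perfect ranking
        assert rep.auc >= 0.95
        # ROC runs (0,0) -> (1,1) monotonically in both coordinates
        assert tuple(rep.roc_points[0]) == (0.0, 0.0)
        assert tuple(rep.roc_points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(rep.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(rep.roc_points[:, 1]) >= 0)

    def test_missing_subset_gene_rejected(self):
        expr = separated_expr()
        train, test = stratified_split(expr, 0.5, seed=0)
        with pytest.raises(KeyError):
            evaluate_subset(train, test, ["NOPE"])

    def test_export(self, tmp_path):
        expr = separated_expr()
        train, test = stratified_split(expr, 0.5, seed=0)
        rep = evaluate_subset(train, test, ["G1", "G2"])
        assert rep.to_tsv(tmp_path / "m.tsv").exists()
        assert rep.roc_to_tsv(tmp_path / "roc.tsv").exists()


class TestAuc:
    def test_perfect_separation_is_one(self):
        y = np.array([-1, -1, 1, 1])
        assert auc_pair_counting(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_hand_case_half(self):
        y = np.array([1, -1, -1, 1])
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        assert auc_pair_counting(y, scores) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_counting_with_ties(self, seed):
        from sklearn.metrics import auc as trap_auc
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(seed)
        y = rng.permutation([-1] * 7 + [1] * 8)
        scores = rng.integers(0, 4, size=15).astype(float)  # heavy ties
        fpr, tpr, _ = roc_curve(y, scores, pos_label=1, drop_intermediate=False)
        assert trap_auc(fpr, tpr) == pytest.approx(auc_pair_counting(y, scores))

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(3)
        y = rng.permutation([-1] * 10 + [1] * 10)
        scores = rng.normal(size=20)
        a = auc_pair_counting(y, scores)
        assert auc_pair_counting(y, -scores) == pytest.approx(1.0 - a)


class TestSelectBestSubset:
    def test_singleton_ranking(self):
        expr = separated_expr(p=1)
        subset, acc = select_best_subset(["G1"], expr, folds=4, seed=0)
        assert subset == ["G1"] and 0 <= acc <= 1

    def test_chosen_accuracy_is_sweep_maximum(self):
        from genefs import cv_accuracy

        expr = separated_expr(p=5)
        order = ["G1", "G2", "G3", "G4", "G5"]
        subset, acc = select_best_subset(order, expr, folds=4, seed=1)
        from genefs._rand import child_seed

        sweep = []
        for k in range(1, 6):
            sub = expr.subset_genes(order[:k])
            sweep.append(cv_accuracy(sub, kernel="rbf", C=1.0, gamma=1.0 / k,
                                     folds=4, seed=child_seed(1, "subset-cv")))
        assert acc == pytest.approx(max(sweep))
        assert len(subset) == int(np.argmax(sweep)) + 1  # smallest maximizer

    def test_informed_ranking_beats_random_on_held_out_auc(self):
        wins = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            y = np.array([-1] * 30 + [1] * 30)
            X = rng.normal(size=(60, 20))
            X[y == 1, :4] += 1.5
            expr = make_expr(X, y)
            train, test = stratified_split(expr, 0.5, seed=seed)
            ranked = rfe_rank(
                train, optimizer="pso", kernel="rbf", reoptimize_every=25,
                seed=seed, cv_folds=3,
                optimizer_kwargs={"swarm_size": 5, "iterations": 5},
            )
            subset, _ = select_best_subset(ranked, train, folds=3, seed=seed)
            informed = evaluate_subset(train, test, subset).auc
            rand_order = [f"G{j+1}" for j in rng.permutation(20)]
            rand_subset = rand_order[: len(subset)]
            random_auc = evaluate_subset(train, test, rand_subset).auc
            wins.append(informed - random_auc)
        assert np.median(wins) > 0
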