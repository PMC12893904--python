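"""Mean-score closed forms, permutation p contracts, exact Spearman trends."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunokit.ligand_receptor import (
    LigandReceptorModel,
    LRPair,
    LRScore,
    exact_spearman,
    lr_age_trend,
    lr_mean_score,
    lr_permutation_test,
)

PAIR = LRPair(ligand="Dll1", receptor="Notch2", sender="hep", receiver="T cell")


def expr_adata(rows, types, ages=None, genes=("Dll1", "Notch2")):
    X = np.asarray(rows, dtype=float)
    obs = pd.DataFrame(
        {"cell_type": types}, index=[f"c{i}" for i in range(len(types))]
    )
    if ages is not None:
        obs["age"] = ages
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(genes)))


class TestMeanScore:
    def test_closed_form(self):
        # ligand mean over senders = 2.0, receptor mean over receivers = 4.0
        a = expr_adata(
            [[1, 9], [3, 9], [9, 3], [9, 5]],
            ["hep", "hep", "T cell", "T cell"],
        )
        assert lr_mean_score(a, PAIR) == pytest.approx(3.0)

    def test_all_zero_gives_zero(self):
        a = expr_adata([[0, 0], [0, 0]], ["hep", "T cell"])
        assert lr_mean_score(a, PAIR) == pytest.approx(0.0)

    def test_matches_two_mean_oracle(self, rng):
        X = rng.uniform(0, 5, size=(40, 2))
        types = rng.choice(["hep", "T cell", "other"], size=40)
        types[:2] = ["hep", "T cell"]  # guarantee presence
        a = expr_adata(X, types)
        oracle = 0.5 * (
            X[types == "hep", 0].mean() + X[types == "T cell", 1].mean()
        )
        assert lr_mean_score(a, PAIR) == pytest.approx(oracle)

    def test_missing_gene_and_type_errors(self):
        a = expr_adata([[1, 1], [1, 1]], ["hep", "T cell"])
        with pytest.raises(ValueError, match="absent"):
            lr_mean_score(a, LRPair("nope", "Notch2", "hep", "T cell"))
        with pytest.raises(ValueError, match="absent"):
            lr_mean_score(a, LRPair("Dll1", "Notch2", "hep", "B cell"))

    def test_empty_pair_field_rejected(self):
        with pytest.raises(ValueError):
            LRPair("", "Notch2", "hep", "T cell")


class TestPermutation:
    def test_extreme_observed_gives_min_p(self):
        # senders own all ligand signal, receivers all receptor signal: no
        # permutation can match the observed score, so p = 1/(n_perm+1)
        n = 30
        X = np.zeros((n, 2))
        types = np.array(["hep"] * 10 + ["T cell"] * 10 + ["other"] * 10)
        X[types == "hep", 0] = 10.0
        X[types == "T cell", 1] = 10.0
        a = expr_adata(X, types, ages=[16.0] * n)
        res = lr_permutation_test(a, PAIR, n_perm=999, seed=0)
        assert res.p_perm == pytest.approx(1 / 1000)
        assert res.age == 16.0

    def test_exchangeable_expression_gives_p_one(self):
        # every cell identical: all permuted scores equal the observed score
        a = expr_adata(
            np.full((20, 2), 3.0),
            ["hep"] * 10 + ["T cell"] * 10,
            ages=[8.0] * 20,
        )
        res = lr_permutation_test(a, PAIR, n_perm=199, seed=1)
        assert res.p_perm == pytest.approx(1.0)

    def test_p_never_zero_and_resolution(self, rng):
        X = rng.uniform(0, 3, size=(24, 2))
        a = expr_adata(X, ["hep"] * 12 + ["T cell"] * 12, ages=[8.0] * 24)
        res = lr_permutation_test(a, PAIR, n_perm=99, seed=2)
        assert res.p_perm >= 1 / 100
        assert (res.p_perm * 100) == pytest.approx(round(res.p_perm * 100))

    def test_too_few_cells_or_perms(self):
        a = expr_adata([[1, 1], [1, 1]], ["hep", "T cell"])
        with pytest.raises(ValueError):
            lr_permutation_test(a, PAIR, n_perm=999)
        b = expr_adata(np.ones((8, 2)), ["hep"] * 4 + ["T cell"] * 4)
        with pytest.raises(ValueError):
            lr_permutation_test(b, PAIR, n_perm=10)


class TestExactSpearman:
    def test_perfect_trend_six_ages(self):
        rho, p = exact_spearman(
            np.array([8, 16, 24, 32, 40, 52.0]),
            np.array([1.0, 2.0, 2.5, 3.0, 4.0, 9.0]),
        )
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(6))

    def test_perfect_negative_trend(self):
        rho, p = exact_spearman(
            np.arange(6.0), np.array([9.0, 7.0, 5.0, 3.0, 2.0, 1.0])
        )
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 720)

    def test_matches_brute_force_enumeration(self, rng):
        from itertools import permutations

        x = np.arange(1.0, 6.0)
        y = np.array([2.0, 5.0, 1.0, 4.0, 3.0])
        rho, p = exact_spearman(x, y)
        null = [
            abs(stats.spearmanr(x, np.array(perm)).statistic)
            for perm in permutations(y)
        ]
        assert p == pytest.approx(np.mean(np.array(null) >= abs(rho) - 1e-12))

    def test_monotone_transform_invariance(self):
        x = np.array([8, 16, 24, 32, 40, 52.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        r1, p1 = exact_spearman(x, y)
        r2, p2 = exact_spearman(x, np.exp(y))
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_ties_fall_back_to_approximation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rho, p = exact_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


def make_scores(values, ages=(8, 16, 24, 32, 40, 52)):
    return [
        LRScore(pair=PAIR, age=float(a), mean_value=float(v))
        for a, v in zip(ages, values)
    ]


class TestAgeTrend:
    def test_bonferroni_scaling(self):
        tr1 = lr_age_trend(make_scores([1, 2, 3, 4, 5, 6]), m=1)
        tr10 = lr_age_trend(make_scores([1, 2, 3, 4, 5, 6]), m=10)
        assert tr1.p == pytest.approx(2 / 720)
        assert tr10.p_bonferroni == pytest.approx(10 * 2 / 720)
        tr_many = lr_age_trend(make_scores([1, 2, 3, 4, 5, 6]), m=1000)
        assert tr_many.p_bonferroni == 1.0

    def test_categories(self):
        assert lr_age_trend(make_scores([1, 2, 3, 4, 5, 6]), m=1).category == (
            "increasing"
        )
        assert lr_age_trend(make_scores([6, 5, 4, 3, 2, 1]), m=1).category == (
            "decreasing"
        )
        assert lr_age_trend(make_scores([3, 1, 4, 2, 6, 5]), m=1).category == "flat"

    def test_significant_raw_made_flat_by_correction(self):
        tr = lr_age_trend(make_scores([1, 2, 3, 4, 5, 6]), m=50)
        assert tr.p < 0.05 < tr.p_bonferroni
        assert tr.category == "flat"

    def test_constant_values_raise(self):
        with pytest.raises(ValueError, match="constant"):
            lr_age_trend(make_scores([2, 2, 2, 2, 2, 2]), m=1)

    def test_too_few_ages(self):
        with pytest.raises(ValueError):
            lr_age_trend(make_scores([1, 2], ages=(8, 16)), m=1)


class TestModelInterface:
    def test_end_to_end_increasing_pair(self, rng):
        ages = [8.0, 16.0, 24.0, 32.0, 40.0, 52.0]
        genes = ["Dll1", "Notch2"] + [f"hk{j}" for j in range(10)]
        blocks = []
        for i, age in enumerate(ages):
            # stable housekeeping background so total-count normalisation
            # does not swallow the age-dependent ligand signal
            X = rng.poisson(5.0, size=(60, 12)).astype(float)
            types = np.array(["hep"] * 30 + ["T cell"] * 30)
            X[types == "hep", 0] += rng.poisson(3.0 * (i + 1), size=30)
            blocks.append(expr_adata(X, types, ages=[age] * 60, genes=genes))
        adata = ad.concat(blocks, index_unique="-")
        res = LigandReceptorModel(adata, [PAIR]).fit(n_perm=199, seed=0)
        assert len(res.table) == 6
        trend = res.age_trends(m=1)[0]
        assert trend.category == "increasing"
        assert "Ligand-receptor" in res.summary()
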