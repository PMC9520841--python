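"""Procrustes ANOVA, CVA, DFA, permutation tests and leave-one-out validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fleagm.shape_core import gpa
from fleagm.shape_stats import (
    FactorialDesign,
    classification_improvement,
    cva,
    dfa_two_group,
    loo_cross_validate,
    permutation_test_group_distances,
    procrustes_anova,
)
from fleagm.synthetic import ShapeSimSpec, simulate_landmark_dataset


def _toy_design(rng, n_per_cell=4):
    sex = np.repeat(["F", "F", "M", "M"], n_per_cell)
    species = np.tile(np.repeat(["canis", "orientis"], n_per_cell), 2)
    return FactorialDesign(sex=sex, species=species)


def _gaussian_groups(rng, sizes, sep, dim=6):
    """Gaussian clusters with mean offset `sep` along the first axis per group."""
    X, labels = [], []
    for g, size in enumerate(sizes):
        mu = np.zeros(dim)
        mu[0] = g * sep
        X.append(rng.normal(size=(size, dim)) + mu)
        labels += [f"g{g}"] * size
    return np.vstack(X), np.array(labels)


class TestProcrustesAnova:
    def test_sequential_ss_matches_projection_oracle(self, rng):
        """SS from nested least squares equal explicit hat-matrix projections."""
        design = _toy_design(rng, n_per_cell=3)
        Y = rng.normal(size=(design.n, 6))
        table = procrustes_anova(Y, design).set_index("effect")

        # oracle: sequential SS via explicit orthogonal projections
        sex_d = (design.sex == "F").astype(float)
        sp_d = (design.species == "canis").astype(float)
        ones = np.ones(design.n)
        mats = [
            np.column_stack([ones]),
            np.column_stack([ones, sex_d]),
            np.column_stack([ones, sex_d, sp_d]),
            np.column_stack([ones, sex_d, sp_d, sex_d * sp_d]),
        ]
        rss = []
        for X in mats:
            H = X @ np.linalg.pinv(X)
            rss.append(float(np.sum(((np.eye(design.n) - H) @ Y) ** 2)))
        assert table.loc["sex", "SS"] == pytest.approx(rss[0] - rss[1], abs=1e-10)
        assert table.loc["species", "SS"] == pytest.approx(rss[1] - rss[2], abs=1e-10)
        assert table.loc["sex:species", "SS"] == pytest.approx(rss[2] - rss[3], abs=1e-10)
        assert table.loc["residual", "SS"] == pytest.approx(rss[3], abs=1e-10)
        # sequential decomposition sums to the total SS
        total = rss[0]
        assert table["SS"].sum() == pytest.approx(total, rel=1e-8)

    def test_df_bookkeeping(self, rng):
        design = _toy_design(rng, n_per_cell=5)
        Y = rng.normal(size=(design.n, 2 * 13))
        table = procrustes_anova(Y, design).set_index("effect")
        assert list(table["df"]) == [22, 22, 22, (design.n - 4) * 22]

    def test_zero_variance_gives_nan_f(self, rng):
        design = _toy_design(rng)
        Y = np.zeros((design.n, 8))
        table = procrustes_anova(Y, design).set_index("effect")
        assert table["SS"].sum() == 0.0
        assert math.isnan(table.loc["sex", "F"])

    def test_empty_cell_rejected(self, rng):
        design = FactorialDesign(
            sex=np.array(["F"] * 8), species=np.array(["canis"] * 4 + ["orientis"] * 4)
        )
        with pytest.raises(ValueError, match="cells"):
            procrustes_anova(rng.normal(size=(8, 6)), design)


class TestCVA:
    def test_four_groups_three_variates_sum_100(self, rng):
        X, labels = _gaussian_groups(rng, [20, 15, 12, 10], sep=2.0)
        res = cva(X, labels, n_perm=0)
        assert len(res.eigenvalues) == 3
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.percent_variance) <= 1e-9)

    def test_identical_means_zero_distance(self, rng):
        X = rng.normal(size=(60, 5))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        X[30:] -= X[30:].mean(axis=0) - X[:30].mean(axis=0)  # force equal means
        res = cva(X, labels, n_perm=0)
        assert res.mahalanobis.loc["a", "b"] < 1e-8
        assert res.eigenvalues[0] < 1e-12

    def test_two_group_cv1_parallel_to_discriminant(self, rng):
        X, labels = _gaussian_groups(rng, [25, 25], sep=3.0, dim=5)
        res = cva(X, labels, n_perm=0)
        mask = labels == "g0"
        W = (
            np.cov(X[mask].T, bias=False) * (mask.sum() - 1)
            + np.cov(X[~mask].T, bias=False) * ((~mask).sum() - 1)
        ) / (len(X) - 2)
        w_axis = np.linalg.solve(W, X[mask].mean(0) - X[~mask].mean(0))
        cos = abs(res.axes[:, 0] @ w_axis) / (
            np.linalg.norm(res.axes[:, 0]) * np.linalg.norm(w_axis)
        )
        assert cos == pytest.approx(1.0, abs=1e-8)
        # brute-force Mahalanobis oracle
        d = X[mask].mean(0) - X[~mask].mean(0)
        maha = np.sqrt(d @ np.linalg.solve(W, d))
        assert res.mahalanobis.loc["g0", "g1"] == pytest.approx(maha, abs=1e-8)

    def test_mahalanobis_affine_invariance(self, rng):
        X, labels = _gaussian_groups(rng, [20, 20, 15], sep=1.5, dim=4)
        res1 = cva(X, labels, n_perm=0)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        res2 = cva(X @ A.T, labels, n_perm=0)
        np.testing.assert_allclose(
            res1.mahalanobis.values, res2.mahalanobis.values, atol=1e-6
        )

    def test_singleton_group_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        labels = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError):
            cva(X, labels, n_perm=0)

    def test_sklearn_lda_crosscheck(self, rng):
        """Resubstitution assignments match scikit-learn's LDA on full-rank data."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, labels = _gaussian_groups(rng, [30, 30], sep=1.0, dim=5)
        res = dfa_two_group(X, labels, n_perm=0, run_loo=False)
        clf = sklearn.LinearDiscriminantAnalysis(solver="svd").fit(X, labels)
        ours = np.where(
            (res.scores - res.cutoff) * np.sign(
                res.scores[labels == res.group_names[0]].mean() - res.cutoff
            ) >= 0,
            res.group_names[0],
            res.group_names[1],
        )
        agreement = np.mean(ours == clf.predict(X))
        assert agreement > 0.97  # same rule up to the prior term in the threshold


class TestPermutationTests:
    def test_reproducible_given_seed(self, rng):
        X, labels = _gaussian_groups(rng, [10, 10], sep=1.0, dim=4)
        p1 = permutation_test_group_distances(X, labels, n_perm=200, seed=5)
        p2 = permutation_test_group_distances(X, labels, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_saturated_significance_attains_minimum(self, rng):
        X, labels = _gaussian_groups(rng, [12, 12], sep=50.0, dim=4)
        for statistic in ("mahalanobis", "procrustes"):
            p = permutation_test_group_distances(
                X, labels, statistic=statistic, n_perm=99, seed=1
            )
            assert p.loc["g0", "g1"] == pytest.approx(1 / 100)

    def test_null_p_values_uniform(self):
        """Under exchangeability p is uniform on {1/(B+1), ..., 1} (KS at alpha=0.01)."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            X = rng.normal(size=(16, 4))
            labels = np.array(["a"] * 8 + ["b"] * 8)
            p = permutation_test_group_distances(X, labels, n_perm=49, seed=int(rng.integers(2**31)))
            pvals.append(p.loc["a", "b"])
        stat = stats.kstest(pvals, "uniform").statistic
        # lattice spacing 1/50 inflates KS slightly; 0.01-level critical ~0.073
        assert stat < 0.073 + 1 / 100


class TestPaperScaleSeparation:
    def test_all_group_pairs_significant_at_study_scale(self, default_dataset):
        """With study-scale group sizes and effects, every pair of sex x species
        groups separates at p < 0.001 under the mean-shape permutation test."""
        from fleagm.shape_core import gpa

        res = gpa(default_dataset)
        groups = FactorialDesign.from_labels(default_dataset.labels).cells()
        p = permutation_test_group_distances(
            res.tangent, groups, statistic="procrustes", n_perm=1999, seed=0
        )
        off = p.values[~np.eye(4, dtype=bool)]
        assert off.max() < 0.001


class TestDFAandLOO:
    def test_separated_groups_no_resubstitution_error(self, rng):
        X, labels = _gaussian_groups(rng, [15, 15], sep=30.0, dim=5)
        res = dfa_two_group(X, labels, n_perm=50, seed=0)
        assert np.diag(res.resubstitution.values).sum() == 30
        assert res.loo_misclassification.max() == 0.0
        assert res.p_permutation == pytest.approx(1 / 51)

    def test_null_loo_error_near_half(self, rng):
        errs = []
        for _ in range(30):
            X, labels = _gaussian_groups(rng, [12, 12], sep=0.0, dim=4)
            table, rates, _ = loo_cross_validate(X, labels)
            errs.append(1 - np.diag(table.values).sum() / 24)
        assert 0.35 < np.mean(errs) < 0.65

    def test_axis_recovers_generating_direction(self):
        spec = ShapeSimSpec(
            species_effect=0.05,
            sex_effect=0.0,
            interaction_effect=0.0,
            landmark_noise_sd=0.01,
            rotation_range=(0.0, 0.0),
            translation_range=(0.0, 0.0),
            scale_range=(1.0, 1.0),
            seed=9,
        )
        dataset, truth = simulate_landmark_dataset(spec)
        res = gpa(dataset)
        dfa = dfa_two_group(
            res.tangent, dataset.labels["species"].to_numpy(), n_perm=0, run_loo=False
        )
        cos = abs(dfa.axis @ truth["species"]) / np.linalg.norm(dfa.axis)
        assert cos > 0.95

    def test_loo_at_least_resubstitution_on_average(self, rng):
        loo_err, resub_err = [], []
        for _ in range(100):
            X, labels = _gaussian_groups(rng, [12, 12], sep=0.8, dim=4)
            res = dfa_two_group(X, labels, n_perm=0)
            n = len(labels)
            resub_err.append(1 - np.diag(res.resubstitution.values).sum() / n)
            loo_err.append(1 - np.diag(res.loo.values).sum() / n)
        assert np.mean(loo_err) >= np.mean(resub_err)

    def test_loo_contingency_rows_sum_to_group_sizes(self, rng):
        X, labels = _gaussian_groups(rng, [9, 14], sep=1.0, dim=4)
        table, rates, n_bad = loo_cross_validate(X, labels)
        assert n_bad == 0
        assert table.loc["g0"].sum() == 9
        assert table.loc["g1"].sum() == 14


class TestClassificationImprovement:
    @staticmethod
    def _table(wrong, total, classes=("canis", "orientis"), cls="orientis"):
        other = classes[0] if cls == classes[1] else classes[1]
        t = pd.DataFrame(0, index=list(classes), columns=list(classes))
        t.loc[cls, cls] = total - wrong
        t.loc[cls, other] = wrong
        t.loc[other, other] = 50
        return t

    def test_printed_rate_pairs(self):
        # females: 31% (16/51) observer vs 6% (3/47) classifier -> 5.2-fold
        imp = classification_improvement(self._table(16, 51), self._table(3, 47))
        row = imp.loc["orientis"]
        assert row["misclassification_before_pct"] == 31
        assert row["misclassification_after_pct"] == 6
        assert row["fold_improvement"] == 5.2
        # males: 57% (4/7) vs 14% (1/7) -> 4.1-fold
        imp = classification_improvement(self._table(4, 7), self._table(1, 7))
        row = imp.loc["orientis"]
        assert row["misclassification_before_pct"] == 57
        assert row["misclassification_after_pct"] == 14
        assert row["fold_improvement"] == 4.1

    def test_equal_tables_fold_one(self):
        t = self._table(5, 20)
        assert classification_improvement(t, t).loc["orientis", "fold_improvement"] == 1.0

    def test_zero_after_rate_flagged_infinite(self):
        imp = classification_improvement(self._table(5, 20), self._table(0, 20))
        assert imp.loc["orientis", "infinite"]
        assert math.isinf(imp.loc["orientis", "fold_improvement"])

    def test_indeterminate_excluded_from_denominator(self):
        obs = pd.DataFrame(
            [[40, 4, 6], [16, 35, 10]],
            index=["canis", "orientis"],
            columns=["canis", "orientis", "indeterminate"],
        )
        loo = self._table(3, 47)
        imp = classification_improvement(obs, loo)
        assert imp.loc["orientis", "misclassification_before_pct"] == 31  # 16/51
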