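"""Adjacency, topological overlap, module detection and hub ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from irlnet.synthetic_data import (
    generate_planted_modules,
    generate_scale_free_expression,
)
from irlnet.wgcna_lite import (
    GREY,
    WgcnaParams,
    adjacency,
    detect_modules,
    hub_weights,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    remove_outlier_samples,
    run_wgcna,
    tom_similarity,
)


def matrix_with_correlation(rho, n_samples=200, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    x = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(n_samples)
    return pd.DataFrame([z, x], index=["a", "b"])


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                            [-1.0, -2.0, -3.0]], index=list("abc"))
        a = adjacency(mat, beta=7)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] == pytest.approx(1.0)   # unsigned

    def test_powering_matches_hand_arithmetic(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
                           index=["a", "b"])
        # cor = -1 exactly; rescale one row to get cor -0.5
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        e = rng.standard_normal(5000)
        x = -0.5 * z + math.sqrt(1 - 0.25) * e
        mat = pd.DataFrame([z, x], index=["a", "b"])
        a = adjacency(mat, beta=2)
        rho = np.corrcoef(z, x)[0, 1]
        assert a.loc["a", "b"] == pytest.approx(rho**2, abs=1e-12)

    def test_zero_variance_feature_gets_zero_adjacency(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        a = adjacency(mat, beta=3)
        assert a.loc["a", "b"] == 0.0
        assert a.loc["a", "a"] == 1.0


class TestTom:
    def test_two_node_closed_form(self):
        # TOM_12 = (0 + a) / (min(a, a) + 1 - a) = a
        for a_val in (0.0, 0.2, 0.7, 1.0):
            adj = pd.DataFrame([[1.0, a_val], [a_val, 1.0]], index=["x", "y"],
                               columns=["x", "y"])
            tom = tom_similarity(adj)
            assert tom.loc["x", "y"] == pytest.approx(a_val, abs=1e-12)

    def test_uniform_triangle_closed_form(self):
        # numerator a^2 + a, denominator a + 1 - a + ... = a(a+1)/(a+1) = a
        for a_val in (0.1, 0.5, 0.9):
            adj = pd.DataFrame(np.full((3, 3), a_val))
            np.fill_diagonal(adj.values, 1.0)
            tom = tom_similarity(adj)
            off = tom.values[np.triu_indices(3, 1)]
            assert np.allclose(off, a_val, atol=1e-12)

    def test_bounds_and_symmetry_on_random_adjacency(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            raw = rng.uniform(0, 1, (15, 15))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0.0 and tom.max() <= 1.0
            assert np.allclose(np.diag(tom), 1.0)


class TestOutlierRemoval:
    def test_identical_samples_keep_everything(self):
        mat = pd.DataFrame(np.ones((5, 6)),
                           columns=[f"s{i}" for i in range(6)])
        retained, dropped = remove_outlier_samples(mat)
        assert dropped == []

    def test_injected_outlier_is_removed(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(0, 1, (50, 10)),
                           columns=[f"s{i}" for i in range(10)])
        mat["s9"] += 100.0
        retained, dropped = remove_outlier_samples(mat)
        assert dropped == ["s9"]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                           columns=[f"s{i}" for i in range(8)])
        mat["s0"] += 50.0
        r1, d1 = remove_outlier_samples(mat)
        r2, d2 = remove_outlier_samples(mat[list(reversed(mat.columns))])
        assert set(d1) == set(d2)

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError):
            remove_outlier_samples(pd.DataFrame(np.ones((5, 3))))


class TestSoftThreshold:
    def test_fit_table_has_one_row_per_beta(self):
        mat = generate_scale_free_expression(n_features=60, n_samples=30, seed=0)
        beta, fit = pick_soft_threshold(mat, beta_grid=(1, 3, 5))
        assert list(fit["beta"]) == [1, 3, 5]

    def test_deterministic_selection(self):
        mat = generate_scale_free_expression(seed=1)
        assert pick_soft_threshold(mat)[0] == pick_soft_threshold(mat)[0]

    def test_scale_free_fixture_reaches_target_fit(self):
        mat = generate_scale_free_expression(seed=0)
        beta, fit = pick_soft_threshold(mat, r2_target=0.75)
        assert fit["r2"].max() >= 0.75
        chosen = fit.loc[fit["beta"] == beta, "r2"].iloc[0]
        assert chosen >= 0.75

    def test_too_few_features_is_an_error(self):
        mat = generate_scale_free_expression(n_features=5, n_samples=20, seed=0)
        with pytest.raises(ValueError):
            pick_soft_threshold(mat)


class TestEigengene:
    def test_identical_features_give_their_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        mat = pd.DataFrame([profile, profile, profile], index=list("abc"),
                           columns=[f"s{i}" for i in range(5)])
        eig = module_eigengene(mat, ["a", "b", "c"])
        std = (profile - profile.mean()) / profile.std()
        expected = std / np.linalg.norm(std)
        assert np.allclose(eig.to_numpy(), expected, atol=1e-10)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_sign_anchoring_under_global_negation(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(0, 1, (4, 30)) + rng.normal(0, 1, 30),
                           index=list("abcd"))
        eig_pos = module_eigengene(mat, list("abcd"))
        eig_neg = module_eigengene(-mat, list("abcd"))
        for eig, m in ((eig_pos, mat), (eig_neg, -mat)):
            cors = [np.corrcoef(m.loc[f], eig)[0, 1] for f in "abcd"]
            assert np.mean(cors) > 0

    def test_two_feature_module_matches_hand_svd(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [1.0, 2.2, 2.8, 4.1]],
                           index=["a", "b"])
        eig = module_eigengene(mat, ["a", "b"])
        std = ((mat.T - mat.mean(axis=1)) / mat.std(axis=1, ddof=0)).T.to_numpy()
        # rank-~1: PC1 proportional to the mean standardized profile
        expected = std.mean(axis=0)
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(eig.to_numpy()), np.abs(expected), atol=1e-3)


class TestModulesAndMerging:
    def test_two_separated_blocks_give_two_modules(self):
        mat, truth, _ = generate_planted_modules(sizes=(40, 35), seed=6)
        params = WgcnaParams()
        tom = tom_similarity(adjacency(mat, params.beta))
        labels = detect_modules(tom, params)
        labels, _ = merge_modules(labels, mat, params.merge_height)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_undersized_branch_goes_grey(self):
        mat, truth, _ = generate_planted_modules(sizes=(40, 29), seed=6)
        params = WgcnaParams(min_module_size=30)
        tom = tom_similarity(adjacency(mat, params.beta))
        labels = detect_modules(tom, params)
        small = truth.index[truth == "M2"]
        assert (labels.loc[small] == GREY).all()

    def test_identical_eigengene_modules_merge(self):
        # one homogeneous block artificially split in two
        mat, truth, _ = generate_planted_modules(sizes=(60,), within_cor=0.9,
                                                 seed=7)
        labels = pd.Series(
            ["A"] * 30 + ["B"] * 30, index=mat.index, name="module"
        )
        merged, eigs = merge_modules(labels, mat, merge_height=0.10)
        assert merged.nunique() == 1

    def test_orthogonal_modules_stay_apart_and_merge_is_idempotent(self):
        mat, truth, _ = generate_planted_modules(sizes=(40, 35), seed=8)
        labels = truth.copy()
        merged, _ = merge_modules(labels, mat, merge_height=0.10)
        assert set(merged) == {"M1", "M2"}
        again, _ = merge_modules(merged, mat, merge_height=0.10)
        assert (again == merged).all()


class TestTraitAndHubs:
    def test_eigengene_equal_to_trait_gives_r2_one(self):
        eigs = pd.DataFrame({"M1": [0.1, -0.2, 0.5, -0.4, 0.3]},
                            index=[f"s{i}" for i in range(5)])
        trait = eigs["M1"] * 3.0 + 7.0          # affine transform
        stats = module_trait_correlation(eigs, trait)
        assert stats.loc["M1", "r2"] == pytest.approx(1.0)

    def test_constant_trait_is_an_error(self):
        eigs = pd.DataFrame({"M1": [0.1, -0.2, 0.5]}, index=list("abc"))
        with pytest.raises(ValueError):
            module_trait_correlation(eigs, pd.Series([1.0, 1.0, 1.0],
                                                     index=list("abc")))

    def test_dominant_feature_ranks_first(self):
        n = 6
        a = np.full((n, n), 0.1)
        a[0, :] = a[:, 0] = 1.0
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"f{i}" for i in range(n)],
                           columns=[f"f{i}" for i in range(n)])
        labels = pd.Series("M1", index=adj.index)
        hubs = hub_weights(adj, labels, "M1")
        assert hubs.iloc[0]["feature"] == "f0"

    def test_top_k_overflow_returns_all_with_warning(self):
        adj = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        labels = pd.Series("M1", index=adj.index)
        with pytest.warns(UserWarning):
            hubs = hub_weights(adj, labels, "M1", top_k=10)
        assert len(hubs) == 4

    def test_grey_is_not_a_module(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            hub_weights(adj, pd.Series(GREY, index=adj.index), GREY)


def test_full_run_recovers_trait_module_and_its_hub():
    mat, truth, trait = generate_planted_modules(seed=9)
    assignment, adj, dropped = run_wgcna(mat, trait, remove_outliers=False)
    assert assignment.trait_stats is not None
    top = assignment.trait_stats["r2"].idxmax()
    assert set(truth[assignment.labels == top]) == {"M1"}
    assert assignment.trait_stats.loc[top, "p"] < 0.01
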