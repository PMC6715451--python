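"""SAM statistic, fudge-constant selection and permutation significance."""

import math

import numpy as np
import pandas as pd
import pytest

from irlnet.containers import ExpressionDataset
from irlnet.diffexpr import (
    call_degs,
    choose_s0,
    intersect_contrasts,
    permutation_pvalues,
    sam_analysis,
    sam_components,
    sam_statistic,
)
from irlnet.synthetic_data import generate_null_dataset


def toy_dataset(case, control):
    """Small unpaired dataset from per-feature lists of group values."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    feats = [f"F{i}" for i in range(case.shape[0])]
    return ExpressionDataset(
        matrix=pd.DataFrame(np.hstack([case, control]), index=feats, columns=cols),
        labels=pd.Series(["case"] * n1 + ["control"] * n2, index=cols),
        contrast=("case", "control"),
        biotype=pd.Series(["mRNA"] * len(feats), index=feats),
    )


class TestSamStatistic:
    def test_identical_groups_give_zero(self):
        ds = toy_dataset([[1, 2, 3], [5, 5, 6]], [[1, 2, 3], [5, 5, 6]])
        d = sam_statistic(ds, s0=0.1)
        assert np.allclose(d, 0.0)

    def test_matches_hand_computation_on_3v3_toy(self):
        case = [[4.0, 5.0, 6.0], [1.0, 1.0, 2.0]]
        control = [[1.0, 2.0, 3.0], [1.5, 1.0, 1.5]]
        ds = toy_dataset(case, control)
        s0 = 0.2
        d = sam_statistic(ds, s0=s0)
        for i, (x1, x2) in enumerate(zip(case, control)):
            r = np.mean(x1) - np.mean(x2)
            pooled = (np.sum((x1 - np.mean(x1)) ** 2)
                      + np.sum((x2 - np.mean(x2)) ** 2)) / 4
            s = math.sqrt((1 / 3 + 1 / 3) * pooled)
            assert d[i] == pytest.approx(r / (s + s0), abs=1e-12)

    def test_scale_equivariance_with_zero_fudge(self):
        ds = toy_dataset([[4, 5, 6], [1, 3, 2]], [[1, 2, 3], [4, 5, 7]])
        scaled = toy_dataset(
            10 * np.array([[4, 5, 6], [1, 3, 2]], dtype=float),
            10 * np.array([[1, 2, 3], [4, 5, 7]], dtype=float),
        )
        assert np.allclose(sam_statistic(ds, 0.0), sam_statistic(scaled, 0.0))

    def test_zero_variance_feature_needs_positive_fudge(self):
        ds = toy_dataset([[1, 1, 1]], [[2, 2, 2]])
        with pytest.raises(ValueError):
            sam_statistic(ds, s0=0.0)
        assert np.isfinite(sam_statistic(ds, s0=0.5)).all()

    def test_label_swap_negates_d(self):
        ds = toy_dataset([[4, 5, 6], [1, 3, 2]], [[1, 2, 3], [4, 5, 7]])
        swapped = toy_dataset([[1, 2, 3], [4, 5, 7]], [[4, 5, 6], [1, 3, 2]])
        assert np.allclose(sam_statistic(ds, 0.1), -sam_statistic(swapped, 0.1))

    def test_paired_statistic_uses_within_subject_differences(self):
        cols = ["s1b", "s2b", "s3b", "s1a", "s2a", "s3a"]
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 2.0, 3.5, 4.2]], index=["F0"], columns=cols
        )
        ds = ExpressionDataset(
            matrix=mat,
            labels=pd.Series(["before"] * 3 + ["after"] * 3, index=cols),
            contrast=("after", "before"),
            biotype=pd.Series({"F0": "mRNA"}),
            pairing=pd.Series(["s1", "s2", "s3", "s1", "s2", "s3"], index=cols),
        )
        diffs = np.array([1.0, 1.5, 1.2])
        r = diffs.mean()
        s = diffs.std(ddof=1) / math.sqrt(3)
        assert sam_statistic(ds, 0.0)[0] == pytest.approx(r / s, abs=1e-12)


class TestChooseS0:
    def test_all_equal_s_returns_that_value(self):
        r = np.random.default_rng(0).normal(size=50)
        s = np.full(50, 0.7)
        assert choose_s0(r, s) == pytest.approx(0.7)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        r, s = rng.normal(size=200), rng.uniform(0.1, 2.0, 200)
        assert choose_s0(r, s) == choose_s0(r, s)

    def test_matches_brute_force_over_grid(self):
        # two s-strata; replicate the CV criterion independently
        rng = np.random.default_rng(2)
        s = np.concatenate([np.full(60, 0.2), np.full(60, 2.0)])
        r = rng.normal(scale=s)
        got = choose_s0(r, s, n_windows=2)

        def mad(x):
            return 1.4826 * np.median(np.abs(x - np.median(x)))

        best = (np.inf, None)
        lo = s <= np.quantile(s, 0.5)
        for cand in np.percentile(s, np.arange(0, 101, 5)):
            d = r / (s + cand)
            mads = np.array([mad(d[lo]), mad(d[~lo])])
            cv = mads.std(ddof=1) / mads.mean()
            if cv < best[0] - 1e-15:
                best = (cv, cand)
        assert got == pytest.approx(best[1])


class TestPermutations:
    def test_full_enumeration_on_3v3_uses_twenty_splits(self):
        ds = toy_dataset([[4, 5, 6], [1, 3, 2]], [[1, 2, 3], [4, 5, 7]])
        d = sam_statistic(ds, 0.1)
        _, n_used, full = permutation_pvalues(ds, d, s0=0.1, n_perm=100, seed=0)
        assert full and n_used == 20

    def test_extreme_feature_hits_the_add_one_floor(self):
        # one feature with a huge shift amid pure noise
        rng = np.random.default_rng(3)
        case = rng.normal(0, 0.1, (40, 5))
        control = rng.normal(0, 0.1, (40, 5))
        case[0] += 50.0
        ds = toy_dataset(case, control)
        d = sam_statistic(ds, 0.05)
        p, n_used, full = permutation_pvalues(ds, d, s0=0.05, n_perm=100, seed=0)
        assert full and n_used == 252
        # its |d| can be tied only by its own identity/complement splits:
        # 2 pooled values >= |d|, so p = (1 + 2) / (1 + 252 * 40)
        assert p[0] == pytest.approx(3 / (1 + 252 * 40))

    def test_pvalues_reproducible_under_fixed_seed(self):
        ds = generate_null_dataset(50, 12, seed=4)
        d = sam_statistic(ds, 0.1)
        p1, _, full = permutation_pvalues(ds, d, s0=0.1, n_perm=300, seed=9)
        p2, _, _ = permutation_pvalues(ds, d, s0=0.1, n_perm=300, seed=9)
        assert not full
        assert np.array_equal(p1, p2)

    def test_super_uniform_null_distribution(self):
        from scipy.stats import kstest
        ds = generate_null_dataset(400, 5, seed=5)
        res = sam_analysis(ds, n_perm=1000, seed=5)
        stat = kstest(res.table["p"], "uniform")
        # p-values are valid (not anti-conservative) under the global null
        assert (res.table["p"] < 0.05).mean() < 0.08
        assert stat.pvalue > 0.01 or res.table["p"].mean() > 0.5


class TestCalling:
    def test_threshold_is_strict(self):
        ds = generate_null_dataset(10, 3, seed=0)
        res = sam_analysis(ds, n_perm=100, seed=0)
        res.table.loc[0, "p"] = 0.01
        res.table["called"] = res.table["p"] < 0.01
        degs = call_degs(res, threshold=0.01)
        assert res.table.loc[0, "feature"] not in degs["mRNA"]

    def test_all_p_one_gives_empty_call(self):
        ds = generate_null_dataset(10, 3, seed=0)
        res = sam_analysis(ds, n_perm=100, seed=0)
        res.table["p"] = 1.0
        assert call_degs(res) == {"lncRNA": [], "mRNA": []}

    def test_intersection_identities(self):
        a = {"lncRNA": ["l1", "l2"], "mRNA": ["m1"]}
        b = {"lncRNA": ["l2", "l3"], "mRNA": ["m2"]}
        assert intersect_contrasts(a, b) == {"lncRNA": ["l2"], "mRNA": []}
        assert intersect_contrasts(a, a) == {
            "lncRNA": ["l1", "l2"], "mRNA": ["m1"]
        }
        sub = {"lncRNA": ["l1"], "mRNA": []}
        assert intersect_contrasts(sub, a) == sub


def test_planted_overlap_recovered_exactly(small_cfg, small_truth, small_bundle):
    res_cc = sam_analysis(small_bundle.case_control, n_perm=500, seed=1)
    res_p = sam_analysis(small_bundle.paired, n_perm=500, seed=2)
    inter = intersect_contrasts(call_degs(res_cc), call_degs(res_p))
    found = set(inter["lncRNA"]) | set(inter["mRNA"])
    planted = small_truth.de_features["paired"]
    # replication across contrasts prunes false positives; recovery is high
    assert len(found & planted) / len(planted) >= 0.9
    assert len(found - planted) <= 3
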