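import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import trisomethyl as tm
from trisomethyl.core_io import ValidationError
from trisomethyl.expression import _sam_q_values

from conftest import make_matrix


class TestClassifyCloneByFish:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((300, 285, 15), "trisomy8"),   # exactly the 95% cut-off
            ((300, 284, 16), "reject"),     # 284/300 = 0.9467 < 0.95
            ((300, 15, 285), "disomy8"),
            ((300, 150, 150), "reject"),
        ],
    )
    def test_cutoff_rule(self, counts, expected):
        assert tm.classify_clone_by_fish(*counts) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            tm.classify_clone_by_fish(300, -1, 0)
        with pytest.raises(ValidationError):
            tm.classify_clone_by_fish(300, 200, 200)
        with pytest.raises(ValidationError):
            tm.classify_clone_by_fish(0, 0, 0)


class TestVarianceFilter:
    def test_retains_highest_sd_half(self):
        mat = make_matrix(
            [[1, 1, 1], [1, 2, 3], [0, 3, 6], [0, 5, 10]],
            probe_ids=["a", "b", "c", "d"],
        )
        out = tm.variance_filter(mat, 0.5)
        assert sorted(out.probe_ids) == ["c", "d"]

    def test_fraction_one_is_identity(self):
        mat = make_matrix([[1, 2], [3, 4]])
        out = tm.variance_filter(mat, 1.0)
        assert sorted(out.probe_ids) == sorted(mat.probe_ids)

    def test_tie_at_cut_keeps_lexicographically_smaller_id(self):
        mat = make_matrix(
            [[0, 4], [0, 2], [0, 2]], probe_ids=["zz", "bb", "aa"]
        )
        out = tm.variance_filter(mat, 2 / 3)
        assert sorted(out.probe_ids) == ["aa", "zz"]

    def test_bad_fraction(self):
        mat = make_matrix([[1, 2]])
        with pytest.raises(ValidationError):
            tm.variance_filter(mat, 0.0)


class TestCenteringAndStandardizing:
    def test_median_center_rows(self):
        mat = make_matrix([[1, 2, 3], [5, 5, 5]])
        out = tm.median_center(mat)
        np.testing.assert_allclose(out.values.iloc[0], [-1, 0, 1])
        np.testing.assert_allclose(out.values.iloc[1], [0, 0, 0])

    def test_median_center_idempotent(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.normal(size=(20, 7)))
        once = tm.median_center(mat)
        twice = tm.median_center(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_standardize_population_sd(self):
        mat = make_matrix([[0, 2]])
        out = tm.standardize_rows(mat)
        np.testing.assert_allclose(out.values.iloc[0], [-1, 1])

    def test_constant_rows_dropped_and_means_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 5))
        vals[3] = 2.5
        mat = make_matrix(vals)
        out = tm.standardize_rows(mat)
        assert out.n_probes == 9
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(out.values.std(axis=1, ddof=0), 1.0)


class TestSelectGroupSignificant:
    def test_separated_probe_selected_with_minimal_q(self, sheet):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(50, 8)) * 0.2
        vals[7] = [5, 5, 5, 0, 0, 0, 0, 0]  # trisomy-separated, noiseless
        mat = make_matrix(vals, sample_ids=sheet.sample_ids)
        out = tm.select_group_significant(mat, sheet, alpha=0.05)
        assert "p7" in set(out["probe_id"])
        assert out.iloc[0]["probe_id"] == "p7"

    def test_small_group_is_error(self, sheet):
        mat = make_matrix(np.zeros((3, 4)), sample_ids=["T1", "T2", "T3", "D1"])
        with pytest.raises(ValidationError, match="disomy8"):
            tm.select_group_significant(mat, sheet)

    def test_bh_step_up_hand_example(self):
        # q_i = min_{j>=i} (m p_j / j) on p=(0.01,0.02,0.03), m=3 -> all 0.03
        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_matches_brute_force_step_up(self, pvals):
        q = multipletests(pvals, method="fdr_bh")[1]
        m = len(pvals)
        order = np.argsort(pvals)
        brute = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            candidates = [
                m * pvals[j] / (list(order).index(j) + 1)
                for j in order[rank - 1:]
            ]
            brute[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, brute, rtol=1e-10)


def brute_force_average_linkage(D: np.ndarray):
    """Naive agglomerative average linkage; returns sorted merge heights."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestHca:
    def test_identical_samples_merge_first(self):
        mat = make_matrix(np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]]))
        res = tm.hca(mat, k=2, cluster_features=False)
        assert res.sample_linkage[0, 2] == 0.0  # first merge at distance 0
        assert res.sample_labels["s0"] == res.sample_labels["s1"]
        assert res.sample_labels["s0"] != res.sample_labels["s2"]

    def test_average_linkage_heights_match_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))  # 6 samples
        mat = make_matrix(X)
        res = tm.hca(mat, cluster_features=False)
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(X.T))
        expected = brute_force_average_linkage(D)
        np.testing.assert_allclose(sorted(res.sample_linkage[:, 2]), expected)

    def test_feature_metric_invariant_to_row_affine_scaling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 6))
        m1 = tm.hca(make_matrix(X), k=2)
        m2 = tm.hca(make_matrix(3.0 * X + 10.0), k=2)
        np.testing.assert_allclose(
            m1.feature_linkage[:, 2], m2.feature_linkage[:, 2], atol=1e-8
        )

    def test_too_few_items_is_error(self):
        with pytest.raises(ValidationError):
            tm.hca(make_matrix(np.zeros((3, 1))))


class TestTwoClassTTest:
    def test_welch_hand_computation(self):
        mat = make_matrix([[1, 2, 3, 4, 5, 6]],
                          sample_ids=list("abcdef"))
        p = tm.two_class_t_test(mat, ["a", "b", "c"], ["d", "e", "f"])
        t, p_ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p.iloc[0] == pytest.approx(0.0213, abs=2e-3)
        assert p.iloc[0] == pytest.approx(p_ref)

    def test_degenerate_constant_rows_return_p_one(self):
        mat = make_matrix([[2, 2, 2, 2], [1, 1, 3, 3]], sample_ids=list("abcd"))
        p = tm.two_class_t_test(mat, ["a", "b"], ["c", "d"])
        assert p.iloc[0] == 1.0  # identical means, zero variance
        assert p.iloc[1] == 0.0  # different means, zero variance

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        mat = make_matrix(rng.normal(size=(1000, 8)),
                          sample_ids=list("abcdefgh"))
        p = tm.two_class_t_test(mat, list("abcd"), list("efgh"))
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_is_error(self):
        mat = make_matrix(np.zeros((2, 3)), sample_ids=list("abc"))
        with pytest.raises(ValidationError):
            tm.two_class_t_test(mat, ["a"], ["b", "c"])


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(5, 5, 1.0), (7, 5, 4.0), (4, 5, -2.0), (5.5, 5, 2**0.5)]
    )
    def test_sign_convention(self, a, b, expected):
        assert tm.fold_change(a, b) == pytest.approx(expected)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_magnitude(self, a, b):
        fc = tm.fold_change(a, b)
        assert abs(fc) >= 1.0
        if a != b:
            assert fc == pytest.approx(-tm.fold_change(b, a), rel=1e-9)
        else:
            assert fc == 1.0


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20, 18, 20, 18), 1.0),   # ddCT = 0
            ((19, 18, 20, 18), 2.0),   # ddCT = -1
            ((20, 18, 22, 18), 4.0),   # ddCT = -2
        ],
    )
    def test_worked_examples(self, args, expected):
        assert tm.delta_delta_ct(*args) == pytest.approx(expected)


class TestSam:
    def test_spiked_probe_has_smallest_q(self, sheet):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(200, 8)) * 0.3
        vals[11, :3] += 8.0  # trisomy samples are columns 0..2
        mat = make_matrix(vals, sample_ids=sheet.sample_ids)
        res = tm.sam(mat, sheet, contrast=("trisomy8", "disomy8"),
                     n_permutations=100, seed=0)
        assert res["q"].idxmin() == "p11"
        assert res.loc["p11", "q"] <= res["q"].min() + 1e-12

    def test_d_scores_invariant_to_probe_constant_shift(self, sheet):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(50, 8))
        mat1 = make_matrix(vals, sample_ids=sheet.sample_ids)
        mat2 = make_matrix(vals + 100.0, sample_ids=sheet.sample_ids)
        r1 = tm.sam(mat1, sheet, n_permutations=60, seed=1)
        r2 = tm.sam(mat2, sheet, n_permutations=60, seed=1)
        np.testing.assert_allclose(r1["d"], r2["d"], atol=1e-8)

    def test_exchangeability_under_null(self, sheet):
        # permuting sample labels of null data leaves d-score quantiles stable
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(300, 8))
        mat = make_matrix(vals, sample_ids=sheet.sample_ids)
        shuffled = make_matrix(vals[:, rng.permutation(8)],
                               sample_ids=sheet.sample_ids)
        r1 = tm.sam(mat, sheet, n_permutations=56, seed=2)
        r2 = tm.sam(shuffled, sheet, n_permutations=56, seed=2)
        q1 = np.percentile(r1["d"], [10, 50, 90])
        q2 = np.percentile(r2["d"], [10, 50, 90])
        np.testing.assert_allclose(q1, q2, atol=0.35)

    def test_multiclass_detects_group_structure(self, sheet):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(100, 8)) * 0.3
        vals[5, 3:6] += 6.0  # disomy-specific shift: invisible to no contrast
        mat = make_matrix(vals, sample_ids=sheet.sample_ids)
        res = tm.sam(mat, sheet, contrast="multiclass", n_permutations=100, seed=3)
        assert res["d"].idxmax() == "p5"

    def test_too_few_permutations_is_error(self, sheet):
        mat = make_matrix(np.zeros((5, 8)), sample_ids=sheet.sample_ids)
        with pytest.raises(ValidationError):
            tm.sam(mat, sheet, n_permutations=10)

    def test_q_monotone_in_abs_d(self, sheet):
        rng = np.random.default_rng(10)
        mat = make_matrix(rng.normal(size=(80, 8)), sample_ids=sheet.sample_ids)
        res = tm.sam(mat, sheet, n_permutations=56, seed=4)
        ordered = res.sort_values("d", key=np.abs, ascending=False)["q"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()


class TestCallTrisomyGenes:
    def test_intersection_rule_requires_all_four(self, sheet):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(60, 8)) * 0.25
        # strong true effect in trisomy group only
        vals[3, :3] += 3.0
        # disomy-vs-reference difference only: passes neither trisomy contrast
        vals[4, 3:6] += 3.0
        mat = make_matrix(vals, sample_ids=sheet.sample_ids)
        calls = tm.call_trisomy_genes(mat, sheet, tm.Config(n_permutations=100))
        assert bool(calls.loc["p3", "trisomy_associated"])
        assert not bool(calls.loc["p4", "trisomy_associated"])
        flags = (
            (calls["t_p_vs_disomy"] < 0.05)
            & (calls["t_p_vs_all"] < 0.05)
            & (calls["sam_q_vs_disomy"] <= 0.10)
            & (calls["sam_q_vs_all"] <= 0.10)
        )
        pd.testing.assert_series_equal(
            calls["trisomy_associated"], flags, check_names=False
        )

    def test_null_simulation_flags_almost_nothing(self, sheet):
        rng = np.random.default_rng(12)
        mat = make_matrix(rng.normal(size=(300, 8)), sample_ids=sheet.sample_ids)
        calls = tm.call_trisomy_genes(mat, sheet, tm.Config(n_permutations=100))
        assert int(calls["trisomy_associated"].sum()) <= 3


class TestChromosomeProfile:
    def test_zero_noise_full_dosage_fraction_is_one(self):
        mat, sheet, _ = tm.simulate_expression(
            n_genes_per_chrom={"chr8": 50, "chr2": 50},
            dosage_fraction=1.0, noise_sd=0.0, seed=0,
        )
        prof, frac = tm.chromosome_expression_profile(mat, sheet, "chr8")
        assert frac == 1.0
        assert list(prof["position"]) == sorted(prof["position"])

    def test_disomy_vs_reference_profile_centered_at_zero(self, sim_expression):
        mat, sheet, _ = sim_expression
        prof, _ = tm.chromosome_expression_profile(mat, sheet, "chr8")
        # no disomy-vs-reference effect simulated
        diff = (prof["mean_disomy8"] - prof["mean_reference"]).mean()
        assert abs(diff) < 0.1

    def test_absent_chromosome_is_error(self, sim_expression):
        mat, sheet, _ = sim_expression
        with pytest.raises(ValidationError):
            tm.chromosome_expression_profile(mat, sheet, "chr99")


class TestSamQValueUnit:
    def test_median_fdr_on_constructed_null(self):
        # one real signal among nulls: its q must be the smallest
        d = np.array([0.1, -0.2, 5.0, 0.05])
        d_perm = np.vstack([np.array([0.1, -0.1, 0.2, -0.2])] * 60)
        q = _sam_q_values(d, d_perm)
        assert q[2] == q.min()
        assert (q >= 0).all() and (q <= 1).all()
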