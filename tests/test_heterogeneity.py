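"""Subject clustering, validity-index majority rule, Fisher-z comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import phenoblocks as pb


def _two_clouds(n=120, sep=6.0, d=3, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.standard_normal((n, d))
    X[half:] += sep
    idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    scores = pd.DataFrame(X, index=idx, columns=[f"LV{j + 1}" for j in range(d)])
    truth = np.repeat([1, 2], half)
    return scores, truth


@pytest.mark.filterwarnings("ignore:pairwise LV")
class TestKmeansSubjects:
    def test_separated_clouds_recovered(self):
        scores, truth = _two_clouds()
        assign = pb.kmeans_subjects(scores, 2, seed=0)
        assert adjusted_rand_score(truth, assign.labels.values) == 1.0

    def test_labels_ordered_by_size(self):
        scores, _ = _two_clouds(n=90)
        scores = scores.iloc[:80]  # 45 vs 35
        assign = pb.kmeans_subjects(scores, 2, seed=0)
        sizes = assign.sizes
        assert sizes.loc[1] >= sizes.loc[2]

    def test_deterministic_under_seed(self):
        scores, _ = _two_clouds(seed=3)
        a1 = pb.kmeans_subjects(scores, 2, seed=5)
        a2 = pb.kmeans_subjects(scores, 2, seed=5)
        pd.testing.assert_series_equal(a1.labels, a2.labels)

    def test_k_bounds(self):
        scores, _ = _two_clouds(n=10)
        with pytest.raises(ValueError):
            pb.kmeans_subjects(scores, 1)
        with pytest.raises(ValueError):
            pb.kmeans_subjects(scores, 10)

    def test_multicollinearity_warning(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        scores = pd.DataFrame({"LV1": x, "LV2": x + 0.1 * rng.standard_normal(100)})
        with pytest.warns(UserWarning, match="multicollinearity"):
            pb.kmeans_subjects(scores, 2, seed=0)

    def test_planted_groups_recovered_on_cohort(self, cohort_scores):
        scores, groups = cohort_scores
        assign = pb.kmeans_subjects(scores, 2, seed=0)
        acc = (assign.labels.values == groups.values).mean()
        acc = max(acc, 1 - acc)
        # planted 1.5-SD factor shift on 3 of 14 LVs: well above chance
        assert acc > 0.70


class TestSelectKMajority:
    def test_two_clouds_majority_two(self):
        scores, _ = _two_clouds(n=150, sep=5.0)
        k, votes = pb.select_k_majority(scores, range(2, 7), seed=0)
        assert k == 2
        assert (votes.dropna() == 2).mean() > 0.5

    def test_needs_five_indices(self):
        scores, _ = _two_clouds()
        with pytest.raises(ValueError, match="at least 5"):
            pb.select_k_majority(scores, range(2, 5), indices=["silhouette"])

    def test_majority_equals_single_index_when_unanimous(self):
        scores, _ = _two_clouds(n=100, sep=8.0)
        k_all, votes = pb.select_k_majority(scores, range(2, 6), seed=0)
        unanimous = votes.dropna().unique()
        if len(unanimous) == 1:
            assert k_all == unanimous[0]

    def test_k_range_validation(self):
        scores, _ = _two_clouds(n=20)
        with pytest.raises(ValueError, match="k_range"):
            pb.select_k_majority(scores, range(1, 5))


class TestSilhouette:
    def test_far_pairs_near_one(self):
        idx = pd.Index(list("abcd"), name="subject_id")
        scores = pd.DataFrame(
            {"LV1": [0.0, 0.1, 100.0, 100.1]}, index=idx
        )
        labels = pd.Series([1, 1, 2, 2], index=idx)
        vals, mean = pb.silhouette_report(scores, labels)
        assert mean > 0.99

    def test_arbitrary_split_near_zero(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"S{i}" for i in range(200)], name="subject_id")
        scores = pd.DataFrame(rng.standard_normal((200, 2)), index=idx,
                              columns=["LV1", "LV2"])
        labels = pd.Series(rng.integers(1, 3, 200), index=idx)
        _, mean = pb.silhouette_report(scores, labels)
        assert abs(mean) < 0.1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
        scores = pd.DataFrame(rng.standard_normal((n, 3)), index=idx,
                              columns=["LV1", "LV2", "LV3"])
        labels = pd.Series(rng.integers(1, 4, n), index=idx)
        vals, _ = pb.silhouette_report(scores, labels)
        X = scores.values
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        for i in range(n):
            own = labels.values == labels.values[i]
            a = D[i, own & (np.arange(n) != i)].mean()
            b = min(
                D[i, labels.values == g].mean()
                for g in np.unique(labels.values)
                if g != labels.values[i]
            )
            assert vals.iloc[i] == pytest.approx((b - a) / max(a, b), abs=1e-9)


class TestGroupLvTests:
    def test_planted_shift_highly_significant(self, cohort_scores):
        scores, groups = cohort_scores
        res = pb.group_lv_tests(scores, groups)
        for lv in ["LV5", "LV6", "LV7"]:
            assert res.loc[lv, "p"] < 0.05 / 14

    def test_null_type_one_error(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            x = rng.standard_normal(60)
            idx = pd.Index([f"S{i}" for i in range(60)], name="subject_id")
            scores = pd.DataFrame({"LV1": x}, index=idx)
            labels = pd.Series(np.repeat([1, 2], 30), index=idx)
            p = pb.group_lv_tests(scores, labels).loc["LV1", "p"]
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.035)

    def test_all_equal_p_one(self):
        idx = pd.Index([f"S{i}" for i in range(10)], name="subject_id")
        scores = pd.DataFrame({"LV1": np.ones(10)}, index=idx)
        labels = pd.Series(np.repeat([1, 2], 5), index=idx)
        with pytest.warns(UserWarning, match="all observations equal"):
            res = pb.group_lv_tests(scores, labels)
        assert res.loc["LV1", "p"] == 1.0


class TestFisherComparison:
    def test_equal_correlations_p_one(self):
        cmp = pb.compare_correlations_fisher(0.3, 100, 0.3, 50)
        assert cmp.z_stat == 0.0 and cmp.p == 1.0

    def test_published_group_contrast_moderate(self):
        # r = 0.12 (n 508) vs -0.03 (n 375): p near 0.03 from the rounded r
        cmp = pb.compare_correlations_fisher(0.12, 508, -0.03, 375)
        assert cmp.p == pytest.approx(0.028, abs=0.005)

    def test_published_sign_flip_magnitude(self):
        # r = -0.2 vs 0.17: p on the order of 1e-8
        cmp = pb.compare_correlations_fisher(-0.2, 508, 0.17, 375)
        assert 1e-9 < cmp.p < 1e-7

    @given(
        r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
        n1=st.integers(5, 500), n2=st.integers(5, 500),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, r1, r2, n1, n2):
        a = pb.compare_correlations_fisher(r1, n1, r2, n2)
        b = pb.compare_correlations_fisher(r2, n2, r1, n1)
        assert a.z_stat == pytest.approx(-b.z_stat, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_degenerate_r_raises(self):
        with pytest.raises(ValueError, match="Fisher"):
            pb.compare_correlations_fisher(1.0, 50, 0.2, 50)


class TestGroupwiseCorrelations:
    def test_copied_group_all_p_one(self):
        rng = np.random.default_rng(1)
        half = pd.DataFrame(
            rng.standard_normal((50, 3)), columns=["LV1", "LV2", "LV3"]
        )
        scores = pd.concat([half, half], ignore_index=True)
        scores.index = pd.Index([f"S{i}" for i in range(100)], name="subject_id")
        labels = pd.Series(np.repeat([1, 2], 50), index=scores.index)
        mats, comps = pb.groupwise_correlation_matrices(scores, labels)
        assert np.allclose(comps["p"], 1.0)
        for g in (1, 2):
            M = mats[g].values
            assert np.allclose(M, M.T) and np.allclose(np.diag(M), 1.0)

    def test_sign_flipped_coupling_flagged(self):
        rng = np.random.default_rng(2)
        n = 440
        z = rng.standard_normal(n)
        lv_a = z + 0.8 * rng.standard_normal(n)
        sign = np.repeat([1.0, -1.0], n // 2)
        lv_b = sign * z + 0.8 * rng.standard_normal(n)
        idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
        scores = pd.DataFrame(
            {"LV1": lv_a, "LV2": lv_b, "LV3": rng.standard_normal(n)}, index=idx
        )
        labels = pd.Series(np.repeat([1, 2], n // 2), index=idx)
        _, comps = pb.groupwise_correlation_matrices(scores, labels)
        flagged = comps.set_index(["lv_a", "lv_b"]).loc[("LV1", "LV2")]
        assert flagged["p_bh"] < 0.05
        assert flagged["r1"] > 0 > flagged["r2"]
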