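"""PLSPM engine: closed-form identities, sign alignment, parameter recovery."""
import numpy as np
import pandas as pd
import pytest

import phenoblocks as pb
from phenoblocks.blocks import BlockStructure

from conftest import exact_corr_pair, one_factor_block


class TestPathModel:
    def test_star_model_arc_count(self):
        blocks = BlockStructure({f"t{i}": i for i in range(1, 15)})
        model = pb.build_default_path_model(blocks, target_block=13)
        assert model.path.values.sum() == 13
        assert model.path.loc[13].drop(13).all()

    def test_two_blocks_one_arc(self):
        blocks = BlockStructure({"x": 1, "y": 2})
        model = pb.build_default_path_model(blocks, target_block=2)
        assert model.path.values.sum() == 1

    def test_target_by_trait_name(self):
        blocks = BlockStructure({"x": 1, "SPO2": 2})
        model = pb.build_default_path_model(blocks)
        assert model.path.loc[2, 1]

    def test_cyclic_matrix_rejected(self):
        blocks = BlockStructure({"x": 1, "y": 2})
        path = pd.DataFrame(
            [[False, True], [True, False]], index=[1, 2], columns=[1, 2]
        )
        with pytest.raises(ValueError, match="cycle"):
            pb.PathModel(blocks, path)

    def test_unknown_target_rejected(self):
        blocks = BlockStructure({"x": 1, "y": 2})
        with pytest.raises(KeyError):
            pb.build_default_path_model(blocks, target_block="nope")


class TestAlignSigns:
    def _anti_block(self, n=300, seed=4):
        rng = np.random.default_rng(seed)
        df, f = one_factor_block([0.8, 0.85, 0.8, 0.85], n, rng)
        df["m1"] = -df["m1"]  # MCH-like negated pair
        df["m4"] = -df["m4"]
        blocks = BlockStructure({c: 1 for c in df.columns})
        return df, blocks

    def test_exactly_the_negated_pair_flipped(self):
        df, blocks = self._anti_block()
        _, flipped = pb.align_signs(df, blocks)
        assert sorted(flipped) == ["m1", "m4"]

    def test_all_positive_block_untouched(self):
        rng = np.random.default_rng(0)
        df, _ = one_factor_block([0.8, 0.9], 200, rng)
        blocks = BlockStructure({c: 1 for c in df.columns})
        aligned, flipped = pb.align_signs(df, blocks)
        assert flipped == []
        pd.testing.assert_frame_equal(aligned, df)

    def test_idempotent(self):
        df, blocks = self._anti_block()
        once, _ = pb.align_signs(df, blocks)
        twice, flipped2 = pb.align_signs(once, blocks)
        assert flipped2 == []
        pd.testing.assert_frame_equal(once, twice)


class TestFitPlspm:
    def _two_block_model(self, df, split):
        blocks = BlockStructure(
            {c: (1 if c in split else 2) for c in df.columns}
        )
        return blocks, pb.build_default_path_model(blocks, target_block=2)

    def test_single_mv_blocks_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x", "y"])
        blocks, model = self._two_block_model(df, split={"x"})
        fit = pb.fit_plspm(df, model)
        assert fit.converged
        assert np.allclose(fit.loadings.values, 1.0)
        z = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
        assert np.allclose(fit.lv_scores["LV1"], z, atol=1e-12)

    def test_lv_scores_standardized(self, small_delta, small_cohort):
        _, _, _, blocks, _ = small_cohort
        aligned, _ = pb.align_signs(small_delta, blocks)
        fit = pb.fit_plspm(aligned, pb.build_default_path_model(blocks, "SPO2"))
        assert fit.converged
        assert np.all(np.abs(fit.lv_scores.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(fit.lv_scores.std(axis=0, ddof=0) - 1) < 1e-10)

    def test_two_mv_block_equal_loadings(self):
        # symmetric case: the anchor relates to both MVs through their
        # common direction, so mode A converges to the equal-weight
        # composite with loadings sqrt((1+r)/2)
        r = 0.6
        n = 4000
        df = exact_corr_pair(r, n=n, seed=8)
        common = (df["x1"] + df["x2"]).values
        df["target"] = 0.4 * common / common.std() + np.random.default_rng(
            9
        ).standard_normal(n)
        blocks, model = self._two_block_model(df, split={"x1", "x2"})
        fit = pb.fit_plspm(df, model)
        expected = np.sqrt((1 + r) / 2)
        assert fit.loadings["x1"] == pytest.approx(expected, abs=0.01)
        assert fit.loadings["x2"] == pytest.approx(expected, abs=0.01)

    def test_one_factor_loading_recovery(self):
        # composite loadings slightly exceed the planted factor loading
        # (the composite mixes in unique variance); within 0.05 at 4 MVs
        rng = np.random.default_rng(12)
        n = 2000
        df, f = one_factor_block([0.85, 0.85, 0.85, 0.85], n, rng)
        df["target"] = 0.4 * f + rng.standard_normal(n)
        blocks, model = self._two_block_model(df, split={"m1", "m2", "m3", "m4"})
        fit = pb.fit_plspm(df, model)
        assert fit.converged
        for mv in ["m1", "m2", "m3", "m4"]:
            assert fit.loadings[mv] == pytest.approx(0.85, abs=0.05)

    def test_zero_variance_mv_raises(self):
        df = pd.DataFrame({"x": np.ones(50), "y": np.arange(50.0)})
        blocks, model = self._two_block_model(df, split={"x"})
        with pytest.raises(ValueError, match="zero-variance"):
            pb.fit_plspm(df, model)


class TestUnidimensionality:
    def test_single_mv_block(self, small_delta):
        rep = pb.unidimensionality(small_delta, ["LLS"])
        assert (rep.c_alpha, rep.dg_rho, rep.eig_1st, rep.eig_2nd) == (1, 1, 1, 0)

    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 0.9])
    def test_two_mv_closed_forms(self, r):
        df = exact_corr_pair(r, n=300, seed=int(r * 100))
        rep = pb.unidimensionality(df, ["x1", "x2"])
        assert rep.eig_1st == pytest.approx(1 + r, abs=1e-9)
        assert rep.eig_2nd == pytest.approx(1 - r, abs=1e-9)
        assert rep.c_alpha == pytest.approx(2 * r / (1 + r), abs=1e-9)
        lam2 = (1 + r) / 2
        rho = (2 * np.sqrt(lam2)) ** 2 / ((2 * np.sqrt(lam2)) ** 2 + 2 * (1 - lam2))
        assert rep.dg_rho == pytest.approx(rho, abs=1e-9)

    def test_eigenvalue_trace_identity(self, small_delta, small_cohort):
        _, _, _, blocks, _ = small_cohort
        for b in [5, 6, 9]:
            members = blocks.members(b)
            R = np.corrcoef(small_delta[members].values, rowvar=False)
            rep = pb.unidimensionality(small_delta, members)
            evals = np.linalg.eigvalsh(R)
            assert evals.sum() == pytest.approx(len(members), abs=1e-9)
            assert rep.eig_1st == pytest.approx(evals.max(), abs=1e-9)

    def test_sign_alignment_inside_alpha(self):
        # a negated member must not wreck standardized alpha
        rng = np.random.default_rng(3)
        df, _ = one_factor_block([0.8, 0.8], 500, rng)
        plain = pb.unidimensionality(df, ["m1", "m2"])
        df["m1"] = -df["m1"]
        flipped = pb.unidimensionality(df, ["m1", "m2"])
        assert flipped.c_alpha == pytest.approx(plain.c_alpha, abs=1e-9)

    def test_report_covers_all_blocks(self, small_delta, small_cohort):
        _, _, _, blocks, _ = small_cohort
        report = pb.unidimensionality_report(small_delta, blocks)
        assert len(report) == 14
        assert report.loc["LV12", "n_mvs"] == 1
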