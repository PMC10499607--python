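import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulokit as rk
from regulokit.grn_infer import GRN


def _paired(expr: dict, access: dict, obs=None):
    e = pd.DataFrame(expr).T
    a = pd.DataFrame(access).T
    n = e.shape[1]
    cols = [f"o{i}" for i in range(n)]
    e.columns = cols
    a.columns = cols
    meta = obs if obs is not None else pd.DataFrame(index=cols)
    return rk.PairedMatrix(e, a, meta)


def _sites(*rows):
    return pd.DataFrame(
        rows, columns=["region_id", "motif_id", "tf", "strand", "offset", "logodds_score"]
    )


class TestBuildDesign:
    def test_column_is_expression_times_accessibility(self):
        data = _paired({"TF1": [1.0, 2.0], "G1": [0.0, 0.0]}, {"r1": [0.5, 1.0]})
        pairs = pd.DataFrame({"gene_id": ["G1"], "region_id": ["r1"]})
        sites = _sites(("r1", "M1", "TF1", "+", 0, 1.0))
        design, labels = rk.build_design("G1", pairs, sites, data, min_detect=0.0)
        np.testing.assert_allclose(design.iloc[:, 0], [0.5, 2.0])
        assert labels == [("TF1", "r1")]

    def test_self_loop_term_absent(self):
        data = _paired({"G1": [1.0, 2.0]}, {"r1": [0.5, 1.0]})
        pairs = pd.DataFrame({"gene_id": ["G1"], "region_id": ["r1"]})
        sites = _sites(("r1", "M1", "G1", "+", 0, 1.0))
        assert rk.build_design("G1", pairs, sites, data, min_detect=0.0) is None

    def test_duplicate_tf_region_pairs_collapse(self):
        data = _paired({"TF1": [1.0, 2.0], "G1": [0.0, 0.0]}, {"r1": [0.5, 1.0]})
        pairs = pd.DataFrame({"gene_id": ["G1"], "region_id": ["r1"]})
        sites = _sites(
            ("r1", "M1", "TF1", "+", 0, 1.0), ("r1", "M1", "TF1", "+", 7, 2.0)
        )
        design, _ = rk.build_design("G1", pairs, sites, data, min_detect=0.0)
        assert design.shape[1] == 1

    def test_low_detection_tf_dropped(self):
        e = np.zeros(100)
        e[:3] = 1.0  # 3% detection
        data = _paired(
            {"TF1": e, "G1": np.zeros(100)}, {"r1": np.full(100, 0.5)}
        )
        pairs = pd.DataFrame({"gene_id": ["G1"], "region_id": ["r1"]})
        sites = _sites(("r1", "M1", "TF1", "+", 0, 1.0))
        assert rk.build_design("G1", pairs, sites, data, min_detect=0.05) is None


class TestFitTargetModel:
    def test_noiseless_recovery_with_orthogonal_nuisance(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        x2 = rng.normal(size=200)
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # orthogonalize
        design = pd.DataFrame({"TF1|r1": x1, "TF2|r2": x2})
        fit = rk.fit_target_model(2.0 * x1, design)
        np.testing.assert_allclose(fit.terms["beta"], [2.0, 0.0], atol=1e-10)
        assert fit.terms["pval"].iloc[1] > 0.9

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        design = pd.DataFrame(x, columns=[f"T{i}|r{i}" for i in range(5)])
        fit = rk.fit_target_model(y, design)
        xd = np.column_stack([np.ones(200), x])
        oracle = np.linalg.solve(xd.T @ xd, xd.T @ y)
        np.testing.assert_allclose(fit.terms["beta"], oracle[1:], atol=1e-8)
        np.testing.assert_allclose(fit.intercept, oracle[0], atol=1e-8)

    def test_pvalues_match_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 3))
        y = x[:, 0] * 0.5 + rng.normal(size=80)
        design = pd.DataFrame(x, columns=[f"T{i}|r{i}" for i in range(3)])
        fit = rk.fit_target_model(y, design)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.terms["pval"], ref.pvalues[1:], atol=1e-10)
        np.testing.assert_allclose(fit.r_squared, ref.rsquared, atol=1e-10)

    def test_duplicated_column_dropped_fit_succeeds(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        design = pd.DataFrame({"A|r1": x, "B|r2": x.copy()})
        fit = rk.fit_target_model(x * 3.0, design)
        assert fit.status == "ok"
        assert len(fit.terms) == 1
        assert fit.dropped == [("B", "r2")]
        np.testing.assert_allclose(fit.terms["beta"], [3.0], atol=1e-8)

    def test_too_few_observations_is_no_model(self):
        design = pd.DataFrame(np.ones((3, 4)), columns=[f"T{i}|r" for i in range(4)])
        assert rk.fit_target_model(np.ones(3), design).status == "no-model"

    @pytest.mark.parametrize("method", ["ridge", "lasso", "elastic-net"])
    def test_regularized_methods_return_coefficients_without_pvalues(self, method):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 2))
        y = 2 * x[:, 0] + rng.normal(0, 0.1, 100)
        design = pd.DataFrame(x, columns=["A|r1", "B|r2"])
        fit = rk.fit_target_model(y, design, method=method)
        assert fit.terms["pval"].isna().all()
        assert abs(fit.terms["beta"].iloc[0]) > abs(fit.terms["beta"].iloc[1])


class TestInferGrn:
    def test_zero_fdr_threshold_empties_network(self, small_regulome):
        truth, data, regions, genes, motifs, genome = small_regulome
        pairs = rk.assign_regions_to_genes(regions, genes)
        grn, modules = rk.infer_grn(
            data, rk.truth_sites(truth), pairs, fdr_threshold=0.0
        )
        assert len(grn.significant) == 0
        assert modules == []

    def test_bh_fdr_nondecreasing_in_pvalue_rank(self, small_grn):
        grn, _ = small_grn
        ordered = grn.edges.sort_values("pval")
        assert (ordered["fdr"] >= ordered["pval"] - 1e-12).all()
        assert ordered["fdr"].cummax().equals(ordered["fdr"].cummax())

    def test_raising_threshold_only_adds_edges(self, small_grn):
        grn, _ = small_grn
        loose = GRN(grn.edges, fdr_threshold=0.2).significant
        tight = GRN(grn.edges, fdr_threshold=0.01).significant
        tight_keys = set(map(tuple, tight[["tf", "region_id", "target"]].values))
        loose_keys = set(map(tuple, loose[["tf", "region_id", "target"]].values))
        assert tight_keys <= loose_keys

    def test_coefficients_match_pseudoinverse_solve(self, small_regulome, small_grn):
        truth, data, *_ = small_regulome
        grn, _ = small_grn
        target = truth.target_ids[0]
        sub = grn.edges.loc[grn.edges["target"] == target]
        cols = [
            data.expression.loc[tf].to_numpy() * data.accessibility.loc[rid].to_numpy()
            for tf, rid in zip(sub["tf"], sub["region_id"])
        ]
        xd = np.column_stack([np.ones(data.n_obs)] + cols)
        beta = np.linalg.pinv(xd) @ data.expression.loc[target].to_numpy()
        np.testing.assert_allclose(sub["beta"], beta[1:], atol=1e-8)

    def test_parameter_recovery_on_simulated_truth(self, small_regulome, small_grn):
        truth, *_ = small_regulome
        grn, _ = small_grn
        merged = grn.edges.merge(truth.wiring, on=["tf", "region_id", "target"])
        assert len(merged) == len(truth.wiring)
        assert stats.pearsonr(merged["beta"], merged["beta_true"])[0] > 0.9

    def test_modules_split_by_sign_and_disjoint(self, small_grn):
        grn, modules = small_grn
        assert modules
        sig = grn.significant
        for m in modules:
            overlap_backed = m.positive_targets | m.negative_targets
            backed = set(sig.loc[sig["tf"] == m.tf, "target"])
            assert overlap_backed <= backed
            sub = sig.loc[sig["tf"] == m.tf]
            only_pos = set(sub.loc[sub["beta"] > 0, "target"]) - set(sub.loc[sub["beta"] < 0, "target"])
            assert only_pos <= m.positive_targets

    def test_permutation_breaks_significance(self, small_regulome):
        truth, data, regions, genes, motifs, genome = small_regulome
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n_obs)
        expr = data.expression.copy()
        expr.loc[truth.target_ids] = expr.loc[truth.target_ids].to_numpy()[:, perm]
        shuffled = rk.PairedMatrix(expr, data.accessibility, data.obs_meta)
        pairs = rk.assign_regions_to_genes(regions, genes)
        grn, _ = rk.infer_grn(shuffled, rk.truth_sites(truth), pairs)
        # with the target decoupled from its design, few targets stay significant
        frac = grn.significant["target"].nunique() / len(truth.target_ids)
        assert frac <= 0.1


class TestTfActivity:
    def _grn_edges(self, betas):
        return pd.DataFrame(
            {
                "tf": ["TF1"] * len(betas),
                "region_id": [f"r{i}" for i in range(len(betas))],
                "target": [f"G{i}" for i in range(len(betas))],
                "beta": betas,
            }
        )

    def test_mean_beta_times_mean_expression(self):
        data = _paired({"TF1": [1.0, 3.0]}, {"r1": [0.5, 0.5]})
        act = rk.tf_activity_in_branch(self._grn_edges([1.0, 3.0]), data, ["o0", "o1"])
        assert act["TF1"] == pytest.approx(2.0 * 2.0)

    def test_negative_betas_give_negative_activity(self):
        data = _paired({"TF1": [2.0, 2.0]}, {"r1": [0.5, 0.5]})
        act = rk.tf_activity_in_branch(self._grn_edges([-1.0, -3.0]), data, ["o0", "o1"])
        assert act["TF1"] < 0

    def test_zero_expression_zero_activity(self):
        data = _paired({"TF1": [0.0, 0.0]}, {"r1": [0.5, 0.5]})
        act = rk.tf_activity_in_branch(self._grn_edges([1.0]), data, ["o0", "o1"])
        assert act["TF1"] == 0.0
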