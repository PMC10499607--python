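import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulokit as rk
from regulokit.core_io import ValidationError
from regulokit.perturb import _lor_from_counts


class TestAssignGuides:
    def test_separable_mixture_recovers_high_component(self):
        counts = pd.DataFrame(
            {"g1": [1, 1, 2, 50, 60, 55, 1, 2, 58, 52, 1, 61]},
            index=[f"c{i}" for i in range(12)],
        )
        x = rk.assign_guides(counts, seed=0)
        expected = (counts["g1"] >= 50).astype(int)
        np.testing.assert_array_equal(x["g1"], expected)

    def test_zero_counts_never_assigned(self):
        counts = pd.DataFrame({"g1": [0, 0, 50, 60, 3, 2, 55, 58, 1, 2, 49, 61]})
        x = rk.assign_guides(counts, seed=0)
        assert (x.loc[counts["g1"] == 0, "g1"] == 0).all()

    def test_degenerate_counts_fall_back_with_warning(self):
        counts = pd.DataFrame({"g1": [7] * 20})
        with pytest.warns(UserWarning, match="fall"):
            x = rk.assign_guides(counts, seed=0)
        assert (x["g1"] == 0).all()  # ln 7 < ln 10 fallback threshold

    def test_too_few_nonzero_fall_back(self):
        counts = pd.DataFrame({"g1": [0] * 10 + [100, 2]})
        with pytest.warns(UserWarning):
            x = rk.assign_guides(counts, seed=0)
        assert x["g1"].tolist() == [0] * 10 + [1, 0]

    def test_deterministic_and_relabel_invariant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.integers(1, 4, 30), rng.integers(40, 80, 30)])
        rng.shuffle(vals)
        counts = pd.DataFrame(vals.reshape(20, 3), columns=list("abc"))
        x1 = rk.assign_guides(counts, seed=5)
        x2 = rk.assign_guides(counts, seed=5)
        assert x1.equals(x2)
        relabeled = counts.rename(columns={"a": "z"})[["b", "c", "z"]]
        x3 = rk.assign_guides(relabeled, seed=5)
        np.testing.assert_array_equal(x1["a"], x3["z"])


class TestPerturbationProbability:
    def _run(self, sim, seed=0):
        X = rk.assign_guides(sim.umi_counts, seed=seed)
        return X, rk.perturbation_probability(
            sim.expression, X,
            sim.obs_meta[["n_features", "organoid", "cell_type"]],
            sim.guide_map, seed=seed,
        )

    def test_probability_bounds_and_noncarrier_zero(self, screen_sim):
        X, pp = self._run(screen_sim)
        p = pp.per_guide.to_numpy()
        finite = p[~np.isnan(p)]
        assert ((finite >= 0) & (finite <= 1)).all()
        assert (pp.per_guide.to_numpy()[X.to_numpy() == 0][~np.isnan(
            pp.per_guide.to_numpy()[X.to_numpy() == 0])] == 0).all()

    def test_target_level_is_max_over_guides(self, screen_sim):
        X, pp = self._run(screen_sim)
        target = screen_sim.guide_map.iloc[0]
        guides = [g for g in X.columns if screen_sim.guide_map[g] == target]
        block = pp.per_guide[guides].fillna(0.0)
        np.testing.assert_allclose(pp.per_target[target], block.max(axis=1))

    def test_no_effect_guides_sit_near_half_for_carriers(self):
        # with a zero coefficient the squared-error delta is 0 and
        # logistic(0) = 0.5 exactly; the fitted coefficient is only
        # approximately zero (and correlates with the carriers' residuals),
        # so probabilities hover moderately above one half without saturating
        sim = rk.simulate_screen(
            n_cells=600, targets=["T0", "T1"], seed=3, expr_effect=0.0
        )
        X, pp = self._run(sim, seed=3)
        carriers = pp.per_guide.to_numpy()[X.to_numpy() == 1]
        carriers = carriers[~np.isnan(carriers)]
        assert abs(np.median(carriers) - 0.5) < 0.2
        assert np.median(carriers) < 0.9

    def test_huge_effect_saturates_probability(self):
        sim = rk.simulate_screen(
            n_cells=600, targets=["T0", "T1"], seed=4,
            expr_effect=4.0, escaper_fraction=0.0, n_effect_genes=40,
        )
        X, pp = self._run(sim, seed=4)
        carriers_p = pp.per_guide.to_numpy()[X.to_numpy() == 1]
        carriers_p = carriers_p[~np.isnan(carriers_p)]
        assert np.median(carriers_p) > 0.95

    def test_rare_guides_reported_missing(self):
        sim = rk.simulate_screen(n_cells=400, targets=["T0", "T1"], seed=5)
        X = rk.assign_guides(sim.umi_counts, seed=5)
        X = X.copy()
        rare = X.columns[0]
        X.loc[:, rare] = 0
        X.iloc[:2, 0] = 1  # only 2 carriers
        pp = rk.perturbation_probability(
            sim.expression, X,
            sim.obs_meta[["n_features", "organoid", "cell_type"]],
            sim.guide_map, seed=5,
        )
        assert pp.per_guide[rare].isna().all()


class TestKoEffects:
    def test_constructed_shift_detected_with_sign(self):
        rng = np.random.default_rng(0)
        n = 400
        y = pd.DataFrame(
            rng.normal(1, 0.3, (n, 30)), columns=[f"gene{i}" for i in range(30)]
        )
        p = pd.DataFrame({"T0": (np.arange(n) < 150).astype(float)})
        y.loc[p["T0"] == 1, "gene0"] -= 0.5
        cov = pd.DataFrame({"n_features": rng.normal(size=n)})
        res = rk.ko_transcriptomic_effects(y, p, cov)
        hit = res.set_index(["gene", "target"]).loc[("gene0", "T0")]
        assert hit["de"]
        assert hit["coef"] < 0
        null_hits = res.loc[(res["gene"] != "gene0") & res["de"]]
        assert len(null_hits) == 0

    def test_zero_fdr_threshold_empties_de(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame(rng.normal(size=(100, 10)))
        p = pd.DataFrame({"T0": rng.integers(0, 2, 100).astype(float)})
        res = rk.ko_transcriptomic_effects(y, p, pd.DataFrame({"n_features": rng.normal(size=100)}), fdr=0.0)
        assert not res["de"].any()


class TestCmh:
    def test_balanced_identical_strata_are_null(self):
        tables = np.array([[[5, 5], [5, 5]], [[5, 5], [5, 5]]], dtype=float)
        stat, p = rk.cmh_test(tables)
        assert stat == 0.0
        assert p == 1.0

    def test_matches_reference_implementation(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(3)
        for _ in range(5):
            tables = rng.integers(1, 50, size=(3, 2, 2)).astype(float)
            stat, p = rk.cmh_test(tables)
            ref = StratifiedTable(list(tables)).test_null_odds(correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_single_stratum_equals_closed_form(self):
        a, b, c, d = 12.0, 5.0, 7.0, 20.0
        stat, _ = rk.cmh_test(np.array([[[a, b], [c, d]]]))
        n = a + b + c + d
        expected = (n - 1) * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_all_zero_strata_give_p_one(self):
        assert rk.cmh_test(np.zeros((2, 2, 2))) == (0.0, 1.0)


class TestComposition:
    def test_lor_formula_on_printed_toy_table(self):
        assert _lor_from_counts(10, 90, 5, 195) == pytest.approx(
            np.log((10 / 90) / (5 / 195))
        )
        assert _lor_from_counts(10, 90, 5, 195) == pytest.approx(1.466, abs=1e-3)

    def test_zero_cell_correction_keeps_lor_finite(self):
        assert np.isfinite(_lor_from_counts(0, 10, 5, 5))

    def test_enriched_target_survives_filters_with_max_lor(self, screen_sim):
        X = rk.assign_guides(screen_sim.umi_counts, seed=5)
        res = rk.composition_enrichment(
            X, screen_sim.obs_meta["branch"], screen_sim.obs_meta["organoid"],
            screen_sim.guide_map,
        )
        assert res.max_lor.idxmax() == "T0"
        t0 = res.lor.loc[res.lor["target"] == "T0"].set_index("branch")["lor"]
        assert t0.idxmax() == "ventral"
        survivors = res.per_guide_branch.loc[res.per_guide_branch["pass2"]]
        assert set(survivors["target"]) == {"T0"}

    def test_single_organoid_significance_fails_filter_one(self):
        # construct a guide enriched only inside one organoid
        rng = np.random.default_rng(0)
        n = 800
        cells = [f"c{i}" for i in range(n)]
        org = pd.Series(np.where(np.arange(n) < 400, "o1", "o2"), index=cells)
        branch = pd.Series(rng.choice(["x", "y"], n), index=cells)
        x = pd.DataFrame(0, index=cells, columns=["gA_1", "gA_2"])
        carriers = rng.choice(400, 60, replace=False)  # all in organoid o1
        x.iloc[carriers, 0] = 1
        branch.iloc[carriers] = "x"  # strong enrichment, one organoid only
        x.iloc[rng.choice(np.arange(400, 800), 40, replace=False), 1] = 1
        res = rk.composition_enrichment(
            x, branch, org, pd.Series({"gA_1": "A", "gA_2": "A"})
        )
        assert not res.per_guide_branch["pass1"].any()

    def test_opposite_direction_partners_fail_filter_two(self):
        rng = np.random.default_rng(1)
        n = 1200
        cells = [f"c{i}" for i in range(n)]
        org = pd.Series(rng.choice(["o1", "o2", "o3"], n), index=cells)
        branch = pd.Series(rng.choice(["x", "y"], n), index=cells)
        x = pd.DataFrame(0, index=cells, columns=["gA_1", "gA_2"])
        c1 = rng.choice(n, 150, replace=False)
        x.iloc[c1, 0] = 1
        branch.iloc[c1] = "x"  # guide 1 enriched in x
        c2 = np.setdiff1d(rng.choice(n, 300, replace=False), c1)[:150]
        x.iloc[c2, 1] = 1
        branch.iloc[c2] = "y"  # guide 2 enriched in y (opposite direction)
        res = rk.composition_enrichment(
            x, branch, org, pd.Series({"gA_1": "A", "gA_2": "A"})
        )
        assert res.per_guide_branch["pass1"].any()
        assert not res.per_guide_branch["pass2"].any()

    def test_single_organoid_dataset_rejected(self):
        x = pd.DataFrame({"g": [1, 0]}, index=["c1", "c2"])
        with pytest.raises(ValidationError):
            rk.composition_enrichment(
                x, pd.Series(["a", "b"], index=x.index),
                pd.Series(["o1", "o1"], index=x.index), pd.Series({"g": "T"}),
            )
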