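import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulokit as rk
from regulokit.core_io import ValidationError


def _expr(n_genes=60, n_obs=300, seed=0):
    rng = np.random.default_rng(seed)
    mat = np.maximum(rng.normal(1.0, 0.5, (n_genes, n_obs)), 0.0)
    return pd.DataFrame(
        mat, index=[f"g{i}" for i in range(n_genes)], columns=[f"o{i}" for i in range(n_obs)]
    )


class TestGeneModuleScore:
    def test_random_module_centres_on_zero(self):
        expr = _expr()
        pool = list(expr.index)
        rng = np.random.default_rng(1)
        means = []
        for d in range(50):
            module = list(rng.choice(pool, size=6, replace=False))
            means.append(rk.gene_module_score(expr, module, pool, seed=d).mean())
        assert abs(np.mean(means)) < 0.05

    def test_shift_against_bin_mates_scores_positive(self):
        # the score compares module genes to expression-bin-matched controls,
        # so an upward shift relative to the genes sharing their bins must
        # come out positive (it is attenuated below the raw +1 because the
        # shift also moves the module into higher-expression bins)
        expr = _expr(n_genes=500, seed=2)
        module = [f"g{i}" for i in range(5)]
        shifted = expr.copy()
        shifted.loc[module] += 1.0
        score = rk.gene_module_score(shifted, module, list(shifted.index), seed=0)
        assert score.mean() > 0.4
        null = rk.gene_module_score(expr, module, list(expr.index), seed=0)
        assert score.mean() > null.mean() + 0.3

    def test_deterministic(self):
        expr = _expr()
        pool = list(expr.index)
        a = rk.gene_module_score(expr, pool[:4], pool, seed=3)
        b = rk.gene_module_score(expr, pool[:4], pool, seed=3)
        assert a.equals(b)

    def test_empty_module_rejected(self):
        expr = _expr()
        with pytest.raises(ValidationError):
            rk.gene_module_score(expr, [], list(expr.index))

    def test_module_outside_pool_rejected(self):
        expr = _expr()
        with pytest.raises(ValidationError):
            rk.gene_module_score(expr, ["nope"], list(expr.index))


class TestRegulatoryModuleDeviation:
    def test_uniform_module_deviates_nowhere(self):
        rng = np.random.default_rng(0)
        access = pd.DataFrame(
            np.clip(rng.normal(0.5, 0.02, (40, 100)), 0, 1),
            index=[f"r{i}" for i in range(40)],
        )
        z = rk.regulatory_module_deviation(access, [f"r{i}" for i in range(5)], seed=0)
        assert np.abs(z).mean() < 2.0

    def test_branch_specific_module_has_signed_contrast(self):
        rng = np.random.default_rng(1)
        n_obs = 120
        in_a = np.arange(n_obs) < 60
        access = np.clip(rng.normal(0.5, 0.05, (40, n_obs)), 0, 1)
        module = [f"r{i}" for i in range(5)]
        access[:5, in_a] = np.clip(rng.normal(0.9, 0.02, (5, 60)), 0, 1)
        access[:5, ~in_a] = np.clip(rng.normal(0.1, 0.02, (5, 60)), 0, 1)
        df = pd.DataFrame(access, index=[f"r{i}" for i in range(40)])
        z = rk.regulatory_module_deviation(df, module, seed=0)
        assert z[in_a].mean() > 1.0
        assert z[~in_a].mean() < -1.0

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        access = pd.DataFrame(rng.random((30, 50)), index=[f"r{i}" for i in range(30)])
        a = rk.regulatory_module_deviation(access, ["r0", "r1"], seed=9)
        b = rk.regulatory_module_deviation(access, ["r0", "r1"], seed=9)
        assert a.equals(b)


class TestVarianceExplained:
    def test_pure_pseudotime_signal(self):
        pt = np.linspace(0, 1, 100)
        branch = np.array(["a", "b"] * 50)
        r2b, r2p, r2both = rk.variance_explained(pt, branch, pt)
        assert r2p == pytest.approx(1.0)
        assert r2both == pytest.approx(1.0)

    def test_pure_branch_signal(self):
        branch = np.array(["a"] * 50 + ["b"] * 50)
        act = (branch == "a").astype(float)
        r2b, r2p, _ = rk.variance_explained(act, branch, np.linspace(0, 1, 100))
        assert r2b == pytest.approx(1.0)

    def test_independent_noise_explains_nothing(self):
        rng = np.random.default_rng(0)
        act = rng.normal(size=500)
        branch = rng.choice(["a", "b"], 500)
        pt = rng.uniform(size=500)
        r2b, r2p, r2both = rk.variance_explained(act, branch, pt)
        assert max(r2b, r2p, r2both) <= 0.05

    def test_nesting_inequality(self):
        rng = np.random.default_rng(1)
        act = rng.normal(size=200)
        branch = rng.choice(["a", "b", "c"], 200)
        pt = rng.uniform(size=200)
        r2b, r2p, r2both = rk.variance_explained(act, branch, pt)
        assert r2both >= max(r2b, r2p) - 1e-10

    def test_constant_activity_all_zero(self):
        out = rk.variance_explained(
            np.ones(50), np.array(["a", "b"] * 25), np.linspace(0, 1, 50)
        )
        assert out == (0.0, 0.0, 0.0)


class TestDifferentialModuleActivity:
    def _inputs(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        obs = [f"o{i}" for i in range(200)]
        branch = pd.Series(rng.choice(["A", "B"], 200), index=obs)
        pt = pd.Series(rng.uniform(size=200), index=obs)
        act = pd.DataFrame(
            rng.normal(size=(10, 200)), index=[f"m{i}" for i in range(10)], columns=obs
        )
        act.loc["m0", branch == "A"] += shift
        return act, branch, pt

    def test_identical_distributions_not_returned(self):
        act, branch, pt = self._inputs(shift=0.0)
        out = rk.differential_module_activity(act, branch, pt, ("A", "B"))
        assert len(out["A"]) == 0 and len(out["B"]) == 0

    def test_strong_shift_ranked_first(self):
        act, branch, pt = self._inputs(shift=3.0)
        out = rk.differential_module_activity(act, branch, pt, ("A", "B"))
        assert out["A"].iloc[0]["module"] == "m0"
        assert "m0" not in set(out["B"]["module"])

    def test_top_k_clamped_to_qualifying(self):
        act, branch, pt = self._inputs(shift=3.0)
        out = rk.differential_module_activity(act, branch, pt, ("A", "B"), top_k=100)
        assert len(out["A"]) <= 10

    def test_empty_branch_after_restriction_rejected(self):
        act, branch, pt = self._inputs()
        pt[branch == "A"] = 0.0  # branch A never in the top quantile
        with pytest.raises(ValidationError):
            rk.differential_module_activity(act, branch, pt, ("A", "B"), quantile=0.9)

    def test_wilcoxon_matches_exact_permutation_for_tiny_groups(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        stat = stats.mannwhitneyu(x, y, alternative="two-sided")
        # exact oracle: enumerate all label permutations of the pooled sample
        pooled = np.concatenate([x, y])
        obs_u = stat.statistic
        n = len(x)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n):
            xa = pooled[list(idx)]
            ya = np.delete(pooled, list(idx))
            ranks = stats.rankdata(np.concatenate([xa, ya]))
            u = ranks[:n].sum() - n * (n + 1) / 2
            us.append(u)
        us = np.asarray(us)
        mu = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(us - mu) >= np.abs(obs_u - mu) - 1e-9)
        assert stat.pvalue == pytest.approx(p_exact, abs=1e-9)


class TestBranchActivationScore:
    def test_perfectly_tracking_module(self):
        obs = [f"o{i}" for i in range(50)]
        p = pd.Series(np.linspace(0, 1, 50), index=obs)
        expr = pd.DataFrame(
            {o: [p[o], p[o], 1 - p[o]] for o in obs}, index=["g1", "g2", "g3"]
        )
        out = rk.branch_activation_score(expr, {"up": ["g1", "g2"], "down": ["g3"]}, p)
        assert out.loc["up", "mean_corr"] == pytest.approx(1.0)
        assert out.loc["down", "mean_corr"] == pytest.approx(-1.0)

    def test_z_scores_use_population_sd(self):
        obs = [f"o{i}" for i in range(30)]
        p = pd.Series(np.linspace(0, 1, 30), index=obs)
        expr = pd.DataFrame({o: [p[o], 1 - p[o]] for o in obs}, index=["g1", "g2"])
        out = rk.branch_activation_score(expr, {"a": ["g1"], "b": ["g2"]}, p)
        np.testing.assert_allclose(sorted(out["z"]), [-1.0, 1.0], atol=1e-9)

    def test_constant_genes_skipped_and_counted(self):
        obs = [f"o{i}" for i in range(20)]
        p = pd.Series(np.linspace(0, 1, 20), index=obs)
        expr = pd.DataFrame(
            {o: [p[o], 0.7] for o in obs}, index=["g1", "gconst"]
        )
        out = rk.branch_activation_score(expr, {"m": ["g1", "gconst"]}, p)
        assert out.loc["m", "n_skipped"] == 1
        assert out.loc["m", "n_genes"] == 1

    def test_spearman_invariant_to_monotone_transform(self):
        obs = [f"o{i}" for i in range(40)]
        p = pd.Series(np.linspace(0.01, 0.99, 40), index=obs)
        expr = pd.DataFrame({o: [np.exp(3 * p[o])] for o in obs}, index=["g1"])
        out = rk.branch_activation_score(expr, {"m": ["g1"]}, p, method="spearman")
        assert out.loc["m", "mean_corr"] == pytest.approx(1.0)
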