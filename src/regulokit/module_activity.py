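"""Per-observation TF-module activity scores and their branch/pseudotime structure.

A TF's activity is proxied by the expression of its regulated gene set (gene
module) or the accessibility of its regulatory regions (regulatory module).
Gene-module scores subtract bin-matched control genes from the module mean;
regulatory-module deviations are background-matched z-scores.  Downstream
summaries decompose activity variance into branch and pseudotime components,
rank branch-upregulated modules by a rank-sum test, and correlate module gene
expression with branch (absorption) probabilities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError


def gene_module_score(
    expr: pd.DataFrame,
    module_genes: Sequence[str],
    pool_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Module mean expression minus bin-matched control mean, per observation.

    Pool genes are binned into ``n_bins`` expression-average bins; each module
    gene draws ``n_ctrl`` controls from its own bin (with replacement), so the
    expected score of a random module is 0.
    """
    module = [g for g in module_genes]
    if not module:
        raise ValidationError("empty module")
    pool = list(pool_genes)
    missing = set(module) - set(pool)
    if missing:
        raise ValidationError(f"module genes outside pool: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    avg = expr.loc[pool].mean(axis=1)
    n_bins = min(n_bins, len(pool))
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    by_bin = {b: avg.index[bins == b].to_numpy() for b in range(n_bins)}

    controls: list[str] = []
    for gene in module:
        candidates = by_bin[int(bins.loc[gene])]
        controls.extend(rng.choice(candidates, size=n_ctrl, replace=True))
    module_mean = expr.loc[module].mean(axis=0)
    ctrl_mean = expr.loc[controls].mean(axis=0)
    return module_mean - ctrl_mean


def regulatory_module_deviation(
    access: pd.DataFrame,
    module_regions: Sequence[str],
    background_draws: int = 50,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Background-matched accessibility deviation z per observation.

    The observed signal is the mean accessibility of the module regions; the
    expectation and spread come from ``background_draws`` random region sets
    matched on mean-accessibility quantile bins.  A degenerate background
    (sd 0) yields z = 0.
    """
    module = list(module_regions)
    if not module:
        raise ValidationError("empty module region set")
    rng = np.random.default_rng(seed)
    avg = access.mean(axis=1)
    n_bins = min(n_bins, len(access))
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    by_bin = {b: avg.index[bins == b].to_numpy() for b in range(n_bins)}

    observed = access.loc[module].mean(axis=0).to_numpy()
    bg = np.empty((background_draws, access.shape[1]))
    module_bins = [int(bins.loc[r]) for r in module]
    for d in range(background_draws):
        sampled = [rng.choice(by_bin[b]) for b in module_bins]
        bg[d] = access.loc[sampled].mean(axis=0).to_numpy()
    expected = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    z = np.zeros_like(observed)
    ok = sd > 0
    z[ok] = (observed[ok] - expected[ok]) / sd[ok]
    return pd.Series(z, index=access.columns)


def variance_explained(
    activity: pd.Series | np.ndarray,
    branch: Sequence[str] | np.ndarray,
    pseudotime: Sequence[float] | np.ndarray,
) -> tuple[float, float, float]:
    """R^2 of activity ~ branch, ~ pseudotime, and ~ branch + pseudotime."""
    y = np.asarray(activity, dtype=float)
    branch = np.asarray(branch)
    pt = np.asarray(pseudotime, dtype=float)
    if len(y) < 3:
        raise ValidationError("need at least 3 observations")
    if len(np.unique(branch)) < 2:
        raise ValidationError("need at least 2 branches")
    if np.allclose(y, y[0]):
        return 0.0, 0.0, 0.0

    dummies = pd.get_dummies(pd.Series(branch), drop_first=True).to_numpy(dtype=float)

    def _r2(x: np.ndarray) -> float:
        xd = np.column_stack([np.ones(len(y)), x])
        coef, _, _, _ = np.linalg.lstsq(xd, y, rcond=None)
        resid = y - xd @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        return float(1 - (resid @ resid) / ss_tot)

    return _r2(dummies), _r2(pt[:, None]), _r2(np.column_stack([dummies, pt]))


def differential_module_activity(
    activity: pd.DataFrame,
    branch: pd.Series,
    pseudotime: pd.Series,
    branch_pair: tuple[str, str],
    quantile: float = 0.7,
    top_k: int = 15,
    fdr: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Top branch-upregulated modules among late-pseudotime observations.

    Observations of the two branches above the pseudotime ``quantile`` enter a
    two-sided Wilcoxon rank-sum test per module; BH-corrected up-modules
    (FDR < ``fdr``) are ranked by mean activity difference and the ``top_k``
    returned per branch.
    """
    a_name, b_name = branch_pair
    sel = branch.isin(branch_pair)
    obs = branch.index[sel]
    cut = float(np.quantile(pseudotime.loc[obs], quantile))
    late = obs[pseudotime.loc[obs] > cut]
    in_a = late[branch.loc[late] == a_name]
    in_b = late[branch.loc[late] == b_name]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValidationError(
            f"branch empty after pseudotime restriction: {a_name}={len(in_a)}, "
            f"{b_name}={len(in_b)}"
        )
    xa = activity.loc[:, in_a].to_numpy()
    xb = activity.loc[:, in_b].to_numpy()
    res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
    _, adj, _, _ = multipletests(res.pvalue, method="fdr_bh")
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    table = pd.DataFrame(
        {
            "module": activity.index,
            "mean_diff": diff,
            "pval": res.pvalue,
            "fdr": adj,
        }
    )
    out = {}
    for name, sign in ((a_name, 1), (b_name, -1)):
        up = table.loc[(table["fdr"] < fdr) & (sign * table["mean_diff"] > 0)].copy()
        up["mean_diff_up"] = sign * up["mean_diff"]
        out[name] = (
            up.sort_values("mean_diff_up", ascending=False)
            .head(top_k)
            .reset_index(drop=True)
        )
    return out


def branch_activation_score(
    expr: pd.DataFrame,
    modules: Mapping[str, Sequence[str]],
    branch_probs: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """z-scored mean correlation of module gene expression with branch probability.

    Per gene the Pearson (default) or Spearman correlation with the branch
    probability is computed across observations; per module the mean of those
    correlations; across modules the means are z-scored with the population
    (n) standard deviation.  Constant genes are skipped and counted.
    """
    p = branch_probs.to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("branch probabilities must lie in [0, 1]")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for name, genes in modules.items():
        cors, skipped = [], 0
        for gene in genes:
            x = expr.loc[gene].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                skipped += 1
                continue
            cors.append(float(corr_fn(x, p)[0]))
        rows.append((name, np.mean(cors) if cors else np.nan, len(cors), skipped))
    out = pd.DataFrame(rows, columns=["module", "mean_corr", "n_genes", "n_skipped"])
    vals = out["mean_corr"].to_numpy()
    sd = np.nanstd(vals)  # population sd
    mean = np.nanmean(vals)
    out["z"] = (vals - mean) / sd if sd > 0 else 0.0
    return out.set_index("module")
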