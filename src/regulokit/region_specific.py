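"""Branch-specific GRN construction via accessibility-outlier analysis and pruning.

Per region, accessibility probabilities across high-resolution clusters are
trimmed-z-transformed after regressing out the per-cluster sequencing-depth
covariate; extreme clusters become close/open outliers (BH FDR < 0.01 on the
Gaussian tail probabilities).  A step-wise rule turns outliers into the set of
clusters where the region is accessible, a chi-square depletion test flags
regions inaccessible in a branch, and the global GRN is pruned accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import PairedMatrix, ValidationError
from .grn_infer import GRN


@dataclass
class AccessibilityOutliers:
    """Trimmed z-scores and close/open outlier flags per (region, cluster)."""

    z: pd.DataFrame
    p_close: pd.DataFrame
    p_open: pd.DataFrame
    close_flags: pd.DataFrame
    open_flags: pd.DataFrame
    degenerate: pd.Series  # regions whose trimmed sd was 0


def trimmed_z(
    access_by_cluster: pd.DataFrame,
    covariate: np.ndarray | pd.Series | None = None,
    lower: float = 5.0,
    upper: float = 95.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-region trimmed z-transformation of cluster accessibility.

    The covariate (mean ATAC reads per cluster) is regressed out first; the
    mean and s.d. are then computed only over clusters whose residual lies
    strictly between the 5th and 95th percentiles.  The strict band matters:
    a zero-inflated region places its closed clusters exactly at the lower
    percentile, and excluding them lets the trimmed moments describe the open
    clusters so closures of any size become detectable outliers.  When ties at
    a boundary empty the strict band, the inclusive band is used instead, and
    the trimmed s.d. is floored so a constant bulk makes any departing cluster
    an extreme outlier.  Regions whose residuals are all identical get z = 0
    and a degenerate flag.
    """
    x = access_by_cluster.to_numpy(dtype=float)
    n_regions, n_clusters = x.shape
    if n_clusters < 10:
        raise ValidationError(f"need >= 10 clusters for trimming, got {n_clusters}")
    if covariate is None:
        cov = np.zeros(n_clusters)
    else:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (n_clusters,):
            raise ValidationError("covariate length must equal number of clusters")
    design = np.column_stack([np.ones(n_clusters), cov])
    coef, _, _, _ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x.T - design @ coef  # clusters x regions

    z = np.zeros_like(resid)
    degenerate = np.zeros(n_regions, dtype=bool)
    lo = np.percentile(resid, lower, axis=0)
    hi = np.percentile(resid, upper, axis=0)
    for j in range(n_regions):
        r = resid[:, j]
        if np.ptp(r) < 1e-10:  # all clusters (residually) identical
            degenerate[j] = True
            continue
        band = r[(r > lo[j]) & (r < hi[j])]
        if len(band) < 2:
            # ties at a percentile boundary can empty the strict band
            # (e.g. one outlier against an otherwise constant bulk)
            band = r[(r >= lo[j]) & (r <= hi[j])]
        sd = band.std(ddof=1) if len(band) >= 2 else 0.0
        if not np.isfinite(sd):
            degenerate[j] = True
            continue
        # sd floor: a constant trimmed bulk makes any departure an extreme
        # outlier rather than a division error
        z[:, j] = (r - band.mean()) / max(sd, 1e-8)
    zdf = pd.DataFrame(
        z.T, index=access_by_cluster.index, columns=access_by_cluster.columns
    )
    return zdf, pd.Series(degenerate, index=access_by_cluster.index)


def call_outliers(
    z: pd.DataFrame,
    degenerate: pd.Series | None = None,
    fdr: float = 0.01,
) -> AccessibilityOutliers:
    """Close/open outlier flags at BH FDR < ``fdr``, per region across clusters.

    p_close = Phi(z) flags unusually low accessibility; p_open = 1 - Phi(z)
    flags unusually high accessibility.
    """
    zv = z.to_numpy(dtype=float)
    p_close = stats.norm.cdf(zv)
    p_open = stats.norm.sf(zv)

    def _bh_flags(p: np.ndarray) -> np.ndarray:
        flags = np.zeros_like(p, dtype=bool)
        for j in range(p.shape[0]):
            _, adj, _, _ = multipletests(p[j], method="fdr_bh")
            flags[j] = adj < fdr
        return flags

    close = _bh_flags(p_close)
    open_ = _bh_flags(p_open)
    if degenerate is not None:
        deg = degenerate.to_numpy(dtype=bool)
        close[deg] = False
        open_[deg] = False
    idx, cols = z.index, z.columns
    return AccessibilityOutliers(
        z=z,
        p_close=pd.DataFrame(p_close, index=idx, columns=cols),
        p_open=pd.DataFrame(p_open, index=idx, columns=cols),
        close_flags=pd.DataFrame(close, index=idx, columns=cols),
        open_flags=pd.DataFrame(open_, index=idx, columns=cols),
        degenerate=degenerate
        if degenerate is not None
        else pd.Series(False, index=idx),
    )


def accessible_clusters(outliers: AccessibilityOutliers) -> dict[str, set]:
    """Step-wise accessibility rule per region.

    With close outliers: all clusters except the close outliers.  Without close
    outliers: the open outliers if any exist, otherwise all clusters.
    """
    all_clusters = set(outliers.z.columns)
    out: dict[str, set] = {}
    for region in outliers.z.index:
        close = set(outliers.close_flags.columns[outliers.close_flags.loc[region]])
        open_ = set(outliers.open_flags.columns[outliers.open_flags.loc[region]])
        if close:
            out[region] = all_clusters - close
        elif open_:
            out[region] = open_
        else:
            out[region] = set(all_clusters)
    return out


def metacell_accessibility(
    accessible: Mapping[str, set],
    metacell_clusters: pd.Series,
) -> pd.DataFrame:
    """Propagate cluster-level accessibility to metacells via their cluster."""
    regions = list(accessible)
    mat = np.zeros((len(regions), len(metacell_clusters)), dtype=bool)
    clusters = metacell_clusters.to_numpy()
    for i, region in enumerate(regions):
        acc = accessible[region]
        mat[i] = np.isin(clusters, list(acc))
    return pd.DataFrame(mat, index=regions, columns=metacell_clusters.index)


def _odds_ratio(table: np.ndarray) -> float:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane-Anscombe correction
    return (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])


def region_depletion_test(
    metacell_branch: pd.Series,
    metacell_access: pd.DataFrame,
    fdr: float = 0.01,
    or_threshold: float = 0.5,
) -> pd.DataFrame:
    """Chi-square test for regions depleting accessible metacells in a branch.

    Per (region, branch) the 2x2 table crosses branch membership with region
    accessibility; BH runs across regions within each branch.  A region is
    inaccessible in a branch iff FDR < ``fdr`` AND odds ratio < ``or_threshold``.
    """
    branches = sorted(metacell_branch.unique())
    if len(branches) < 2:
        raise ValidationError("need at least 2 branches")
    access = metacell_access.loc[:, metacell_branch.index].to_numpy(dtype=bool)
    rows = []
    for branch in branches:
        in_branch = (metacell_branch == branch).to_numpy()
        pvals, ors = [], []
        for i in range(access.shape[0]):
            acc = access[i]
            table = np.array(
                [
                    [(in_branch & acc).sum(), (in_branch & ~acc).sum()],
                    [(~in_branch & acc).sum(), (~in_branch & ~acc).sum()],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                pvals.append(1.0)
            else:
                pvals.append(
                    float(stats.chi2_contingency(table, correction=False)[1])
                )
            ors.append(_odds_ratio(table))
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for i, region in enumerate(metacell_access.index):
            rows.append(
                (
                    region, branch, pvals[i], adj[i], ors[i],
                    bool(adj[i] < fdr and ors[i] < or_threshold),
                )
            )
    return pd.DataFrame(
        rows, columns=["region_id", "branch", "pval", "fdr", "odds_ratio", "inaccessible"]
    )


def inaccessible_regions(depletion: pd.DataFrame) -> dict[str, set]:
    """branch -> set of region ids flagged inaccessible."""
    out: dict[str, set] = {b: set() for b in depletion["branch"].unique()}
    flagged = depletion.loc[depletion["inaccessible"]]
    for region, branch in flagged[["region_id", "branch"]].itertuples(index=False):
        out[branch].add(region)
    return out


def prune_grn_by_branch(
    grn: GRN,
    inaccessible: Mapping[str, set],
    data: PairedMatrix,
    branch_labels: pd.Series | None = None,
    tf_min_detect: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Branch GRNs: drop edges via branch-inaccessible regions, then weak TFs.

    A TF is kept in a branch only when its expression is detected (> 0) in at
    least ``tf_min_detect`` of that branch's observations.  Pruning only
    removes edges: every branch GRN is a subset of the global significant set.
    """
    if branch_labels is None:
        branch_labels = data.obs_meta["branch"]
    sig = grn.significant
    out: dict[str, pd.DataFrame] = {}
    for branch in inaccessible:
        obs = branch_labels.index[branch_labels == branch]
        edges = sig.loc[~sig["region_id"].isin(inaccessible[branch])].copy()
        if len(obs):
            detect = (data.expression.loc[:, obs] > 0).mean(axis=1)
            weak = set(detect.index[detect < tf_min_detect])
            edges = edges.loc[~edges["tf"].isin(weak)]
        out[branch] = edges.reset_index(drop=True)
    return out
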