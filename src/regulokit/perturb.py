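"""Pooled CRISPR screen analysis: guide assignment, perturbation probability,
knockout transcriptomic effects, and compositional enrichment.

Guide UMI counts are bimodal (ambient background vs real capture), so cells are
assigned by a two-component Gaussian mixture on ln counts.  Because a guide
does not guarantee a phenotype (escapers), each assignment is converted into a
perturbation probability by comparing the squared error of a regularized
multi-gene regression with and without the guide term:

    P(X_j = 1) = logistic((SSE_0 - SSE) / (2 sigma^2))

Composition changes are tested per guide and branch with a Cochran-Mantel-
Haenszel test stratified by organoid, filtered for cross-organoid and
cross-guide consistency, and summarized per target by the maximum log odds
ratio across branches.

Orientation note: unlike the genes-x-observations PairedMatrix, this module is
cell-centric — matrices are cells x guides / cells x genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError


@dataclass
class ScreenData:
    """Cell x guide assignments with guide -> target map and cell metadata."""

    X: pd.DataFrame                # cells x guides, binary
    guide_map: pd.Series           # guide -> target gene
    obs_meta: pd.DataFrame         # organoid, branch, cell_type, n_features
    Y: pd.DataFrame | None = None  # cells x genes, log-normalized

    def __post_init__(self) -> None:
        xv = self.X.to_numpy()
        if not np.isin(xv, (0, 1)).all():
            raise ValidationError("guide assignment matrix must be binary")
        unmapped = set(self.X.columns) - set(self.guide_map.index)
        if unmapped:
            raise ValidationError(f"guides without target: {sorted(unmapped)[:5]}")


@dataclass
class PerturbationProbabilities:
    """Cell x guide probabilities and their per-target maximum."""

    per_guide: pd.DataFrame
    per_target: pd.DataFrame


@dataclass
class CompositionResult:
    """Per-(guide, branch) CMH statistics, filters, and per-target LOR summary."""

    per_guide_branch: pd.DataFrame
    lor: pd.DataFrame              # target, branch, lor
    max_lor: pd.Series             # target -> max LOR across branches
    counts: pd.DataFrame           # target x branch cell counts N


def assign_guides(
    umi_counts: pd.DataFrame,
    seed: int = 0,
    fallback_ln_threshold: float = float(np.log(10.0)),
) -> pd.DataFrame:
    """Binarize guide UMI counts with a 2-component GMM on ln counts.

    Nonzero counts are pooled, ln-transformed and fit with a free-variance
    two-component mixture; entries with posterior >= 0.5 for the higher-mean
    component are assigned.  Zeros are never assigned.  With fewer than 10
    nonzero values (or a degenerate distribution) a fixed ln-count threshold
    is applied instead, with a warning.
    """
    from sklearn.mixture import GaussianMixture

    counts = umi_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative UMI counts")
    nz_mask = counts > 0
    vals = np.log(counts[nz_mask])
    assigned = np.zeros_like(counts, dtype=np.int8)
    if len(vals) == 0:
        raise ValidationError("no nonzero UMI counts")
    if len(vals) < 10 or np.ptp(vals) == 0:
        warnings.warn(
            "too few / degenerate nonzero counts for mixture fit; "
            f"falling back to ln-count threshold {fallback_ln_threshold:.3g}",
            stacklevel=2,
        )
        assigned[nz_mask] = (np.log(counts[nz_mask]) >= fallback_ln_threshold).astype(np.int8)
        return pd.DataFrame(assigned, index=umi_counts.index, columns=umi_counts.columns)
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(
        vals.reshape(-1, 1)
    )
    high = int(np.argmax(gmm.means_.ravel()))
    post = gmm.predict_proba(vals.reshape(-1, 1))[:, high]
    assigned[nz_mask] = (post >= 0.5).astype(np.int8)
    return pd.DataFrame(assigned, index=umi_counts.index, columns=umi_counts.columns)


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric columns standardized, categorical columns dummy-coded."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            sd = v.std()
            parts.append(((v - v.mean()) / sd if sd > 0 else v * 0.0)[:, None])
        else:
            parts.append(
                pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            )
    return np.column_stack(parts) if parts else np.empty((len(covariates), 0))


def perturbation_probability(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    covariates: pd.DataFrame,
    guide_map: pd.Series,
    n_var_features: int = 500,
    l1_ratio: float = 0.5,
    seed: int = 0,
    min_cells: int = 5,
) -> PerturbationProbabilities:
    """Perturbation probability per cell and guide from regression error deltas.

    An elastic-net regression of each of the ``n_var_features`` most variable
    genes on [covariates, guide assignments] is fit with the penalty strength
    chosen per gene by cross-validation; per carrier cell the fit is
    re-evaluated with the guide column zeroed and the squared-error difference
    (summed over the selected features) becomes a probability through the
    logistic transform, with sigma^2 the mean squared residual of the full
    fit.  Non-carriers get p = 0; guides with fewer than ``min_cells``
    carriers are reported as missing.  Target-level probabilities take the
    maximum over the target's guides.
    """
    from sklearn.linear_model import ElasticNetCV

    variances = Y.var(axis=0)
    feats = variances.sort_values(ascending=False).index[: min(n_var_features, Y.shape[1])]
    y = Y.loc[:, feats].to_numpy(dtype=float)
    xg = X.to_numpy(dtype=float)
    z = np.column_stack([_covariate_design(covariates), xg])
    n_guide_cols = xg.shape[1]

    coef = np.zeros((y.shape[1], z.shape[1]))  # features x predictors
    resid = np.empty_like(y)                   # cells x features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(y.shape[1]):
            cv = ElasticNetCV(
                l1_ratio=l1_ratio, alphas=20, cv=3, random_state=seed
            ).fit(z, y[:, j])
            coef[j] = cv.coef_
            resid[:, j] = y[:, j] - cv.predict(z)
    sigma2 = float((resid ** 2).mean())

    guide_beta = coef[:, -n_guide_cols:]       # features x guides
    p = np.zeros_like(xg)
    missing = []
    for j, guide in enumerate(X.columns):
        carriers = xg[:, j] == 1
        if carriers.sum() < min_cells:
            p[:, j] = np.nan
            missing.append(guide)
            continue
        beta_j = guide_beta[:, j]              # per-feature coefficient
        r = resid[carriers]                    # carrier residuals
        # zeroing the guide column shifts predictions by -beta_j
        delta = ((r + beta_j) ** 2 - r ** 2).sum(axis=1)
        p[carriers, j] = 1.0 / (1.0 + np.exp(-delta / (2.0 * sigma2)))
    per_guide = pd.DataFrame(p, index=Y.index, columns=X.columns)

    targets = sorted(guide_map.loc[list(X.columns)].unique())
    per_target = pd.DataFrame(0.0, index=Y.index, columns=targets)
    for target in targets:
        guides = [g for g in X.columns if guide_map[g] == target]
        block = per_guide[guides].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_target[target] = np.nanmax(block, axis=1)
    per_target = per_target.fillna(0.0)
    return PerturbationProbabilities(per_guide=per_guide, per_target=per_target)


def ko_transcriptomic_effects(
    Y: pd.DataFrame,
    p_target: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr: float = 1e-4,
) -> pd.DataFrame:
    """Per-gene linear model with all target probabilities; per-target F test.

    Covariates enter as in :func:`perturbation_probability` (numeric scaled,
    categorical dummy-coded).  Aliased columns are dropped deterministically.
    Returns one row per (gene, target) with coefficient, p-value, BH FDR and a
    DE flag at FDR < ``fdr``.
    """
    from .grn_infer import _drop_aliased

    cov = _covariate_design(covariates)
    pt = p_target.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(Y)), cov, pt])
    target_cols = np.arange(x.shape[1] - pt.shape[1], x.shape[1])
    kept, dropped = _drop_aliased(x)
    x = x[:, kept]
    col_of = {orig: new for new, orig in enumerate(kept)}

    y = Y.to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = len(Y) - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)

    rows = []
    for t_idx, target in enumerate(p_target.columns):
        orig = target_cols[t_idx]
        if orig not in col_of:
            for gene in Y.columns:
                rows.append((gene, target, np.nan, np.nan))
            continue
        j = col_of[orig]
        se = np.sqrt(np.clip(xtx_inv[j, j] * sigma2, 1e-300, None))
        tvals = coef[j] / se
        pv = 2 * stats.t.sf(np.abs(tvals), dof)
        for g_idx, gene in enumerate(Y.columns):
            rows.append((gene, target, coef[j, g_idx], pv[g_idx]))
    out = pd.DataFrame(rows, columns=["gene", "target", "coef", "pval"])
    ok = out["pval"].notna()
    out["fdr"] = np.nan
    if ok.any():
        _, adj, _, _ = multipletests(out.loc[ok, "pval"], method="fdr_bh")
        out.loc[ok, "fdr"] = adj
    out["de"] = out["fdr"] < fdr
    return out


def cmh_test(tables: np.ndarray) -> tuple[float, float]:
    """Classical Cochran-Mantel-Haenszel chi-square (1 df), no continuity correction.

    ``tables`` has shape (K, 2, 2).  Strata with margin total <= 1 contribute
    nothing; if all strata are empty the test is undefined and p = 1.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    if t.shape[1:] != (2, 2) or (t < 0).any():
        raise ValidationError("tables must be nonnegative with shape (K, 2, 2)")
    num = 0.0
    var = 0.0
    used = 0
    for k in range(t.shape[0]):
        a, b = t[k, 0]
        c, d = t[k, 1]
        n = a + b + c + d
        if n <= 1:
            continue
        used += 1
        e = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n ** 2 * (n - 1))
        num += a - e
        var += v
    if used == 0 or var == 0:
        return 0.0, 1.0
    statistic = num ** 2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def _lor_from_counts(n11: float, n10: float, n01: float, n00: float) -> float:
    vals = np.array([n11, n10, n01, n00], dtype=float)
    if (vals == 0).any():
        vals = vals + 0.5
    return float(np.log((vals[0] / vals[1]) / (vals[2] / vals[3])))


def composition_enrichment(
    X: pd.DataFrame,
    branch: pd.Series,
    organoid: pd.Series,
    guide_map: pd.Series,
    fdr_organoid: float = 0.05,
    fdr_partner: float = 0.01,
) -> CompositionResult:
    """Branch-composition enrichment of guides with consistency filtering.

    Per (guide, branch): a CMH test stratified by organoid plus per-organoid
    Fisher exact tests (each family BH-corrected).  Filter 1 keeps guides
    significant (organoid-level FDR < ``fdr_organoid``) in more than one
    organoid with a consistent direction; filter 2 additionally requires the
    same significant effect (CMH FDR < ``fdr_partner``, same direction) from
    at least one other guide of the same target.  Cells of surviving guides
    are pooled per target for the log-odds-ratio summary.
    """
    organoids = sorted(organoid.unique())
    if len(organoids) < 2:
        raise ValidationError("need >= 2 organoids for the consistency filter")
    branches = sorted(branch.unique())
    xv = X.to_numpy(dtype=bool)
    rows = []
    fisher_rows = []
    for j, guide in enumerate(X.columns):
        has = xv[:, j]
        for b in branches:
            in_b = (branch == b).to_numpy()
            strata = []
            for org in organoids:
                in_org = (organoid == org).to_numpy()
                strata.append(
                    [
                        [(has & in_b & in_org).sum(), (has & ~in_b & in_org).sum()],
                        [(~has & in_b & in_org).sum(), (~has & ~in_b & in_org).sum()],
                    ]
                )
            strata = np.asarray(strata, dtype=float)
            statistic, cmh_p = cmh_test(strata)
            pooled = strata.sum(axis=0)
            direction = np.sign(
                _lor_from_counts(pooled[0, 0], pooled[0, 1], pooled[1, 0], pooled[1, 1])
            )
            rows.append((guide, guide_map[guide], b, statistic, cmh_p, direction))
            for org_idx, org in enumerate(organoids):
                table = strata[org_idx]
                if table.sum() == 0:
                    f_p, f_dir = 1.0, 0.0
                else:
                    f_p = float(stats.fisher_exact(table)[1])
                    f_dir = np.sign(
                        _lor_from_counts(table[0, 0], table[0, 1], table[1, 0], table[1, 1])
                    )
                fisher_rows.append((guide, b, org, f_p, f_dir))

    per_gb = pd.DataFrame(
        rows, columns=["guide", "target", "branch", "cmh_stat", "cmh_p", "direction"]
    )
    _, adj, _, _ = multipletests(per_gb["cmh_p"], method="fdr_bh")
    per_gb["cmh_fdr"] = adj
    fisher = pd.DataFrame(
        fisher_rows, columns=["guide", "branch", "organoid", "fisher_p", "direction"]
    )
    _, fadj, _, _ = multipletests(fisher["fisher_p"], method="fdr_bh")
    fisher["fisher_fdr"] = fadj

    # filter 1: significant in > 1 organoid, consistent direction
    pass1 = []
    for (guide, b), grp in fisher.groupby(["guide", "branch"]):
        sig = grp.loc[grp["fisher_fdr"] < fdr_organoid]
        ok = len(sig) > 1 and sig["direction"].nunique() == 1 and (sig["direction"] != 0).all()
        pass1.append((guide, b, ok, len(sig)))
    p1 = pd.DataFrame(pass1, columns=["guide", "branch", "pass1", "n_sig_organoids"])
    per_gb = per_gb.merge(p1, on=["guide", "branch"], how="left")

    # filter 2: a partner guide of the same target with the same significant effect
    pass2 = np.zeros(len(per_gb), dtype=bool)
    for i, row in per_gb.iterrows():
        if not row["pass1"]:
            continue
        partners = per_gb.loc[
            (per_gb["target"] == row["target"])
            & (per_gb["guide"] != row["guide"])
            & (per_gb["branch"] == row["branch"])
            & (per_gb["cmh_fdr"] < fdr_partner)
            & (per_gb["direction"] == row["direction"])
        ]
        pass2[i] = len(partners) > 0
    per_gb["pass2"] = pass2

    surviving = set(per_gb.loc[per_gb["pass2"], "guide"])
    cell_target = pd.Series("", index=X.index, dtype=object)
    for guide in surviving:
        carriers = X.index[X[guide] == 1]
        cell_target.loc[carriers] = guide_map[guide]
    assigned = cell_target != ""
    counts = (
        pd.crosstab(cell_target[assigned], branch[assigned])
        .reindex(columns=branches, fill_value=0)
        if assigned.any()
        else pd.DataFrame(0, index=pd.Index([], dtype=object), columns=branches)
    )

    lor_rows = []
    total = counts.to_numpy().sum()
    for target in counts.index:
        in_t = counts.loc[target]
        for b in branches:
            n11 = in_t[b]
            n10 = in_t.sum() - n11
            n01 = counts[b].sum() - n11
            n00 = total - n11 - n10 - n01
            lor_rows.append((target, b, _lor_from_counts(n11, n10, n01, n00)))
    lor = pd.DataFrame(lor_rows, columns=["target", "branch", "lor"])
    max_lor = (
        lor.groupby("target")["lor"].max()
        if len(lor)
        else pd.Series(dtype=float)
    )
    return CompositionResult(
        per_guide_branch=per_gb, lor=lor, max_lor=max_lor, counts=counts
    )
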