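"""Regression-based GRN inference from TF-expression x binding-site-accessibility products.

For each target gene i the model is

    Y_i = sum_j beta_j * e_j * a_j + epsilon

where Y_i is the target's log-normalized expression, e_j the log-normalized
expression of TF j and a_j the accessibility probability of the candidate
region carrying TF j's binding site within the target's regulatory window.
The default back-end is ordinary least squares (a Gaussian GLM with identity
link); per-coefficient significance comes from the single-term F test, which
for OLS equals the two-sided t test on the coefficient.  P-values are pooled
across all targets before Benjamini-Hochberg correction, and edges at
FDR < 0.05 define each TF's positively / negatively regulated modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import PairedMatrix, ValidationError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["tf", "region_id", "target", "beta", "pval", "fdr"]

FitMethod = Literal["gaussian-glm", "ridge", "lasso", "elastic-net", "gradient-boosting"]


@dataclass
class FitResult:
    """Per-target fit: term table (tf, region_id, beta, pval), intercept, R^2."""

    status: str                      # "ok" | "no-model"
    terms: pd.DataFrame | None = None
    intercept: float = np.nan
    r_squared: float = np.nan
    dropped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TFModule:
    """A TF's signed target-gene and regulatory-region sets."""

    tf: str
    positive_targets: set[str]
    negative_targets: set[str]
    positive_regions: set[str]
    negative_regions: set[str]


@dataclass
class GRN:
    """All fitted edges plus the FDR threshold defining significance."""

    edges: pd.DataFrame              # EDGE_COLUMNS (+ per-target r_squared, n_terms)
    fdr_threshold: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.edges.loc[self.edges["fdr"] < self.fdr_threshold]


def build_design(
    target: str,
    pairs: pd.DataFrame,
    sites: pd.DataFrame,
    data: PairedMatrix,
    min_detect: float = 0.05,
) -> tuple[pd.DataFrame, list[tuple[str, str]]] | None:
    """One design column per distinct (tf, region) acting on ``target``.

    Column values are e_tf * a_region per observation.  Terms are dropped when
    the TF equals the target (self-loop), the TF is missing from the expression
    matrix, the region is missing from accessibility, or the TF is detected
    (expression > 0) in fewer than ``min_detect`` of observations.  Returns
    None when no term survives (the "no-model" outcome).
    """
    region_ids = pairs.loc[pairs["gene_id"] == target, "region_id"]
    sub = sites.loc[sites["region_id"].isin(set(region_ids)), ["tf", "region_id"]]
    sub = sub.drop_duplicates().sort_values(["tf", "region_id"], kind="mergesort")
    expr, access = data.expression, data.accessibility
    n_obs = data.n_obs
    cols, labels = [], []
    for tf, region in sub.itertuples(index=False):
        if tf == target or tf not in expr.index or region not in access.index:
            continue
        e = expr.loc[tf].to_numpy()
        if (e > 0).sum() < min_detect * n_obs:
            continue
        cols.append(e * access.loc[region].to_numpy())
        labels.append((tf, region))
    if not cols:
        return None
    design = pd.DataFrame(
        np.column_stack(cols),
        index=expr.columns,
        columns=[f"{tf}|{region}" for tf, region in labels],
    )
    return design, labels


def _drop_aliased(x: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, list[int]]:
    """Greedy rank filter: keep columns in order, dropping linearly dependent ones."""
    kept: list[int] = []
    basis: np.ndarray | None = None
    for j in range(x.shape[1]):
        col = x[:, j]
        if basis is None:
            resid = col
        else:
            coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
            resid = col - basis @ coef
        scale = np.linalg.norm(col) + 1e-300
        if np.linalg.norm(resid) / scale > tol:
            kept.append(j)
            basis = x[:, kept]
    dropped = [j for j in range(x.shape[1]) if j not in kept]
    return np.asarray(kept, dtype=int), dropped


def fit_target_model(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    term_labels: Sequence[tuple[str, str]] | None = None,
    method: FitMethod = "gaussian-glm",
    seed: int = 0,
) -> FitResult:
    """Fit one target's model and test each coefficient.

    The default Gaussian GLM solves least squares with an intercept; rank-
    deficient designs drop aliased columns (later duplicates in term order) and
    fit the reduced model.  Regularized back-ends report coefficients without
    p-values; gradient boosting reports feature importances as |beta|.
    """
    y = np.asarray(y, dtype=float)
    if design.shape[1] < 1:
        return FitResult(status="no-model")
    if term_labels is None:
        term_labels = [tuple(c.split("|", 1)) for c in design.columns]
    x = design.to_numpy(dtype=float)
    n = len(y)

    if method in ("ridge", "lasso", "elastic-net"):
        from sklearn.linear_model import ElasticNet, Lasso, Ridge

        model = {
            "ridge": Ridge(alpha=1.0),
            "lasso": Lasso(alpha=0.01, max_iter=5000),
            "elastic-net": ElasticNet(alpha=0.01, l1_ratio=0.5, max_iter=5000),
        }[method].fit(x, y)
        pred = model.predict(x)
        terms = pd.DataFrame(
            {
                "tf": [t for t, _ in term_labels],
                "region_id": [r for _, r in term_labels],
                "beta": model.coef_,
                "pval": np.nan,
            }
        )
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ((y - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
        return FitResult("ok", terms, float(model.intercept_), float(r2))

    if method == "gradient-boosting":
        from sklearn.ensemble import GradientBoostingRegressor

        model = GradientBoostingRegressor(random_state=seed).fit(x, y)
        terms = pd.DataFrame(
            {
                "tf": [t for t, _ in term_labels],
                "region_id": [r for _, r in term_labels],
                "beta": model.feature_importances_,
                "pval": np.nan,
            }
        )
        return FitResult("ok", terms, np.nan, float(model.score(x, y)))

    # default: ordinary least squares (Gaussian GLM, identity link)
    if n <= design.shape[1] + 1:
        return FitResult(status="no-model")
    kept, dropped_idx = _drop_aliased(np.column_stack([np.ones(n), x]))
    kept_x = [j - 1 for j in kept if j > 0]  # indices into design columns
    dropped = [term_labels[j - 1] for j in dropped_idx if j > 0]
    xk = x[:, kept_x]
    xd = np.column_stack([np.ones(n), xk])
    coef, _, _, _ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ coef
    dof = n - xd.shape[1]
    sigma2 = (resid @ resid) / dof if dof > 0 else np.nan
    # a numerically perfect fit has sigma2 ~ 0; the tiny floor keeps the t test
    # finite so exactly-null coefficients report p ~ 1 instead of 0/0
    sigma2 = max(sigma2, 1e-20)
    xtx_inv = np.linalg.pinv(xd.T @ xd)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    terms = pd.DataFrame(
        {
            "tf": [term_labels[j][0] for j in kept_x],
            "region_id": [term_labels[j][1] for j in kept_x],
            "beta": coef[1:],
            "pval": pvals[1:],
        }
    )
    return FitResult("ok", terms, float(coef[0]), float(r2), dropped)


def infer_grn(
    data: PairedMatrix,
    sites: pd.DataFrame,
    gene_pairs: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_detect: float = 0.05,
    method: FitMethod = "gaussian-glm",
    targets: Sequence[str] | None = None,
) -> tuple[GRN, list[TFModule]]:
    """Fit every target gene, pool all p-values through one BH correction.

    ``gene_pairs`` is the (gene_id, region_id) assignment, ``sites`` the
    binding-site table.  Edges with FDR below ``fdr_threshold`` are significant
    and define the per-TF modules, split by coefficient sign.  Targets without
    any surviving term are skipped and logged.
    """
    if targets is None:
        targets = [
            g for g in gene_pairs["gene_id"].unique() if g in data.expression.index
        ]
    rows = []
    for target in targets:
        built = build_design(target, gene_pairs, sites, data, min_detect)
        if built is None:
            logger.info("target %s: no surviving terms, skipped", target)
            continue
        design, labels = built
        fit = fit_target_model(data.expression.loc[target].to_numpy(), design, labels, method)
        if fit.status != "ok" or fit.terms is None:
            logger.info("target %s: no-model outcome, skipped", target)
            continue
        t = fit.terms.copy()
        t["target"] = target
        t["r_squared"] = fit.r_squared
        t["n_terms"] = len(fit.terms)
        rows.append(t)
    if not rows:
        edges = pd.DataFrame(columns=EDGE_COLUMNS + ["r_squared", "n_terms"])
        return GRN(edges, fdr_threshold), []
    edges = pd.concat(rows, ignore_index=True)
    if edges["pval"].notna().any():
        _, fdr, _, _ = multipletests(edges["pval"].fillna(1.0), method="fdr_bh")
        edges["fdr"] = fdr
    else:
        edges["fdr"] = np.nan
    edges = edges[["tf", "region_id", "target", "beta", "pval", "fdr", "r_squared", "n_terms"]]
    grn = GRN(edges, fdr_threshold)
    return grn, extract_modules(grn)


def extract_modules(grn: GRN) -> list[TFModule]:
    """Signed gene / regulatory modules from the significant edge set."""
    sig = grn.significant
    modules = []
    for tf, grp in sig.groupby("tf"):
        pos = grp.loc[grp["beta"] > 0]
        neg = grp.loc[grp["beta"] < 0]
        modules.append(
            TFModule(
                tf=tf,
                positive_targets=set(pos["target"]),
                negative_targets=set(neg["target"]),
                positive_regions=set(pos["region_id"]),
                negative_regions=set(neg["region_id"]),
            )
        )
    return modules


def tf_activity_in_branch(
    edges: pd.DataFrame,
    data: PairedMatrix,
    branch_obs: Sequence[str] | np.ndarray,
) -> pd.Series:
    """Mean active-edge coefficient x mean branch expression, per TF.

    ``edges`` is the (possibly branch-pruned) active edge table; TFs without
    active edges are absent from the output.
    """
    branch_obs = list(branch_obs)
    if not branch_obs:
        raise ValidationError("empty branch observation set")
    out = {}
    for tf, grp in edges.groupby("tf"):
        if tf not in data.expression.index:
            continue
        mean_beta = grp["beta"].mean()
        mean_expr = data.expression.loc[tf, branch_obs].mean()
        out[tf] = mean_beta * mean_expr
    return pd.Series(out, dtype=float).sort_index()
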