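"""Condition-contrast statistics, stage-specific peak selection, and the
gene-level binding score for coverage tracks.

Three test families: a per-gene Gaussian linear model with covariates and an
F test on the condition coefficient; a two-sided Wilcoxon rank-sum test; and a
binomial GLM (logit link) on binarized peak detections compared with its null
by a likelihood-ratio test.  All p-values are BH-corrected.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneAnnotation, ValidationError
from .grn_infer import _drop_aliased

DIFF_COLUMNS = ["feature", "effect", "pval", "fdr", "test"]


def _bh(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if ok.any():
        _, adj, _, _ = multipletests(p[ok], method="fdr_bh")
        out[ok] = adj
    return out


def de_linear(
    Y: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on covariates + condition; F test on condition.

    ``Y`` is genes x observations.  A condition aliased with the covariates is
    reported as NA for every gene; constant genes get p = 1.
    """
    cond = np.asarray(condition)
    groups = np.unique(cond)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 condition groups, got {len(groups)}")
    indicator = (cond == groups[1]).astype(float)
    n = Y.shape[1]
    parts = [np.ones(n)]
    if covariates is not None:
        for col in covariates.columns:
            v = covariates[col].to_numpy(dtype=float)
            parts.append(v)
    x_full = np.column_stack(parts + [indicator])
    kept, _ = _drop_aliased(x_full)
    aliased = (x_full.shape[1] - 1) not in kept
    if aliased:
        return pd.DataFrame(
            {
                "feature": Y.index,
                "effect": np.nan,
                "pval": np.nan,
                "fdr": np.nan,
                "test": "lm-anova",
            }
        )
    x = x_full[:, kept]
    j = len(kept) - 1
    y = Y.to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ coef
    dof = n - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(np.clip(xtx_inv[j, j] * sigma2, 1e-300, None))
    tvals = coef[j] / se
    pv = 2 * stats.t.sf(np.abs(tvals), dof)
    constant = y.std(axis=1) == 0
    pv[constant] = 1.0
    out = pd.DataFrame(
        {
            "feature": Y.index,
            "effect": coef[j],
            "pval": pv,
            "fdr": _bh(pv),
            "test": "lm-anova",
        }
    )
    out.loc[constant, "effect"] = 0.0
    return out


def de_wilcoxon(Y: pd.DataFrame, condition: pd.Series | np.ndarray) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene with a mean log-difference effect."""
    cond = np.asarray(condition)
    groups = np.unique(cond)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 condition groups, got {len(groups)}")
    a = Y.loc[:, cond == groups[1]].to_numpy()
    b = Y.loc[:, cond == groups[0]].to_numpy()
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    effect = a.mean(axis=1) - b.mean(axis=1)
    pv = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(
        {
            "feature": Y.index,
            "effect": effect,
            "pval": pv,
            "fdr": _bh(pv),
            "test": "wilcoxon",
        }
    )


def da_binomial_lrt(
    detections: pd.DataFrame,
    n_fragments: pd.Series | np.ndarray,
    condition: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Binomial GLM (logit) per peak: ~ n_fragments + condition vs ~ n_fragments.

    Likelihood-ratio test with 1 df.  Constant peaks (all zero / all one) get
    p = 1; fits that fail to converge (for example under perfect separation)
    are flagged in the ``converged`` column.
    """
    frag = np.asarray(n_fragments, dtype=float)
    frag = (frag - frag.mean()) / (frag.std() if frag.std() > 0 else 1.0)
    cond = np.asarray(condition)
    groups = np.unique(cond)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 condition groups, got {len(groups)}")
    indicator = (cond == groups[1]).astype(float)
    n = len(frag)
    x_null = np.column_stack([np.ones(n), frag])
    x_full = np.column_stack([x_null, indicator])
    rows = []
    for peak in detections.index:
        y = detections.loc[peak].to_numpy(dtype=float)
        if y.min() == y.max():
            rows.append((peak, 0.0, 1.0, True))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit(maxiter=50)
                null = sm.GLM(y, x_null, family=sm.families.Binomial()).fit(maxiter=50)
            lr = 2 * (full.llf - null.llf)
            pv = float(stats.chi2.sf(max(lr, 0.0), df=1))
            converged = bool(full.converged and null.converged)
            rows.append((peak, float(full.params[-1]), pv, converged))
        except Exception:
            rows.append((peak, np.nan, np.nan, False))
    out = pd.DataFrame(rows, columns=["feature", "effect", "pval", "converged"])
    out["fdr"] = _bh(out["pval"].to_numpy(dtype=float))
    out["test"] = "binom-lrt"
    return out[["feature", "effect", "pval", "fdr", "test", "converged"]]


def stage_specific_peaks(
    detection_pct: pd.DataFrame,
    stage_sizes: Mapping[str, int] | None = None,
    min_in_stage: float = 15.0,
    min_specificity: float = 1.5,
    top_n: int = 5000,
) -> dict[str, pd.Series]:
    """Top peaks per stage by detection specificity.

    Specificity is the in-stage detection percentage divided by the detection
    percentage over all other observations (size-weighted when ``stage_sizes``
    is given, unweighted mean otherwise).  Peaks need in-stage detection
    > ``min_in_stage`` percent and specificity > ``min_specificity``; the top
    ``top_n`` by specificity are returned (out-stage detection 0 ranks first).
    """
    pct = detection_pct.to_numpy(dtype=float)
    if (pct < 0).any() or (pct > 100).any():
        raise ValidationError("detection percentages must lie in [0, 100]")
    stages = list(detection_pct.columns)
    if stage_sizes is None:
        weights = {s: 1.0 for s in stages}
    else:
        weights = {s: float(stage_sizes[s]) for s in stages}
    out: dict[str, pd.Series] = {}
    for s_idx, stage in enumerate(stages):
        others = [i for i in range(len(stages)) if i != s_idx]
        w = np.array([weights[stages[i]] for i in others])
        out_pct = (pct[:, others] * w).sum(axis=1) / w.sum()
        with np.errstate(divide="ignore"):
            specificity = np.where(out_pct > 0, pct[:, s_idx] / out_pct, np.inf)
        keep = (pct[:, s_idx] > min_in_stage) & (specificity > min_specificity)
        ranked = pd.Series(specificity[keep], index=detection_pct.index[keep])
        out[stage] = ranked.sort_values(ascending=False, kind="mergesort").head(top_n)
    return out


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track into (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValidationError("bedGraph interval with start >= end")
    return df


def gene_binding_score(
    track: pd.DataFrame,
    genes: GeneAnnotation,
    promoter_ext: int = 2000,
    both_sides: bool = False,
) -> pd.Series:
    """Summed track intensity over gene body + promoter extension, per gene.

    The extension is upstream of the TSS (strand-aware); ``both_sides`` also
    extends downstream.  Each track interval contributes value x overlapping
    bases.  Genes on chromosomes absent from the track score 0 with a warning.
    """
    by_chrom = {c: g for c, g in track.groupby("chrom")}
    scores = {}
    missing = []
    for gene in genes.df.itertuples(index=False):
        if gene.strand == "+":
            start = max(0, gene.start - promoter_ext)
            end = gene.end + (promoter_ext if both_sides else 0)
        else:
            start = max(0, gene.start - (promoter_ext if both_sides else 0))
            end = gene.end + promoter_ext
        g = by_chrom.get(gene.chrom)
        if g is None:
            missing.append(gene.gene_id)
            scores[gene.gene_id] = 0.0
            continue
        ov = np.minimum(g["end"].to_numpy(), end) - np.maximum(g["start"].to_numpy(), start)
        ov = np.clip(ov, 0, None)
        scores[gene.gene_id] = float((ov * g["value"].to_numpy()).sum())
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) on chromosomes absent from the track: "
            f"{missing[:3]}",
            stacklevel=2,
        )
    return pd.Series(scores)
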