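"""Coarse-graining of raw cell-level matrices into pseudocells and clusters.

Pseudocells denoise single-cell sparsity: a random 30% of cells seed
territories built from each seed's nearest neighbours in PCA space; expression
is averaged arithmetically and accessibility becomes the mean of binarized
counts, i.e. a detection probability in [0, 1].  High-resolution Louvain
clustering of an LSI embedding then yields the accessibility clusters used by
the GRN model and the branch-specific pruning.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import PairedMatrix, ValidationError


@dataclass
class PseudocellMap:
    """Disjoint seed territories and their aggregated paired matrices."""

    territories: dict[str, list[str]]  # seed cell id -> member cell ids
    expression: pd.DataFrame           # genes x pseudocells (arithmetic mean)
    accessibility: pd.DataFrame        # peaks x pseudocells (mean binarized counts)


def _select_hvg(expr: pd.DataFrame, n_hvg: int) -> pd.DataFrame:
    variances = expr.var(axis=1)
    top = variances.sort_values(ascending=False).index[:n_hvg]
    return expr.loc[top]


def _zscale(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mean) / sd


def make_pseudocells(
    expr: pd.DataFrame,
    access_counts: pd.DataFrame,
    n_pcs: int = 20,
    seed_fraction: float = 0.3,
    k: int = 10,
    seed: int = 0,
    n_hvg: int = 2000,
) -> PseudocellMap:
    """Aggregate cells into seed-centred territories of k nearest neighbours.

    Seeds are a random ``seed_fraction`` of cells (count rounded half-up); each
    territory holds the seed plus its k nearest neighbours in the top ``n_pcs``
    PCs of z-scaled expression of the ``n_hvg`` most variable genes.  A cell
    falling into several territories is kept in one chosen uniformly at random.
    """
    cells = list(expr.columns)
    n = len(cells)
    if n < k + 1:
        raise ValidationError(f"need at least k+1={k + 1} cells, got {n}")
    rng = np.random.default_rng(seed)

    hvg = _select_hvg(expr, n_hvg)
    z = _zscale(hvg.to_numpy())
    n_comp = min(n_pcs, n - 1, z.shape[0])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z.T)

    n_seeds = int(np.floor(seed_fraction * n + 0.5))
    n_seeds = max(1, n_seeds)
    seed_idx = rng.choice(n, size=n_seeds, replace=False)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, neigh = nn.kneighbors(pcs[seed_idx])

    # raw territories: the seed plus its k nearest neighbours
    claims: dict[int, list[int]] = {}
    for s_row, s in enumerate(seed_idx):
        members = [m for m in neigh[s_row] if m != s][:k]
        for cell in [s, *members]:
            claims.setdefault(cell, []).append(s)
    # resolve multi-territory cells uniformly at random
    assignment: dict[int, int] = {}
    for cell in sorted(claims):
        owners = claims[cell]
        assignment[cell] = owners[rng.integers(len(owners))] if len(owners) > 1 else owners[0]

    territories: dict[str, list[str]] = {str(cells[s]): [] for s in seed_idx}
    for cell, owner in assignment.items():
        territories[str(cells[owner])].append(str(cells[cell]))

    access_bin = (access_counts.to_numpy() > 0).astype(float)
    expr_np = expr.to_numpy()
    col_index = {c: i for i, c in enumerate(map(str, cells))}
    e_cols, a_cols, names = [], [], []
    for seed_cell, members in territories.items():
        if not members:
            continue
        idx = [col_index[m] for m in members]
        e_cols.append(expr_np[:, idx].mean(axis=1))
        a_cols.append(access_bin[:, idx].mean(axis=1))
        names.append(seed_cell)
    return PseudocellMap(
        territories={s: m for s, m in territories.items() if m},
        expression=pd.DataFrame(np.column_stack(e_cols), index=expr.index, columns=names),
        accessibility=pd.DataFrame(np.column_stack(a_cols), index=access_counts.index, columns=names),
    )


def lsi(access_counts: pd.DataFrame, n_components: int = 20) -> pd.DataFrame:
    """tf-idf transform followed by truncated SVD; obs x components embedding.

    Term frequency is the per-observation count fraction; idf = log(1 + N/df)
    with df the number of observations detecting the peak.  Component 1 is
    retained (no depth-component dropping).  Signs are fixed so the largest-
    magnitude loading of each component is positive.
    """
    x = access_counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative counts in LSI input")
    if not x.any():
        raise ValidationError("all-zero matrix in LSI")
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    tf = x / totals
    df_count = (x > 0).sum(axis=1)
    idf = np.zeros(x.shape[0])
    nz = df_count > 0
    idf[nz] = np.log(1.0 + x.shape[1] / df_count[nz])
    tfidf = (tf * idf[:, None]).T  # obs x peaks

    u, s, _ = np.linalg.svd(tfidf, full_matrices=False)
    n_comp = min(n_components, len(s))
    emb = u[:, :n_comp] * s[:n_comp]
    # deterministic sign: largest |value| per component made positive
    for j in range(emb.shape[1]):
        i = np.argmax(np.abs(emb[:, j]))
        if emb[i, j] < 0:
            emb[:, j] = -emb[:, j]
    return pd.DataFrame(
        emb, index=access_counts.columns, columns=[f"LSI_{i + 1}" for i in range(n_comp)]
    )


def knn_graph(embedding: np.ndarray, k: int = 20) -> igraph.Graph:
    """Undirected kNN graph (Euclidean) as an igraph Graph."""
    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, neigh = nn.kneighbors(embedding)
    edges = {tuple(sorted((i, int(j)))) for i in range(n) for j in neigh[i] if int(j) != i}
    g = igraph.Graph(n)
    g.add_edges(sorted(edges))
    return g


def cluster_high_resolution(
    embedding: pd.DataFrame | np.ndarray,
    resolution: float = 100,
    seed: int = 0,
    k: int = 20,
) -> np.ndarray:
    """Louvain modularity clustering of a kNN graph at the given resolution.

    Labels are 0-based and contiguous; a fixed seed gives identical labels.
    """
    emb = embedding.to_numpy() if isinstance(embedding, pd.DataFrame) else np.asarray(embedding)
    if emb.shape[0] < 2:
        raise ValidationError("need at least 2 observations to cluster")
    g = knn_graph(emb, k=k)
    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = g.community_multilevel(resolution=resolution)
    finally:
        _random.setstate(state)
    labels = np.asarray(clustering.membership)
    _, contiguous = np.unique(labels, return_inverse=True)
    return contiguous


def summarize_access_by_cluster(
    access: pd.DataFrame, labels: np.ndarray | list
) -> pd.DataFrame:
    """Mean accessibility probability per (peak, cluster)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("empty cluster label set")
    if labels.size != access.shape[1]:
        raise ValidationError(
            f"{labels.size} labels for {access.shape[1]} observations"
        )
    out = {}
    for lab in np.unique(labels):
        out[lab] = access.loc[:, labels == lab].mean(axis=1)
    return pd.DataFrame(out)


def broadcast_cluster_access(
    access_by_cluster: pd.DataFrame, labels: np.ndarray, columns: pd.Index
) -> pd.DataFrame:
    """Represent every observation by its cluster's accessibility vector."""
    mat = access_by_cluster.loc[:, list(np.asarray(labels))].to_numpy()
    return pd.DataFrame(mat, index=access_by_cluster.index, columns=columns)


def coarse_grain(
    expr: pd.DataFrame,
    access_counts: pd.DataFrame,
    n_pcs: int = 20,
    seed_fraction: float = 0.3,
    k: int = 10,
    resolution: float = 100,
    seed: int = 0,
    obs_meta: pd.DataFrame | None = None,
) -> tuple[PairedMatrix, np.ndarray]:
    """Full coarse-graining: pseudocells, LSI, Louvain, cluster-level accessibility.

    Returns a pseudocell-level PairedMatrix whose accessibility is the
    cluster-mean probability broadcast to member pseudocells, plus the cluster
    labels themselves.
    """
    pmap = make_pseudocells(
        expr, access_counts, n_pcs=n_pcs, seed_fraction=seed_fraction, k=k, seed=seed
    )
    emb = lsi(pmap.accessibility, n_components=n_pcs)
    labels = cluster_high_resolution(emb, resolution=resolution, seed=seed)
    by_cluster = summarize_access_by_cluster(pmap.accessibility, labels)
    access = broadcast_cluster_access(by_cluster, labels, pmap.accessibility.columns)
    if obs_meta is None:
        obs_meta = pd.DataFrame(index=pmap.expression.columns)
    else:
        obs_meta = obs_meta.loc[pmap.expression.columns]
    data = PairedMatrix(pmap.expression, access, obs_meta)
    return data, labels
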