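"""TF-TF network construction, embedding, centrality and sign-propagation checks.

The TF-by-TF combined score couples co-expression with inferred interaction
strength, s_ij = r_ij * sqrt(|beta_ij|) + 1, where r is the Pearson correlation
of log-normalized TF expression and beta_ij the mean significant coefficient of
TF j acting on TF i.  The matrix is embedded with PCA + UMAP; PageRank ranks
TFs on the directed regulatory graph; and shortest-path sign products predict
the direction of knockout differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_io import ValidationError
from .grn_infer import GRN


@dataclass
class TFScoreMatrix:
    """Combined score s plus its components r (correlation) and beta."""

    s: pd.DataFrame
    r: pd.DataFrame
    beta: pd.DataFrame


def combined_score(r: float, beta: float) -> float:
    """s = r * sqrt(|beta|) + 1; requires r in [-1, 1]."""
    if abs(r) > 1 + 1e-12:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    return r * np.sqrt(abs(beta)) + 1.0


def tf_score_matrix(grn: GRN, expression: pd.DataFrame) -> TFScoreMatrix:
    """Build the TF-by-TF combined-score matrix from a GRN and expression.

    beta_ij aggregates significant coefficients of TF j on TF i by their mean
    over all linking regions (0 when none exist).
    """
    sig = grn.significant
    tfs = sorted(set(sig["tf"]) & set(expression.index))
    if not tfs:
        raise ValidationError("no TFs with significant edges and expression")
    r = expression.loc[tfs].T.corr(method="pearson").fillna(0.0)
    beta = pd.DataFrame(0.0, index=tfs, columns=tfs)
    tf_tf = sig.loc[sig["target"].isin(tfs) & sig["tf"].isin(tfs)]
    agg = tf_tf.groupby(["target", "tf"])["beta"].mean()
    for (target, tf), b in agg.items():
        beta.loc[target, tf] = b
    s = r * np.sqrt(beta.abs()) + 1.0
    return TFScoreMatrix(s=s, r=r, beta=beta)


def embed_tf_network(
    score: TFScoreMatrix | pd.DataFrame, n_pcs: int = 20, seed: int = 0
) -> pd.DataFrame:
    """PCA on the combined-score rows followed by a 2-D UMAP embedding."""
    from sklearn.decomposition import PCA
    from umap import UMAP

    s = score.s if isinstance(score, TFScoreMatrix) else score
    if len(s) < 3:
        raise ValidationError("need at least 3 TFs to embed")
    x = s.to_numpy(dtype=float)
    if np.allclose(x, x.flat[0]):
        raise ValidationError("constant score matrix cannot be embedded")
    n_comp = min(n_pcs, x.shape[0] - 1, x.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    # embed unique rows only, so duplicated TFs land on identical coordinates
    uniq, inverse = np.unique(np.round(pcs, 12), axis=0, return_inverse=True)
    n_neighbors = min(15, len(uniq) - 1)
    init = "spectral" if len(uniq) >= 10 else "random"  # spectral needs n > k
    coords_u = UMAP(
        n_components=2, n_neighbors=max(n_neighbors, 2), random_state=seed, init=init
    ).fit_transform(uniq)
    coords = coords_u[inverse]
    return pd.DataFrame(coords, index=s.index, columns=["UMAP_1", "UMAP_2"])


def signed_tf_graph(edges: pd.DataFrame) -> nx.DiGraph:
    """Directed graph tf -> target with edge sign = sign of the mean coefficient."""
    g = nx.DiGraph()
    agg = edges.groupby(["tf", "target"])["beta"].mean()
    for (tf, target), beta in agg.items():
        if beta != 0:
            g.add_edge(tf, target, sign=1 if beta > 0 else -1, beta=beta)
    return g


def pagerank_centrality(grn: GRN, damping: float = 0.85) -> pd.Series:
    """PageRank on the TF -> target graph restricted to TF nodes; sums to 1."""
    sig = grn.significant
    if sig.empty:
        raise ValidationError("empty edge set")
    tfs = set(sig["tf"])
    g = nx.DiGraph()
    g.add_nodes_from(sorted(tfs))
    for tf, target in sig[["tf", "target"]].drop_duplicates().itertuples(index=False):
        if target in tfs and tf != target:
            g.add_edge(tf, target)
    scores = nx.pagerank(g, alpha=damping, tol=1e-12, max_iter=1000)
    return pd.Series(scores).sort_index()


@dataclass
class PathPrediction:
    """Per-gene sign predictions plus accuracy and neighbourhood enrichment."""

    per_gene: pd.DataFrame       # gene, predicted_ko_direction, observed, status
    accuracy: float
    unreachable: list[str]
    fisher_first_p: float
    fisher_second_p: float


def predict_direction_by_paths(
    grn: GRN | pd.DataFrame,
    source_tf: str,
    de_table: pd.DataFrame,
) -> PathPrediction:
    """Predict knockout DE directions by shortest-path sign products.

    For each DE gene reachable from ``source_tf`` all unweighted shortest paths
    are enumerated; a path's direction is the product of its edge signs and the
    predicted effect of the source is the mode over paths (ties are labelled
    ambiguous and excluded from accuracy).  Since removing the source inverts
    its net effect, the predicted knockout direction is the negative of that
    mode; accuracy is the fraction of non-ambiguous genes whose observed DE
    direction matches it.  Fisher tests compare DE membership against first-
    and second-order out-neighbourhoods of the source.
    """
    edges = grn.significant if isinstance(grn, GRN) else grn
    g = signed_tf_graph(edges)
    if source_tf not in g:
        raise ValidationError(f"source TF {source_tf!r} not in GRN graph")

    de = dict(zip(de_table["gene"].astype(str), de_table["direction"].astype(int)))
    rows, unreachable = [], []
    n_correct = n_scored = 0
    for gene, observed in de.items():
        if gene == source_tf:
            continue
        if gene not in g or not nx.has_path(g, source_tf, gene):
            unreachable.append(gene)
            continue
        products = []
        for path in nx.all_shortest_paths(g, source_tf, gene):
            sign = 1
            for u, v in zip(path[:-1], path[1:]):
                sign *= g[u][v]["sign"]
            products.append(sign)
        total = sum(products)
        if total == 0:
            rows.append((gene, 0, observed, "ambiguous"))
            continue
        effect = 1 if total > 0 else -1
        predicted_ko = -effect
        correct = predicted_ko == observed
        rows.append((gene, predicted_ko, observed, "correct" if correct else "incorrect"))
        n_scored += 1
        n_correct += int(correct)

    per_gene = pd.DataFrame(
        rows, columns=["gene", "predicted_ko_direction", "observed", "status"]
    )
    accuracy = n_correct / n_scored if n_scored else np.nan

    universe = set(g.nodes) - {source_tf}
    first = set(g.successors(source_tf))
    second = {w for v in first for w in g.successors(v)} - first - {source_tf}
    de_genes = set(de) & universe

    def _fisher(neigh: set[str]) -> float:
        a = len(de_genes & neigh)
        b = len(neigh - de_genes)
        c = len(de_genes - neigh)
        d = len(universe - neigh - de_genes)
        return float(fisher_exact([[a, b], [c, d]])[1])

    return PathPrediction(
        per_gene=per_gene,
        accuracy=accuracy,
        unreachable=unreachable,
        fisher_first_p=_fisher(first),
        fisher_second_p=_fisher(second),
    )
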