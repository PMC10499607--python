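"""Coarse fate graph from cluster-level transition scores and random-walk
branch assignment.

Absorption probabilities into terminal fates (supplied by an external
fate-mapping tool) are rank-normalized into transition scores; high-resolution
clusters become nodes of a directed graph whose edges run forward in
pseudotime between well-connected nearest neighbours in transition-score
space.  Branch identities propagate by uniform random walks backwards from
each terminal tip: a node visited overwhelmingly (> ratio x) from one tip
takes that tip's identity, nodes shared between tips take a merged identity,
and unreachable nodes inherit from their best-connected neighbour.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .core_io import ValidationError

UNASSIGNED = "unassigned"


def transition_scores(absorption_probs: pd.DataFrame) -> pd.DataFrame:
    """Rank each probability column (average ranks for ties) and divide by n.

    Values lie in (0, 1] and are invariant under strictly monotone transforms
    of each column.
    """
    p = absorption_probs.to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("absorption probabilities must lie in [0, 1]")
    ranks = np.column_stack(
        [rankdata(p[:, j], method="average") for j in range(p.shape[1])]
    )
    return pd.DataFrame(
        ranks / p.shape[0],
        index=absorption_probs.index,
        columns=absorption_probs.columns,
    )


def build_fate_graph(
    cluster_scores: pd.DataFrame,
    pseudotime: pd.Series,
    connectivities: pd.DataFrame,
    k: int = 30,
    conn_threshold: float = 0.2,
) -> nx.DiGraph:
    """Directed fate graph over clusters.

    Edges come from the kNN graph in transition-score space (Euclidean),
    pruned to pairs with connectivity > ``conn_threshold`` and oriented
    strictly forward in pseudotime (ties dropped).  Node attributes carry the
    pseudotime and score vector; edge attributes the connectivity.
    """
    conn = connectivities.to_numpy(dtype=float)
    if conn.shape[0] != conn.shape[1]:
        raise ValidationError("connectivity matrix must be square")
    if not np.allclose(conn, conn.T, atol=1e-8):
        raise ValidationError("connectivity matrix must be symmetric")
    if (conn < 0).any():
        raise ValidationError("connectivities must be nonnegative")
    nodes = list(cluster_scores.index)
    x = cluster_scores.to_numpy(dtype=float)
    n = len(nodes)
    g = nx.DiGraph()
    for i, node in enumerate(nodes):
        g.add_node(
            node,
            pseudotime=float(pseudotime.loc[node]),
            scores=x[i].copy(),
        )
    if n < 2:
        return g
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(x)
    _, neigh = nn.kneighbors(x)
    pt = pseudotime.loc[nodes].to_numpy(dtype=float)
    for i in range(n):
        for j in neigh[i]:
            j = int(j)
            if j == i or conn[i, j] <= conn_threshold:
                continue
            if pt[i] < pt[j]:
                g.add_edge(nodes[i], nodes[j], connectivity=float(conn[i, j]))
            elif pt[j] < pt[i]:
                g.add_edge(nodes[j], nodes[i], connectivity=float(conn[i, j]))
            # equal pseudotimes: edge dropped
    return g


def auto_tips(graph: nx.DiGraph, terminal_states: Sequence[str]) -> dict[str, object]:
    """One tip per terminal state: the node maximizing rank(score) * rank(pseudotime)."""
    nodes = list(graph.nodes)
    pt = np.array([graph.nodes[n]["pseudotime"] for n in nodes])
    pt_rank = rankdata(pt, method="average")
    tips = {}
    for s_idx, state in enumerate(terminal_states):
        scores = np.array([graph.nodes[n]["scores"][s_idx] for n in nodes])
        score_rank = rankdata(scores, method="average")
        tips[state] = nodes[int(np.argmax(score_rank * pt_rank))]
    return tips


def _walk_visits(
    graph: nx.DiGraph,
    start: object,
    n_walks: int,
    walk_len: int,
    rng: np.random.Generator,
) -> dict[object, int]:
    """Visit counts over uniform random walks along reversed edges."""
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    preds = [list(graph.predecessors(n)) for n in nodes]
    max_deg = max((len(p) for p in preds), default=0)
    deg = np.array([len(p) for p in preds])
    nbr = np.zeros((len(nodes), max(max_deg, 1)), dtype=np.int64)
    for i, p in enumerate(preds):
        for j, q in enumerate(p):
            nbr[i, j] = index[q]

    visits = np.zeros(len(nodes), dtype=np.int64)
    cur = np.full(n_walks, index[start], dtype=np.int64)
    alive = np.ones(n_walks, dtype=bool)
    np.add.at(visits, cur, 1)
    for _ in range(walk_len):
        d = deg[cur]
        alive &= d > 0
        if not alive.any():
            break
        choice = (rng.random(n_walks) * np.maximum(d, 1)).astype(np.int64)
        nxt = nbr[cur, choice]
        cur = np.where(alive, nxt, cur)
        np.add.at(visits, cur[alive], 1)
    return {nodes[i]: int(visits[i]) for i in range(len(nodes)) if visits[i] > 0}


def assign_branches(
    graph: nx.DiGraph,
    terminal_states: Sequence[str],
    tips: Mapping[str, object] | None = None,
    n_walks: int = 10_000,
    walk_len: int = 200,
    ratio: float = 100.0,
    seed: int = 0,
    merge_map: Mapping[frozenset, str] | None = None,
) -> pd.Series:
    """Node -> branch identity by backward random walks from each tip.

    Visitation frequencies per (node, tip) decide identity: a single tip more
    than ``ratio`` x above the next highest wins outright; tips within
    ``ratio`` x of the maximum share the node, producing a merged identity
    (renamed through ``merge_map``, else the sorted tip names joined by "+").
    Unreached nodes inherit the label of their highest-connectivity labelled
    neighbour; isolated unreached nodes stay "unassigned".
    """
    if tips is None:
        tips = auto_tips(graph, terminal_states)
    rng = np.random.default_rng(seed)
    freq: dict[str, dict[object, int]] = {}
    for state in terminal_states:
        freq[state] = _walk_visits(graph, tips[state], n_walks, walk_len, rng)

    labels: dict[object, str] = {}
    for node in graph.nodes:
        counts = {s: freq[s].get(node, 0) for s in terminal_states}
        top = max(counts.values())
        if top == 0:
            continue
        # single winner iff the top tip exceeds ratio x the next highest;
        # otherwise every tip within ratio x of the maximum shares the node
        winners = [s for s, c in counts.items() if c * ratio >= top]
        if len(winners) == 1:
            labels[node] = winners[0]
        else:
            key = frozenset(winners)
            if merge_map and key in merge_map:
                labels[node] = merge_map[key]
            else:
                labels[node] = "+".join(sorted(winners))

    # unreached nodes inherit from the labelled neighbour with the strongest edge
    und = graph.to_undirected(as_view=False)
    changed = True
    while changed:
        changed = False
        for node in graph.nodes:
            if node in labels:
                continue
            best, best_conn = None, -np.inf
            for nb in und.neighbors(node):
                if nb in labels:
                    c = und[node][nb].get("connectivity", 0.0)
                    if c > best_conn:
                        best, best_conn = nb, c
            if best is not None:
                labels[node] = labels[best]
                changed = True
    out = pd.Series(
        {n: labels.get(n, UNASSIGNED) for n in graph.nodes}, dtype=object
    )
    return out
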