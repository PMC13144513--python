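"""Protein co-regulation network from pairwise ridge regressions.

Every ordered protein pair (predictor -> target) gets a univariate ridge
coefficient on standardized log2 intensities, the fit's R^2, a p value from
the correlation t-test, and a BH q value across all ordered pairs.  Edges are
retained where either direction passes q < 5% and |coefficient| >= 0.15, the
graph is clustered with the Louvain heuristic, and proteins are ranked by
their mean R^2 predicting the rest of the network; an elbow on the cumulative
multi-predictor R^2 curve sizes the pivotal set.

With variables standardized by the population sd, the univariate ridge
coefficient is n*r/(n + lambda), so lambda = 0 recovers the Pearson
correlation exactly — the analytically checkable OLS limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

from ._stats import bh_adjust
from .containers import ProteinMatrix

__all__ = [
    "PairwiseStats",
    "NetworkModel",
    "pairwise_ridge",
    "build_network",
    "cluster_louvain",
    "rank_pivotal",
    "incremental_r2",
    "elbow_select",
    "build_full_network",
]


@dataclass
class PairwiseStats:
    """Ordered pairwise ridge statistics over a protein set.

    Square DataFrames indexed by protein (rows = predictor, columns = target):
    ``coefficient``, ``r2``, ``p``, ``q``; diagonals are NaN.
    """

    coefficient: pd.DataFrame
    r2: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_samples: int
    penalty: float
    excluded: list[str] = field(default_factory=list)


@dataclass
class NetworkModel:
    graph: nx.Graph
    clusters: dict[str, int] = field(default_factory=dict)
    modularity: float = float("nan")
    pivotal_ranking: pd.Series | None = None  # protein -> mean R^2, descending
    cumulative_r2: pd.Series | None = None  # k -> mean R^2
    elbow_k: int | None = None


def _standardized(matrix: ProteinMatrix, proteins) -> tuple[np.ndarray, list[str], list[str]]:
    data = matrix.data[list(proteins)]
    if data.isna().any().any():
        raise ValueError("pairwise ridge requires a fully observed matrix")
    vals = data.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=0)
    tiny = 1e-12 * (1.0 + np.abs(vals.mean(axis=0)))  # constant up to rounding
    excluded = [p for p, s, t in zip(data.columns, sd, tiny) if s <= t]
    keep = [p for p in data.columns if p not in excluded]
    vals = data[keep].to_numpy(dtype=float)
    Z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    return Z, keep, excluded


def pairwise_ridge(
    matrix: ProteinMatrix, proteins=None, penalty: float = 1.0
) -> PairwiseStats:
    """Univariate ridge statistics for every ordered protein pair.

    Coefficient = n*r/(n + penalty) on population-standardized variables;
    R^2 = 1 - mean squared residual of that fit; p from the exact Pearson
    correlation t-test; q by BH across all ordered off-diagonal pairs.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    proteins = list(proteins) if proteins is not None else list(matrix.protein_ids)
    Z, keep, excluded = _standardized(matrix, proteins)
    n = Z.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 samples, got {n}")
    r = (Z.T @ Z) / n
    np.fill_diagonal(r, 1.0)
    coef = n * r / (n + penalty)
    # residual of predicting standardized y from c*x: mean sq = 1 - 2cr + c^2
    r2 = np.clip(2 * coef * r - coef**2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    off = ~np.eye(len(keep), dtype=bool)
    q = np.full_like(p, np.nan)
    q[off] = bh_adjust(p[off])
    for m in (coef, r2, p):
        np.fill_diagonal(m, np.nan)

    def df(a):
        return pd.DataFrame(a, index=keep, columns=keep)

    return PairwiseStats(df(coef), df(r2), df(p), df(q), n, penalty, excluded)


def build_network(
    stats_: PairwiseStats, q_threshold: float = 0.05, coef_threshold: float = 0.15
) -> NetworkModel:
    """Threshold pairwise statistics into an undirected graph.

    An edge joins A and B iff either ordered direction has q < ``q_threshold``
    (strict) and |coefficient| >= ``coef_threshold`` (inclusive); the edge
    carries the passing direction's statistics (larger |coefficient| wins when
    both directions pass).
    """
    proteins = list(stats_.coefficient.index)
    G = nx.Graph()
    G.add_nodes_from(proteins)
    coef = stats_.coefficient.to_numpy()
    q = stats_.q.to_numpy()
    r2 = stats_.r2.to_numpy()
    p = stats_.p.to_numpy()
    n = len(proteins)
    for i in range(n):
        for j in range(i + 1, n):
            candidates = []
            for a, b in ((i, j), (j, i)):
                if q[a, b] < q_threshold and abs(coef[a, b]) >= coef_threshold:
                    candidates.append((abs(coef[a, b]), a, b))
            if candidates:
                _, a, b = max(candidates)
                G.add_edge(
                    proteins[i],
                    proteins[j],
                    coefficient=float(coef[a, b]),
                    p=float(p[a, b]),
                    q=float(q[a, b]),
                    r2=float(r2[a, b]),
                )
    return NetworkModel(graph=G)


def cluster_louvain(
    model: NetworkModel, resolution: float = 1.0, seed: int = 0
) -> NetworkModel:
    """Louvain modularity clustering of the (unweighted) network, seeded."""
    G = model.graph
    if G.number_of_edges() == 0:
        model.clusters = {node: i for i, node in enumerate(G.nodes)}
        model.modularity = float("nan")
        return model
    parts = nx_community.louvain_communities(
        G, weight=None, resolution=resolution, seed=seed
    )
    model.clusters = {node: i for i, part in enumerate(parts) for node in part}
    model.modularity = float(
        nx_community.modularity(G, parts, weight=None, resolution=resolution)
    )
    return model


def rank_pivotal(
    matrix: ProteinMatrix, nodes, penalty: float = 1.0
) -> pd.Series:
    """Rank proteins by mean univariate-ridge R^2 predicting all other nodes.

    Descending score; ties broken by protein id.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("pivotal ranking needs >= 2 nodes")
    stats_ = pairwise_ridge(matrix, nodes, penalty)
    score = stats_.r2.mean(axis=1, skipna=True)
    order = sorted(score.index, key=lambda prot: (-score[prot], prot))
    return score.loc[order]


def incremental_r2(
    matrix: ProteinMatrix, ranked: list[str], penalty: float = 1.0, max_k: int | None = None
) -> pd.Series:
    """Cumulative mean R^2 of top-k ridge panels predicting the network.

    For each k, a multi-predictor ridge of the top-k ranked proteins is fit
    against every network protein (the target is dropped from its own
    predictor set), and the curve records the mean R^2 across targets.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked list is empty")
    K = len(ranked) if max_k is None else max_k
    if K > len(ranked):
        raise ValueError("max_k exceeds the ranked list length")
    Z, keep, _ = _standardized(matrix, ranked)
    if set(keep) != set(ranked):
        raise ValueError("zero-variance protein in the ranked list")
    col = {prot: i for i, prot in enumerate(ranked)}
    n = Z.shape[0]
    curve = {}
    for k in range(1, K + 1):
        top = ranked[:k]
        r2s = []
        for target in ranked:
            preds = [col[prot] for prot in top if prot != target]
            if not preds:
                continue
            X = Z[:, preds]
            y = Z[:, col[target]]
            b = np.linalg.solve(X.T @ X + penalty * np.eye(len(preds)), X.T @ y)
            resid = y - X @ b
            r2s.append(1.0 - (resid @ resid) / n)
        curve[k] = float(np.mean(r2s))
    return pd.Series(curve, name="mean_r2")


def elbow_select(curve: pd.Series) -> int:
    """Kneedle elbow: k maximizing perpendicular distance to the chord.

    The chord is anchored at the origin (zero proteins explain zero variance)
    and the curve's endpoint, so a curve that jumps once and then stagnates
    elbows at the jump.  A curve proportional to k lies on the chord (all
    distances tie at zero) and ties break to the smallest k.
    """
    ks = curve.index.to_numpy(dtype=float)
    ys = curve.to_numpy(dtype=float)
    if len(ks) == 1:
        return int(ks[0])
    dx, dy = ks[-1], ys[-1]  # chord (0, 0) -> (K, y_K)
    norm = np.hypot(dx, dy)
    if norm == 0:
        return int(ks[0])
    dist = np.abs(dy * ks - dx * ys) / norm
    best = int(np.argmax(np.round(dist, 12)))  # argmax takes the first (smallest k) tie
    return int(ks[best])


def build_full_network(
    matrix: ProteinMatrix,
    proteins=None,
    penalty: float = 1.0,
    q_threshold: float = 0.05,
    coef_threshold: float = 0.15,
    resolution: float = 1.0,
    seed: int = 0,
    max_k: int | None = None,
) -> NetworkModel:
    """End-to-end network stage: ridge stats, edges, Louvain, pivotal elbow."""
    stats_ = pairwise_ridge(matrix, proteins, penalty)
    model = build_network(stats_, q_threshold, coef_threshold)
    model = cluster_louvain(model, resolution, seed)
    connected = [n_ for n_ in model.graph.nodes if model.graph.degree[n_] > 0]
    if len(connected) >= 2:
        model.pivotal_ranking = rank_pivotal(matrix, connected, penalty)
        ranked = list(model.pivotal_ranking.index)
        model.cumulative_r2 = incremental_r2(matrix, ranked, penalty, max_k)
        model.elbow_k = elbow_select(model.cumulative_r2)
    return model
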