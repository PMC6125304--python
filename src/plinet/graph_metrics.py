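"""Minimum spanning tree topology and weighted-graph metrics.

From each PLI matrix a minimum spanning tree (MST) is built with Kruskal's
algorithm on link weights 1 - PLI, i.e. the acyclic sub-network of N - 1
links with maximal total connectivity — the connectivity "backbone". Its
topology is summarized by nine metrics: maximal degree, leaf fraction,
diameter, mean eccentricity, maximal betweenness centrality (BC), tree
hierarchy T_h = L / (2 m BC_max), degree correlation R, degree divergence
kappa = <k^2>/<k>, and the mean PLI over tree links.

The printed scale of the first five metrics follows the MST literature's
normalizations (degree, leaf, diameter, eccentricity divided by the link
count m = N - 1; BC already normalized to [0, 1] by node pairs); the raw
unnormalized values are always carried alongside so any alternative
convention can be recovered.

The full weighted graph additionally yields characteristic path length Lw
(edge length 1/PLI), the Stam-style weighted clustering coefficient Cw,
and Newman's modularity Q.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ConnectivityMatrix


@dataclass
class Tree:
    """A spanning tree as an edge list with PLI weights."""

    n_nodes: int
    edges: list[tuple[int, int, float]]   # (i, j, pli), i < j
    degree_sequence: np.ndarray = field(init=False)

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree has exactly N - 1 edges")
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        self.degree_sequence = deg
        g = self.graph
        if not nx.is_tree(g) or g.number_of_nodes() != self.n_nodes:
            raise ValueError("edge list is not a spanning tree")

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges, weight="pli")
        return g


@dataclass
class MSTMetrics:
    """The nine MST metrics; normalized (printed) scale plus raw values."""

    n_nodes: int
    m: int
    degree: float              # k_max / m
    leaf: float                # L / m
    diameter: float            # d / m
    eccentricity: float        # mean nodal eccentricity / m
    bc: float                  # max pair-normalized betweenness, in [0, 1]
    tree_hierarchy: float      # L / (2 m BC_max); NaN when BC_max = 0
    degree_correlation: float  # Pearson r of endpoint degrees; NaN for N = 2
    kappa: float               # <k^2> / <k>
    mst_mean: float            # mean PLI over tree links
    degree_raw: int = 0
    leaf_raw: int = 0
    diameter_raw: int = 0
    eccentricity_raw: float = 0.0


@dataclass
class WeightedMetrics:
    path_length: float
    clustering: float
    modularity: float
    partition: list[set[int]]


def _check_matrix(mat) -> np.ndarray:
    v = mat.values if isinstance(mat, ConnectivityMatrix) else np.asarray(
        mat, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.all(np.isfinite(v)):
        raise ValueError("connectivity matrix must be finite")
    if not np.allclose(v, v.T):
        raise ValueError("connectivity matrix must be symmetric")
    return v


def mst_kruskal(mat) -> Tree:
    """Minimum spanning tree of 1 - PLI via Kruskal's algorithm.

    Minimizing total 1 - PLI maximizes total PLI, so the tree keeps the
    strongest links. Weight ties are broken by lexicographic (i, j) edge
    order (stable sort over edges inserted in that order), making the
    result deterministic.
    """
    v = _check_matrix(mat)
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=1.0 - v[i, j], pli=v[i, j])
    t = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    edges = sorted((min(i, j), max(i, j), d["pli"])
                   for i, j, d in t.edges(data=True))
    return Tree(n_nodes=n, edges=edges)


def tree_metrics(tree: Tree) -> MSTMetrics:
    """All nine MST metrics of one tree.

    Distances are counted in links. BC is normalized per node by the
    (N-1)(N-2)/2 pairs excluding it; in a tree every path is unique. For
    N = 2 both the degree correlation (zero degree variance) and the tree
    hierarchy (BC_max = 0) are undefined and reported as NaN rather than
    fabricated.
    """
    g = tree.graph
    n, m = tree.n_nodes, tree.n_nodes - 1
    deg = tree.degree_sequence

    ecc = nx.eccentricity(g)
    d_raw = max(ecc.values())
    ecc_mean = float(np.mean(list(ecc.values())))
    leaf_raw = int(np.sum(deg == 1))
    k_max = int(deg.max())

    bc = nx.betweenness_centrality(g, normalized=True)
    bc_max = float(max(bc.values()))

    if bc_max > 0:
        t_h = leaf_raw / (2.0 * m * bc_max)
    else:
        t_h = np.nan

    if np.ptp(deg) == 0:
        r = np.nan   # constant degrees: correlation undefined (N = 2 case)
    else:
        x = np.array([[deg[i], deg[j]] for i, j, _ in tree.edges])
        both = np.vstack([x, x[:, ::-1]])   # each edge in both orientations
        r = float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])

    kappa = float(np.mean(deg ** 2) / np.mean(deg))
    weights = [w for _, _, w in tree.edges]

    return MSTMetrics(
        n_nodes=n, m=m,
        degree=k_max / m, leaf=leaf_raw / m, diameter=d_raw / m,
        eccentricity=ecc_mean / m, bc=bc_max, tree_hierarchy=t_h,
        degree_correlation=r, kappa=kappa,
        mst_mean=float(np.mean(weights)),
        degree_raw=k_max, leaf_raw=leaf_raw, diameter_raw=d_raw,
        eccentricity_raw=ecc_mean)


def mst_mean(tree: Tree) -> float:
    """Mean PLI (not 1 - PLI) over the tree's links."""
    return float(np.mean([w for _, _, w in tree.edges]))


def weighted_path_length(mat) -> float:
    """Characteristic path length with edge length 1/PLI.

    Mean over all node pairs of the lowest-sum-of-lengths path. Zero-PLI
    edges are treated as absent; if that disconnects the graph the
    harmonic-mean convention is used (infinite distances drop out) and a
    warning is issued.
    """
    v = _check_matrix(mat)
    n = v.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(v > 0, 1.0 / np.where(v > 0, v, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    if np.any(np.isinf(pair_d)):
        warnings.warn("graph disconnected: harmonic-mean path length used")
        with np.errstate(divide="ignore"):
            return float(1.0 / np.mean(1.0 / pair_d))
    return float(pair_d.mean())


def weighted_clustering(mat) -> float:
    """Weighted clustering coefficient, triple-product form.

    C_i = sum_{k != l} w_ik w_il w_kl / sum_{k != l} w_ik w_il, averaged
    over nodes; nodes with no (or one) neighbor contribute 0. On a complete
    graph with constant weight w this reduces to w.
    """
    v = _check_matrix(mat)
    if np.any(v < 0):
        raise ValueError("weights must be nonnegative")
    w = v.copy()
    np.fill_diagonal(w, 0.0)
    num = np.diag(w @ w @ w)                          # sum_kl w_ik w_kl w_li
    s1 = w.sum(axis=1)
    den = s1 ** 2 - (w ** 2).sum(axis=1)              # sum_{k != l} w_ik w_il
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / den, 0.0)
    return float(c.mean())


def _modularity_value(w: np.ndarray, labels: np.ndarray) -> float:
    k = w.sum(axis=1)
    two_m = k.sum()
    b = (w - np.outer(k, k) / two_m) / two_m
    return float(b[labels[:, None] == labels[None, :]].sum())


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def grow(i, maxlab):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from grow(i + 1, max(maxlab, lab))

    yield from grow(1, 0)


def modularity(mat, method: str = "auto") -> WeightedMetrics | tuple:
    """Partition maximizing weighted Newman modularity Q (resolution 1).

    ``method="exhaustive"`` searches every partition (feasible for up to
    ~10 nodes); ``"greedy"`` uses deterministic greedy agglomeration
    (Clauset-Newman-Moore); ``"auto"`` picks exhaustive for N <= 10.
    Returns (Q, partition) where partition is a list of node sets.
    """
    v = _check_matrix(mat)
    if np.any(v < 0):
        raise ValueError("weights must be nonnegative")
    w = v.copy()
    np.fill_diagonal(w, 0.0)
    if w.sum() == 0:
        raise ValueError("modularity undefined for an all-zero matrix")
    n = w.shape[0]
    if method == "auto":
        method = "exhaustive" if n <= 10 else "greedy"
    if method == "exhaustive":
        best_q, best = -np.inf, None
        for labels in _partitions(n):
            q = _modularity_value(w, labels)
            if q > best_q:
                best_q, best = q, labels
        parts = [set(np.flatnonzero(best == lab))
                 for lab in np.unique(best)]
        return best_q, parts
    if method == "greedy":
        g = nx.from_numpy_array(w)
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
        parts = [set(c) for c in comms]
        q = nx.community.modularity(g, parts, weight="weight")
        return float(q), parts
    raise ValueError(f"unknown method {method!r}")


_MST_FIELDS = ("degree", "leaf", "diameter", "eccentricity", "bc",
               "tree_hierarchy", "degree_correlation", "kappa", "mst_mean")


def subject_metrics(epoch_mats: list, weighted: bool = True,
                    modularity_method: str = "greedy") -> dict:
    """Per-subject metric row: metrics per epoch, averaged across epochs.

    Returns a dict with the nine MST metrics, the global mean PLI, and
    (optionally) the weighted metrics Lw, Cw and Q. NaN-valued metrics
    (degenerate trees) are averaged over the epochs where they exist.
    """
    if not epoch_mats:
        raise ValueError("need at least one epoch matrix")
    rows = []
    for mat in epoch_mats:
        v = _check_matrix(mat)
        tm = tree_metrics(mst_kruskal(v))
        row = {f: getattr(tm, f) for f in _MST_FIELDS}
        iu = np.triu_indices(v.shape[0], k=1)
        row["mean_pli"] = float(v[iu].mean())
        if weighted:
            row["path_length_w"] = weighted_path_length(v)
            row["clustering_w"] = weighted_clustering(v)
            row["modularity_q"] = modularity(v, method=modularity_method)[0]
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.mean(skipna=True).to_dict()


class MSTFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stacks of per-epoch PLI matrices -> per-subject network features.

    ``X`` is a sequence with one entry per subject, each an array of shape
    (n_epochs, n_channels, n_channels); the transform returns a DataFrame
    with one row per subject holding the epoch-averaged MST (and
    optionally weighted) metrics. Composes with
    :class:`plinet.connectivity.PLIConnectivity` in an sklearn pipeline.
    """

    def __init__(self, weighted=True, modularity_method="greedy"):
        self.weighted = weighted
        self.modularity_method = modularity_method

    def fit(self, X, y=None):
        self.feature_names_ = list(_MST_FIELDS) + ["mean_pli"] + (
            ["path_length_w", "clustering_w", "modularity_q"]
            if self.weighted else [])
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [subject_metrics(list(stack), weighted=self.weighted,
                                modularity_method=self.modularity_method)
                for stack in X]
        return pd.DataFrame(rows)
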