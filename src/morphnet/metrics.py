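"""Weighted graph-theory measures for one subject's network.

Conventions follow the common connectivity-toolbox definitions:
edge length is the reciprocal of edge weight, efficiency is the mean
inverse shortest-path length, local efficiency uses cube-root weighting
on the neighborhood subgraph, betweenness counts each unordered node
pair once with fractional credit for ties, and modularity is the best
weighted Newman Q over several seeded community-detection rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import ConnMatrix, WeightMatrix, to_weights


def _as_weight_array(w: WeightMatrix | np.ndarray) -> np.ndarray:
    arr = w.w if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    if np.any(arr < 0):
        raise ValueError("weights must be nonnegative (use a weight transform first)")
    return arr


def shortest_path_lengths(w: WeightMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1/weight.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    arr = _as_weight_array(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(arr > 0, 1.0 / arr, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def global_efficiency(w: WeightMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    d = shortest_path_lengths(w)
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(w: WeightMatrix | np.ndarray) -> np.ndarray:
    """Nodal weighted local efficiency (cube-root convention).

    For node u with neighbor set V (|V| = k >= 2):

        E_loc(u) = sum_{j != h in V} (w_uj * w_uh)^(1/3) / d_jh
                   / (k * (k - 1))

    where d_jh is the shortest path length between j and h on the
    subgraph induced by V with edge lengths (1/w)^(1/3). Nodes with
    fewer than two neighbors score 0.
    """
    arr = _as_weight_array(w)
    n = arr.shape[0]
    out = np.zeros(n)
    with np.errstate(divide="ignore"):
        lengths = np.where(arr > 0, 1.0 / arr, 0.0) ** (1.0 / 3.0)
    for u in range(n):
        nbrs = np.flatnonzero(arr[u] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        d = dijkstra(csr_matrix(sub), directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        cw = np.cbrt(arr[u, nbrs])
        out[u] = float(np.outer(cw, cw).ravel() @ inv.ravel()) / (k * (k - 1))
    return out


def _weight_graph(arr: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(arr.shape[0]))
    ii, jj = np.nonzero(np.triu(arr, 1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(arr[i, j])) for i, j in zip(ii, jj)
    )
    return g


def betweenness(w: WeightMatrix | np.ndarray) -> np.ndarray:
    """Weighted betweenness: shortest-path (length 1/w) throughput per node.

    Each unordered pair is counted once, endpoints excluded, and tied
    shortest paths share credit fractionally (Brandes accumulation).
    """
    arr = _as_weight_array(w)
    g = _weight_graph(arr)
    for _, _, data in g.edges(data=True):
        data["length"] = 1.0 / data["weight"]
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(arr.shape[0])])


def normalize_bc(bc: np.ndarray) -> np.ndarray:
    """Divide by the mean across regions so mean(nBC) = 1."""
    bc = np.asarray(bc, dtype=float)
    m = bc.mean()
    if m <= 0:
        raise ValueError("mean betweenness is zero; nBC undefined")
    return bc / m


def identify_subject_hubs(n_bc: np.ndarray) -> np.ndarray:
    """Boolean hub mask: nBC strictly above mean + sample SD."""
    n_bc = np.asarray(n_bc, dtype=float)
    thresh = n_bc.mean() + n_bc.std(ddof=1)
    return n_bc > thresh


def modularity(
    w: WeightMatrix | np.ndarray, rounds: int = 100, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Best weighted Newman modularity over seeded detection rounds.

    Runs Louvain-style optimization ``rounds`` times with distinct
    seeds and returns the highest Q with its community labels.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    arr = _as_weight_array(w)
    n = arr.shape[0]
    g = _weight_graph(arr)
    if g.number_of_edges() == 0:
        return 0.0, np.arange(n)
    round_seeds = np.random.SeedSequence(seed).generate_state(rounds)
    best_q, best_labels = -np.inf, None
    for rs in round_seeds:
        communities = nx.community.louvain_communities(g, weight="weight", seed=int(rs))
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            best_q = q
            best_labels = np.empty(n, dtype=int)
            for label, members in enumerate(communities):
                best_labels[list(members)] = label
    return float(best_q), best_labels


def partition_modularity(w: WeightMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman Q of a given partition (for oracles and reports)."""
    arr = _as_weight_array(w)
    total = arr.sum()  # 2m for an undirected graph stored symmetrically
    if total == 0:
        return 0.0
    strength = arr.sum(axis=1)
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += arr[np.ix_(idx, idx)].sum() / total - (strength[idx].sum() / total) ** 2
    return float(q)


@dataclass(frozen=True)
class SubjectMetrics:
    """All graph measures for one subject."""

    subject: str
    e_global: float
    e_local: np.ndarray
    m_e_local: float
    q: float
    partition: np.ndarray
    bc: np.ndarray
    m_bc: float
    n_bc: np.ndarray | None
    hubs: frozenset[str]
    provenance: dict = field(default_factory=dict)


def compute_all_metrics(
    conn: ConnMatrix,
    transform: str = "abs",
    rounds: int = 100,
    seed: int = 0,
) -> SubjectMetrics:
    """Full per-subject metric set from a signed correlation matrix."""
    w = to_weights(conn, transform)
    e_glob = global_efficiency(w)
    e_loc = local_efficiency(w)
    bc = betweenness(w)
    q, labels = modularity(w, rounds=rounds, seed=seed)
    if bc.mean() > 0:
        n_bc = normalize_bc(bc)
        hub_mask = identify_subject_hubs(n_bc)
    else:
        warnings.warn(
            f"subject {conn.subject!r}: all betweenness values are zero; "
            "hub screening skipped"
        )
        n_bc = None
        hub_mask = np.zeros(len(bc), dtype=bool)
    hubs = frozenset(str(a) for a in np.asarray(conn.atlas.abbrevs)[hub_mask])
    return SubjectMetrics(
        subject=conn.subject,
        e_global=e_glob,
        e_local=e_loc,
        m_e_local=float(e_loc.mean()),
        q=q,
        partition=labels,
        bc=bc,
        m_bc=float(bc.mean()),
        n_bc=n_bc,
        hubs=hubs,
        provenance={"transform": transform, "rounds": rounds, "seed": seed},
    )
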