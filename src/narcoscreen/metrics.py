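"""Node centralities, community structure and network-level summaries.

Conventions (all on undirected networks):

* degree = number of incident edges; weighted degree = sum of incident
  edge weights (for a hospital in the two-mode network: number of
  distinct patients, and number of prescriptions, respectively);
* betweenness is unnormalized shortest-path betweenness over *unweighted*
  (hop-count) paths — prescription counts are connection strengths, not
  distances;
* eigenvector centrality is the dominant eigenvector of the weighted
  adjacency matrix, computed per connected component by power iteration
  and rescaled globally so the maximum over all nodes is exactly 1;
  isolated nodes score 0;
* community detection is seeded Louvain at a configurable resolution;
  modularity Q is evaluated by the weighted formula
  ``Q = sum_c [W_c/m - (d_c/(2m))^2]`` with ``m`` the total edge weight,
  ``W_c`` the intra-community edge weight and ``d_c`` the community's
  weighted-degree sum;
* diameter and average path length use hop-count distances over
  *connected node pairs only* (the screening networks are highly
  fragmented, so all-pairs statistics would be infinite); the fraction
  of connected pairs is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .records import ConvergenceError, ValidationError
from .network import HOSPITAL


# --------------------------------------------------------------------------
# Centralities
# --------------------------------------------------------------------------

def degree_and_weighted_degree(G: nx.Graph) -> pd.DataFrame:
    """Per-node degree and weighted degree, indexed by node id (sorted)."""
    nodes = sorted(G.nodes)
    return pd.DataFrame(
        {
            "degree": [G.degree(n) for n in nodes],
            "weighted_degree": [
                float(G.degree(n, weight="weight")) for n in nodes
            ],
        },
        index=pd.Index(nodes, name="node_id"),
    )


def betweenness(G: nx.Graph) -> dict[Hashable, float]:
    """Unnormalized hop-count betweenness (undirected pair convention)."""
    return nx.betweenness_centrality(G, normalized=False, weight=None)


def eigenvector(
    G: nx.Graph, tol: float = 1e-8, max_iter: int = 1000,
    fallback: str | None = "lanczos",
) -> dict[Hashable, float]:
    """Eigenvector centrality by per-component shifted power iteration.

    Plain power iteration oscillates on bipartite components (their
    spectra are symmetric, +/- lambda), so each component is handled in
    two stages: a short burst of iterations with the squared adjacency
    ``A^2`` yields the dominant eigenvalue estimate ``lam`` (the
    Rayleigh quotient of ``A^2`` is ``lam^2`` even while the iterate
    still mixes the +/- pair), then the shifted operator ``A + lam*I``
    — which annihilates the ``-lam`` branch — is power-iterated, applied
    twice per sweep to square the contraction per convergence check.
    Convergence is declared when the successive L-infinity change falls
    below ``tol/100``, two orders stricter than the advertised accuracy.
    Each component's vector has unit L2 norm before the final global
    rescaling that makes the maximum over all nodes exactly 1; isolated
    nodes get 0.

    Screening networks can contain components whose two leading
    eigenvalues nearly coincide (two almost identical heavy hospital
    stars sharing one patient); no power scheme converges there within
    any reasonable budget, so such components are finished by a Lanczos
    solve (``fallback="lanczos"``, the default, deterministic start
    vector).  Pass ``fallback=None`` to get the explicit convergence
    error instead.

    Raises
    ------
    ConvergenceError
        If some component has not converged after ``max_iter`` sweeps
        and no fallback is enabled (the error names a node of that
        component).
    ValidationError
        If the network has no edge.
    """
    if G.number_of_edges() == 0:
        raise ValidationError("eigenvector centrality requires >= 1 edge")
    values: dict[Hashable, float] = {n: 0.0 for n in G.nodes}
    stop = tol / 100.0
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            continue
        nodes = sorted(comp)
        A = nx.to_scipy_sparse_array(G, nodelist=nodes, weight="weight",
                                     format="csr", dtype=float)
        x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
        for _ in range(50):  # eigenvalue estimate via A^2
            y = A @ (A @ x)
            x = y / np.linalg.norm(y)
        lam = float(np.sqrt(x @ (A @ (A @ x))))
        for _ in range(max_iter):
            y = A @ x + lam * x
            y = A @ y + lam * y
            y /= np.linalg.norm(y)
            if np.max(np.abs(y - x)) < stop:
                x = y
                break
            x = y
        else:
            if fallback != "lanczos":
                raise ConvergenceError(
                    f"power iteration did not converge after {max_iter} "
                    f"iterations in the component containing {nodes[0]!r}"
                )
            x = _lanczos_perron(A, tol)
        for n, v in zip(nodes, x):
            values[n] = float(v)
    peak = max(values.values())
    return {n: v / peak for n, v in values.items()}


def _lanczos_perron(A, tol: float) -> np.ndarray:
    """Dominant eigenvector of a symmetric nonnegative matrix, for
    components where the leading eigenvalues nearly coincide."""
    n = A.shape[0]
    if n < 6:
        w, v = np.linalg.eigh(A.toarray())
        x = v[:, -1]
    else:
        from scipy.sparse.linalg import eigsh

        w, v = eigsh(A, k=1, which="LA", v0=np.ones(n), tol=tol / 100.0)
        x = v[:, 0]
    if x.sum() < 0:
        x = -x
    x = np.maximum(x, 0.0)  # Perron vector is nonnegative; clip noise
    return x / np.linalg.norm(x)


# --------------------------------------------------------------------------
# Communities and modularity
# --------------------------------------------------------------------------

def modularity(G: nx.Graph, partition: Mapping[Hashable, int]) -> float:
    """Weighted modularity Q of a node partition.

    ``Q = sum_c [W_c/m - (d_c/(2m))^2]`` where ``m`` is the total edge
    weight, ``W_c`` the weight of edges inside community ``c`` and
    ``d_c`` the sum of weighted degrees of its nodes.
    """
    m = sum(d.get("weight", 1) for _, _, d in G.edges(data=True))
    if m == 0:
        raise ValidationError("modularity undefined on an edgeless network")
    intra: dict[int, float] = {}
    degsum: dict[int, float] = {}
    for u, v, data in G.edges(data=True):
        w = data.get("weight", 1)
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    for n in G.nodes:
        c = partition[n]
        degsum[c] = degsum.get(c, 0.0) + G.degree(n, weight="weight")
    communities = set(partition[n] for n in G.nodes)
    return sum(
        intra.get(c, 0.0) / m - (degsum.get(c, 0.0) / (2 * m)) ** 2
        for c in communities
    )


@dataclass
class LouvainResult:
    """A Louvain partition with its community count and modularity Q."""

    partition: dict[Hashable, int]
    n_communities: int
    modularity: float


def communities_louvain(
    G: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> LouvainResult:
    """Seeded Louvain communities; Q evaluated at resolution 1.

    Community ids are integers, numbered by each community's smallest
    node for determinism.

    Raises
    ------
    ValidationError
        On an empty network.
    """
    if G.number_of_nodes() == 0:
        raise ValidationError("cannot detect communities in an empty network")
    comms = louvain_communities(G, weight="weight", resolution=resolution,
                                seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: str(c[0]))
    partition = {n: i for i, members in enumerate(comms) for n in members}
    q = modularity(G, partition) if G.number_of_edges() else 0.0
    return LouvainResult(partition=partition, n_communities=len(comms),
                         modularity=q)


# --------------------------------------------------------------------------
# Path statistics
# --------------------------------------------------------------------------

@dataclass
class PathStatistics:
    """Hop-count path statistics over connected node pairs."""

    diameter: int
    average_path_length: float
    connected_pair_fraction: float


def path_statistics(G: nx.Graph) -> PathStatistics:
    """Diameter and average path length over connected pairs (BFS).

    Raises
    ------
    ValidationError
        If no pair of nodes is connected (edgeless network).
    """
    n = G.number_of_nodes()
    total = 0
    n_pairs = 0
    diameter = 0
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            continue
        for source in comp:
            lengths = nx.single_source_shortest_path_length(G, source)
            for d in lengths.values():
                total += d
                diameter = max(diameter, d)
            n_pairs += len(lengths) - 1  # excludes the source itself
    # each pair was counted in both directions above
    n_pairs //= 2
    total //= 2
    if n_pairs == 0:
        raise ValidationError("no connected node pair; path statistics undefined")
    all_pairs = n * (n - 1) // 2
    return PathStatistics(
        diameter=diameter,
        average_path_length=total / n_pairs,
        connected_pair_fraction=n_pairs / all_pairs,
    )


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    """The standard network-level report of one analysis run."""

    n_nodes: int
    n_edges: int
    average_degree: float
    average_weighted_degree: float
    diameter: int
    modularity: float
    n_communities: int
    average_path_length: float
    connected_pair_fraction: float


def summarize_network(
    G: nx.Graph,
    louvain: LouvainResult | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> NetworkSummary:
    """Assemble the network-level summary (computing Louvain if needed)."""
    if louvain is None:
        louvain = communities_louvain(G, resolution=resolution, seed=seed)
    dw = degree_and_weighted_degree(G)
    paths = path_statistics(G)
    return NetworkSummary(
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        average_degree=float(dw["degree"].mean()),
        average_weighted_degree=float(dw["weighted_degree"].mean()),
        diameter=paths.diameter,
        modularity=louvain.modularity,
        n_communities=louvain.n_communities,
        average_path_length=paths.average_path_length,
        connected_pair_fraction=paths.connected_pair_fraction,
    )


def centrality_table(
    G: nx.Graph, resolution: float = 1.0, seed: int = 0,
    louvain: LouvainResult | None = None,
) -> pd.DataFrame:
    """Full per-node metric table: degree, weighted degree, betweenness,
    eigenvector, community id, node category."""
    df = degree_and_weighted_degree(G)
    bet = betweenness(G)
    eig = (eigenvector(G) if G.number_of_edges()
           else {n: 0.0 for n in G.nodes})
    if louvain is None:
        louvain = communities_louvain(G, resolution=resolution, seed=seed)
    df["betweenness"] = [bet[n] for n in df.index]
    df["eigenvector"] = [eig[n] for n in df.index]
    df["community_id"] = [louvain.partition[n] for n in df.index]
    df.insert(0, "category",
              [G.nodes[n].get("category", "") for n in df.index])
    return df


def hospital_table(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a centrality table to hospital nodes (screening input)."""
    return table[table["category"] == HOSPITAL].copy()
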