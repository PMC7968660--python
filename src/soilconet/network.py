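"""Co-occurrence network construction and topology.

A similarity matrix of pairwise Spearman correlations between taxon
abundance profiles is thresholded at |rho| > St (default 0.6) to give an
undirected signed graph.  Edge sign records the correlation direction;
community detection and all topology metrics run on the unsigned skeleton.
Isolated taxa (no supra-threshold correlation) are not part of the network,
which is why node counts vary between treatments drawn from a shared pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric Spearman correlation matrix over taxa; diagonal exactly 1."""

    taxon_ids: list[str]
    rho: np.ndarray


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph; every edge has |rho| > st."""

    graph: nx.Graph
    st: float


@dataclass
class NetworkReport:
    total_nodes: int
    total_links: int
    pct_negative_links: float
    pct_positive_links: float
    avg_connectivity: float
    avg_path_distance: float
    avg_clustering_coefficient: float
    modularity: float
    module_partition: dict = field(default_factory=dict)


def _as_matrix(table) -> tuple[list[str], np.ndarray]:
    if isinstance(table, CountTable):
        return table.taxon_ids, table.counts.astype(float)
    if isinstance(table, pd.DataFrame):
        return list(table.index), table.to_numpy(dtype=float)
    arr = np.asarray(table, dtype=float)
    return [f"t{i}" for i in range(arr.shape[0])], arr


def spearman_matrix(table) -> SimilarityMatrix:
    """Pairwise Spearman's rho between taxon rows.

    Computed as the Pearson correlation of mid-ranks (ties get average
    ranks).  Rows with zero variance have undefined rank correlation and are
    assigned rho = 0 against every other taxon (logged); the diagonal is
    forced to exactly 1.  Requires at least 3 samples.
    """
    ids, x = _as_matrix(table)
    if x.shape[1] < 3:
        raise ValueError(f"Spearman correlation needs >= 3 samples, got {x.shape[1]}")
    ranks = stats.rankdata(x, axis=1)
    constant = ranks.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "constant abundance rows set to rho=0: %s",
            [ids[i] for i in np.flatnonzero(constant)],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SimilarityMatrix(taxon_ids=ids, rho=rho)


def build_network(
    sim: SimilarityMatrix,
    st: float = 0.6,
    node_attrs: dict[str, dict] | None = None,
) -> CoNetwork:
    """Threshold a similarity matrix into a signed graph.

    An edge joins taxa i != j iff |rho[i, j]| > st (strictly); its sign is
    the sign of rho.  Taxa left without any edge are excluded.
    ``node_attrs`` optionally maps taxon id → attribute dict (e.g. phylum,
    mean abundance) copied onto the nodes.
    """
    if not 0 < st < 1:
        raise ValueError(f"St must lie in (0, 1), got {st}")
    rho = sim.rho
    n = len(sim.taxon_ids)
    mask = np.abs(rho) > st
    np.fill_diagonal(mask, False)
    keep = mask.any(axis=1)

    g = nx.Graph()
    for i in range(n):
        if keep[i]:
            attrs = (node_attrs or {}).get(sim.taxon_ids[i], {})
            g.add_node(sim.taxon_ids[i], **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                g.add_edge(
                    sim.taxon_ids[i],
                    sim.taxon_ids[j],
                    rho=float(rho[i, j]),
                    sign="+" if rho[i, j] > 0 else "-",
                )
    return CoNetwork(graph=g, st=st)


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoNetwork) else net


def link_sign_fractions(net) -> tuple[float, float]:
    """(percent positive, percent negative) of edges; sums to 100."""
    g = _graph(net)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("network has no edges")
    neg = sum(1 for _, _, d in g.edges(data=True) if d.get("sign") == "-")
    return 100.0 * (m - neg) / m, 100.0 * neg / m


def avg_connectivity(net) -> float:
    """Mean node degree, 2·|E| / |V|."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def avg_path_distance(net) -> float:
    """Mean unweighted shortest-path length over connected node pairs.

    Pairs in different components have no path and are excluded (logged when
    the graph is disconnected).
    """
    g = _graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("average path distance undefined without edges")
    components = list(nx.connected_components(g))
    if len(components) > 1:
        logger.info("graph has %d components; averaging within components", len(components))
    total = 0
    pairs = 0
    for comp in components:
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += len(comp) * (len(comp) - 1)
    return total / pairs


def avg_clustering(net) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(g))


def modularity_q(net, communities) -> float:
    """Newman modularity Q of a given partition on the unsigned skeleton."""
    return float(nx.community.modularity(_graph(net), communities))


def detect_modules(net) -> tuple[dict, float]:
    """Greedy agglomerative (CNM) modularity maximization.

    Returns (node → module id, Q).  Module ids are integers assigned in
    order of each module's first node in graph order, so the labelling is
    deterministic for a deterministically built graph.
    """
    g = _graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("module detection needs at least one edge")
    communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    order = {node: i for i, node in enumerate(g)}
    communities.sort(key=lambda c: min(order[v] for v in c))
    partition = {v: m for m, comm in enumerate(communities) for v in comm}
    q = modularity_q(g, communities)
    return partition, q


def network_report(net) -> NetworkReport:
    """The standard topology summary for one empirical network."""
    g = _graph(net)
    pct_pos, pct_neg = link_sign_fractions(g)
    partition, q = detect_modules(g)
    return NetworkReport(
        total_nodes=g.number_of_nodes(),
        total_links=g.number_of_edges(),
        pct_negative_links=pct_neg,
        pct_positive_links=pct_pos,
        avg_connectivity=avg_connectivity(g),
        avg_path_distance=avg_path_distance(g),
        avg_clustering_coefficient=avg_clustering(g),
        modularity=q,
        module_partition=partition,
    )


def edge_list(net) -> pd.DataFrame:
    """Signed edge list (source, target, rho, sign) in insertion order."""
    g = _graph(net)
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "sign": d["sign"]}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])
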