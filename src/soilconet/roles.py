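"""Zi–Pi node roles and Erdős–Rényi null-model comparison.

Node roles follow the within-module degree z-score (Zi) and participation
coefficient (Pi) scheme: with thresholds Zi = 2.5 and Pi = 0.62 the plane
splits into peripherals, connectors, module hubs and network hubs.
Connectors and hubs are the usual keystone candidates.

The null model is G(N, L): random graphs with the empirical node and link
counts, links placed uniformly at random, summarized by the same topology
metrics as the empirical network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    CoNetwork,
    _graph,
    avg_clustering,
    avg_path_distance,
    detect_modules,
)

Z_THRESH = 2.5
P_THRESH = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"


def within_module_degree_z(net, partition: dict) -> dict:
    """Within-module degree z-score Zi per node.

    Zi = (κ_i − mean_m κ) / sd_m κ, where κ_i counts links from node i to
    its own module m and mean/sd (population sd) run over the nodes of m.
    Modules in which every node has the same within-module degree get Zi = 0.
    """
    g = _graph(net)
    missing = [v for v in g if v not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    kappa = {
        v: sum(1 for nb in g[v] if partition[nb] == partition[v]) for v in g
    }
    z: dict = {}
    for m in set(partition[v] for v in g):
        members = [v for v in g if partition[v] == m]
        k = np.array([kappa[v] for v in members], dtype=float)
        sd = k.std()  # population sd
        mean = k.mean()
        for v in members:
            z[v] = 0.0 if sd == 0 else float((kappa[v] - mean) / sd)
    return z


def participation_coefficient(net, partition: dict) -> dict:
    """Participation coefficient Pi = 1 − Σ_t (k_it / k_i)² per node.

    0 when all links stay inside the node's own module; approaches 1 when
    links spread evenly over many modules.  Isolated nodes are rejected —
    they should have been dropped when the network was built.
    """
    g = _graph(net)
    missing = [v for v in g if v not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    pi: dict = {}
    for v in g:
        k = g.degree(v)
        if k == 0:
            raise ValueError(f"isolated node {v!r} has undefined participation")
        per_module: dict = {}
        for nb in g[v]:
            t = partition[nb]
            per_module[t] = per_module.get(t, 0) + 1
        pi[v] = float(1.0 - sum((kt / k) ** 2 for kt in per_module.values()))
    return pi


def classify_role(
    zi: float, pi: float, z_thresh: float = Z_THRESH, p_thresh: float = P_THRESH
) -> str:
    """Map a (Zi, Pi) pair to one of the four role regions.

    Boundaries: hubs need Zi >= z_thresh; connectors need Pi > p_thresh.
    """
    if zi >= z_thresh:
        return ROLE_NETWORK_HUB if pi > p_thresh else ROLE_MODULE_HUB
    return ROLE_CONNECTOR if pi > p_thresh else ROLE_PERIPHERAL


def node_role_table(net, partition: dict | None = None) -> pd.DataFrame:
    """Per-node module id, Zi, Pi and role category (the Zi–Pi scatter as data)."""
    g = _graph(net)
    if partition is None:
        partition, _ = detect_modules(g)
    z = within_module_degree_z(g, partition)
    p = participation_coefficient(g, partition)
    rows = []
    for v in g:
        row = {
            "node": v,
            "module": partition[v],
            "Zi": z[v],
            "Pi": p[v],
            "category": classify_role(z[v], p[v]),
        }
        if "phylum" in g.nodes[v]:
            row["phylum"] = g.nodes[v]["phylum"]
        rows.append(row)
    return pd.DataFrame(rows)


def er_random_network(n_nodes: int, n_links: int, seed: int) -> nx.Graph:
    """G(N, L) random graph: exactly ``n_links`` distinct unordered pairs,
    drawn uniformly; deterministic given ``seed``."""
    max_links = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_links <= max_links:
        raise ValueError(
            f"n_links={n_links} outside [0, {max_links}] for {n_nodes} nodes"
        )
    return nx.gnm_random_graph(n_nodes, n_links, seed=int(seed))


@dataclass
class NullSummary:
    n_replicates: int
    mean_avg_path_distance: float
    mean_avg_clustering: float
    mean_modularity: float
    sd_avg_path_distance: float
    sd_avg_clustering: float
    sd_modularity: float


def null_summary(
    n_nodes: int, n_links: int, n_reps: int = 100, seed: int = 0
) -> NullSummary:
    """Topology of ``n_reps`` G(N, L) nulls at the empirical (N, L).

    Uses the same metric implementations as the empirical network so the
    empirical-vs-random contrast compares like with like.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 null replicates")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    apd, acc, mod = [], [], []
    for s in seeds:
        g = er_random_network(n_nodes, n_links, int(s % 2**31))
        apd.append(avg_path_distance(g))
        acc.append(avg_clustering(g))
        mod.append(detect_modules(g)[1])
    return NullSummary(
        n_replicates=n_reps,
        mean_avg_path_distance=float(np.mean(apd)),
        mean_avg_clustering=float(np.mean(acc)),
        mean_modularity=float(np.mean(mod)),
        sd_avg_path_distance=float(np.std(apd, ddof=1)),
        sd_avg_clustering=float(np.std(acc, ddof=1)),
        sd_modularity=float(np.std(mod, ddof=1)),
    )
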