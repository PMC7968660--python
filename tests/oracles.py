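"""Hand-written brute-force oracles, independent of the library code paths.

Everything here works by explicit enumeration (sorting loops, BFS, triple
counting, all set partitions) so it can cross-check the vectorized /
library-backed implementations on small inputs.
"""

import math
from collections import deque


def midranks(values):
    """Average ranks for ties, computed with explicit sorting loops."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def spearman(x, y):
    return pearson(midranks(x), midranks(y))


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def avg_path_distance(adj):
    """Mean BFS distance over connected unordered pairs."""
    total = 0
    pairs = 0
    nodes = list(adj)
    for i, u in enumerate(nodes):
        dist = bfs_distances(adj, u)
        for v in nodes[i + 1 :]:
            if v in dist:
                total += dist[v]
                pairs += 1
    return total / pairs


def avg_clustering(adj):
    """Mean of 2·e_i / (k_i (k_i − 1)) via exhaustive neighbor-pair checks."""
    total = 0.0
    for u in adj:
        nbrs = list(adj[u])
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        total += 2 * closed / (k * (k - 1))
    return total / len(adj)


def modularity(adj, partition_sets):
    """Q = Σ_m [l_m/L − (d_m/2L)²] by explicit edge counting."""
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    L = len(edges)
    q = 0.0
    for block in partition_sets:
        lm = sum(1 for e in edges if e <= set(block))
        dm = sum(len(adj[u]) for u in block)
        q += lm / L - (dm / (2 * L)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list, by recursive insertion."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def max_modularity(adj):
    """Brute-force maximum Q over every partition of the node set."""
    nodes = list(adj)
    return max(modularity(adj, p) for p in set_partitions(nodes))


def adjacency(graph):
    """Plain dict-of-sets adjacency from a networkx graph."""
    return {u: set(graph[u]) for u in graph}
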