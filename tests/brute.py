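"""Independent brute-force oracles used by the test suite.

Everything here is written directly from first principles (exhaustive
enumeration, simple-path search) and deliberately shares no code with the
package implementation it checks.
"""

from itertools import permutations

import numpy as np


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def all_simple_paths(adj, s, t):
    """Every simple path from s to t, by depth-first enumeration."""
    paths = []
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            paths.append(path)
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + [w]))
    return paths


def shortest_path_counts(adj, s, t):
    """(distance, total shortest paths, per-node interior pass counts)."""
    paths = all_simple_paths(adj, s, t)
    if not paths:
        return None, 0, {}
    d = min(len(p) - 1 for p in paths)
    shortest = [p for p in paths if len(p) - 1 == d]
    through = {}
    for p in shortest:
        for v in p[1:-1]:
            through[v] = through.get(v, 0) + 1
    return d, len(shortest), through


def node_indices(nodes, edges):
    """All five node indices, by exhaustive enumeration."""
    nodes = list(nodes)
    adj = adjacency(nodes, edges)
    n = len(nodes)

    degree = {v: len(adj[v]) for v in nodes}

    clustering = {}
    for v in nodes:
        k = degree[v]
        if k < 2:
            clustering[v] = 0.0
            continue
        nbrs = list(adj[v])
        e = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        clustering[v] = 2.0 * e / (k * (k - 1))

    # distances and shortest-path counts for every unordered pair
    dist = {}
    sigma = {}
    through = {}
    for i in range(n):
        for j in range(i + 1, n):
            s, t = nodes[i], nodes[j]
            d, cnt, thr = shortest_path_counts(adj, s, t)
            dist[(s, t)] = dist[(t, s)] = d
            sigma[(s, t)] = cnt
            through[(s, t)] = thr

    betweenness = {}
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    for v in nodes:
        total = 0.0
        for (s, t), cnt in sigma.items():
            if cnt == 0 or v in (s, t):
                continue
            total += through[(s, t)].get(v, 0) / cnt
        betweenness[v] = total / norm

    closeness = {}
    for v in nodes:
        ds = [dist[(v, u)] for u in nodes if u != v and dist[(v, u)] is not None]
        closeness[v] = len(ds) / sum(ds) if ds and sum(ds) > 0 else 0.0

    topological = {}
    for v in nodes:
        k = degree[v]
        if k == 0:
            topological[v] = 0.0
            continue
        scores = []
        for m in nodes:
            if m == v:
                continue
            shared = len(adj[v] & adj[m])
            if shared == 0:
                continue
            scores.append(shared + (1 if m in adj[v] else 0))
        topological[v] = (sum(scores) / len(scores)) / k if scores else 0.0

    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "clustering": clustering,
        "topological": topological,
    }


def random_graph(rng, max_nodes=8):
    """A random small labelled graph (node list, edge set)."""
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.1, 0.9)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((nodes[i], nodes[j]))
    return nodes, edges


def point_segment_distance(p, a, b):
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def polygon_distance(poly1, poly2):
    """Minimum vertex-to-segment distance between two (disjoint) polygons."""
    best = np.inf
    for va, vb in ((poly1, poly2), (poly2, poly1)):
        segs = list(zip(vb, vb[1:] + [vb[0]]))
        for p in va:
            for a, b in segs:
                best = min(best, point_segment_distance(p, a, b))
    return best


def mid_ranks(values):
    """Average ranks with mid-rank tie handling, from the definition."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(a, b):
    """Pearson correlation of mid-ranks."""
    ra = np.array(mid_ranks(a))
    rb = np.array(mid_ranks(b))
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def candidate_pairs(component, occupied, all_nodes, sim_edges):
    """Exhaustive scan of all (i, j) pairs against the four candidate
    conditions: i in the component, j a node outside it, (i, j) a
    similarity edge."""
    sim = {frozenset(e) for e in sim_edges}
    out = set()
    for i in component:
        for j in all_nodes:
            if j in component:
                continue
            if frozenset((i, j)) in sim:
                out.add((i, j))
    return out
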