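"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) they verify: betweenness by exhaustive simple-path
enumeration, the 2x2 chi-squared by its closed form, and Fisher's test
by direct hypergeometric enumeration with math.comb.
"""

from itertools import combinations, permutations
from math import comb


def _bfs_distance(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_betweenness(nodes, edges):
    """Unnormalized betweenness by enumerating every shortest simple path.

    For each unordered pair {s, t}, all node sequences of the shortest
    length are enumerated from the remaining nodes and checked for
    adjacency; each interior node of each shortest path collects
    1 / (number of shortest s-t paths).
    """
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        dist = _bfs_distance(adj, s)
        if t not in dist:
            continue
        d = dist[t]
        others = [n for n in nodes if n not in (s, t)]
        paths = []
        for interior in permutations(others, d - 1):
            seq = (s, *interior, t)
            if all(seq[i + 1] in adj[seq[i]] for i in range(d)):
                paths.append(interior)
        if not paths:
            continue
        share = 1.0 / len(paths)
        for interior in paths:
            for v in interior:
                btw[v] += share
    return btw


def chi2_closed_form(a, b, c, d):
    """N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the table [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("zero margin")
    return n * (a * d - b * c) ** 2 / denom


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Sums the hypergeometric probability of every table whose probability
    does not exceed that of the observed table (with a tiny relative
    tolerance against float round-off).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
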