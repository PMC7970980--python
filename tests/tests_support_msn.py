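"""Shared test helpers: exhaustive minimum-spanning-network oracle."""
import itertools

import networkx as nx

from btnscreen._seqs import hamming


def brute_force_msn(seqs):
    """Union of all minimum spanning trees by exhaustive enumeration
    (feasible for <= ~7 haplotypes)."""
    ids = list(seqs)
    n = len(ids)
    if n == 1:
        return set()
    all_edges = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    w = {e: hamming(seqs[e[0]], seqs[e[1]]) for e in all_edges}

    def is_spanning_tree(edges):
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for u, v in edges:
            ru, rv = find(u), find(v)
            if ru == rv:
                return False
            parent[ru] = rv
        return True

    trees = [
        t
        for t in itertools.combinations(all_edges, n - 1)
        if is_spanning_tree(t)
    ]
    best = min(sum(w[e] for e in t) for t in trees)
    union = set()
    for t in trees:
        if sum(w[e] for e in t) == best:
            union.update(t)
    return union


def contract_medians(g):
    """Collapse median-node chains of an expanded network back into edges
    between observed haplotypes."""
    observed = [n for n, d in g.nodes(data=True) if not d.get("median")]
    direct = set()
    for a, b in itertools.combinations(observed, 2):
        for path in nx.all_simple_paths(g, a, b, cutoff=g.number_of_nodes()):
            if len(path) >= 2 and all(
                g.nodes[n].get("median") for n in path[1:-1]
            ):
                direct.add(frozenset((a, b)))
                break
    return direct
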