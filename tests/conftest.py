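import numpy as np
import pytest

from haplospec.simulate import revcomp

COMP = str.maketrans("ACGT", "TGCA")


def brute_force_verdicts(contigs, reads, k, canonical=True, max_shared_fraction=0.0):
    """Independent quadratic substring oracle for the k-mer subtraction.

    For each contig k-mer window (skipping windows with non-ACGT
    characters), scan every read — and, when canonicalization is on, every
    read's reverse complement — for the k-mer as a literal substring.
    """
    texts = list(reads)
    if canonical:
        texts = texts + [revcomp(r) for r in reads]
    haystack = "#".join(texts)
    verdicts = []
    for contig in contigs:
        windows = [
            contig[i : i + k]
            for i in range(len(contig) - k + 1)
            if set(contig[i : i + k]) <= set("ACGT")
        ]
        if not windows:
            verdicts.append("too_short")
            continue
        shared = sum(1 for w in windows if w in haystack)
        frac = shared / len(windows)
        verdicts.append("retained" if frac <= max_shared_fraction else "eliminated")
    return verdicts


def random_unrooted_tree(rng: np.random.Generator, n_taxa: int):
    """Random additive unrooted tree as (edges, leaf labels).

    Built by repeatedly splitting a random edge to attach a new pendant
    leaf.  Nodes are ints; leaves are labelled ``t0..t{n-1}``.  Returns
    (edge dict {(u, v): length}, {leaf node: label}).
    """
    assert n_taxa >= 3
    next_node = [0]

    def new_node():
        next_node[0] += 1
        return next_node[0] - 1

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = new_node()
    leaves = {}
    edges = {}
    for _ in range(3):
        leaf = new_node()
        leaves[leaf] = None
        edges[(center, leaf)] = blen()
    for _ in range(n_taxa - 3):
        (u, v) = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid = new_node()
        split = float(rng.uniform(0.2, 0.8)) * length
        edges[(u, mid)] = split
        edges[(mid, v)] = length - split
        leaf = new_node()
        leaves[leaf] = None
        edges[(mid, leaf)] = blen()
    for i, leaf in enumerate(sorted(leaves)):
        leaves[leaf] = f"t{i}"
    return edges, leaves


def tree_distance_matrix(edges, leaves):
    """Path-length distances between leaves of an edge-dict tree."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    labels = [leaves[n] for n in sorted(leaves)]
    nodes = sorted(leaves)
    n = len(nodes)
    D = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = lengths[nodes[i]][nodes[j]]
    return labels, D


def true_bipartitions(edges, leaves):
    """Internal-edge splits of an edge-dict tree, canonicalized as in
    haplospec.evolution.tree_bipartitions."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    all_labels = sorted(leaves.values())
    ref = all_labels[0]
    out = {}
    for (u, v), w in edges.items():
        if u in leaves or v in leaves:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        side_nodes = nx.node_connected_component(h, v)
        side = frozenset(leaves[n] for n in side_nodes if n in leaves)
        if ref in side:
            side = frozenset(all_labels) - side
        out[side] = w
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
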