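"""Shared helpers for tree tests: random additive matrices with an
independent (graph path-sum) distance oracle."""

import itertools

import networkx as nx
import numpy as np
from skbio import DistanceMatrix


def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (taxa, DistanceMatrix) where distances
    are brute-force shortest-path sums over the tree graph — independent
    of any NJ code under test."""
    g = nx.Graph()
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = list(taxa)
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = f"i{next(counter)}"
        g.add_edge(nodes[i], parent, weight=float(rng.uniform(0.1, 2.0)))
        g.add_edge(nodes[j], parent, weight=float(rng.uniform(0.1, 2.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        lengths = nx.single_source_dijkstra_path_length(g, taxa[a])
        for b in range(n_taxa):
            d[a, b] = lengths[taxa[b]]
    np.fill_diagonal(d, 0.0)
    return taxa, DistanceMatrix((d + d.T) / 2, ids=taxa)


def tip_distances(tree, taxa):
    """Tip-to-tip path lengths of a tree, ordered like ``taxa``."""
    tt = tree.tip_tip_distances()
    return np.array([[0.0 if a == b else tt[a, b] for b in taxa]
                     for a in taxa])
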