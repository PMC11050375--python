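import logging

import dendropy
import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea

# keep expected-warning noise (dropped species, undefined MNTD, ...) quiet
logging.getLogger("ecoassembly").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):1,C:2); — the worked 3-tip example used throughout."""
    return ea.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def random_tree6():
    """Random 6-tip Yule tree for exhaustive brute-force comparisons."""
    return ea.simulate_tree(6, seed=42)


@pytest.fixture(scope="session")
def scenario_small():
    """Mixed-regime synthetic dataset small enough for fast tests."""
    cfg = ea.ScenarioConfig(n_species=60, n_sites=24, community_size=86,
                            seed=7)
    return ea.generate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def community_from_array(a, species=None, sites=None):
    a = np.asarray(a)
    sites = sites or [f"s{i}" for i in range(a.shape[0])]
    species = species or [f"sp{j}" for j in range(a.shape[1])]
    return ea.CommunityMatrix(
        pd.DataFrame(a, index=sites, columns=species), drop_empty_sites=False)


# ---------------------------------------------------------------------------
# independent brute-force oracles built directly on the dendropy tree,
# sharing no code with the implementation's edge-incidence machinery


def _root_path_edges(tree: dendropy.Tree, leaf):
    edges = []
    node = leaf
    while node.parent_node is not None:
        edges.append(node)
        node = node.parent_node
    return edges


def oracle_faith_pd(phylo: ea.Phylogeny, labels, include_root=True):
    tree = phylo.tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    edge_union = set()
    per_leaf = []
    for lab in labels:
        path = _root_path_edges(tree, leaves[lab])
        per_leaf.append(set(path))
        edge_union |= set(path)
    total = sum(n.edge.length or 0.0 for n in edge_union)
    if not include_root:
        shared = set.intersection(*per_leaf) if per_leaf else set()
        total -= sum(n.edge.length or 0.0 for n in shared)
    return total


def oracle_patristic(phylo: ea.Phylogeny, a, b):
    tree = phylo.tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    pa = _root_path_edges(tree, leaves[a])
    pb = _root_path_edges(tree, leaves[b])
    sym = set(pa) ^ set(pb)
    return sum(n.edge.length or 0.0 for n in sym)


def oracle_mntd(phylo, labels):
    labels = list(labels)
    mins = []
    for a in labels:
        d = [oracle_patristic(phylo, a, b) for b in labels if b != a]
        mins.append(min(d))
    return float(np.mean(mins))


def oracle_beta_mntd(phylo, x_counts, y_counts, labels, weighted=True):
    xs = [(l, c) for l, c in zip(labels, x_counts) if c > 0]
    ys = [(l, c) for l, c in zip(labels, y_counts) if c > 0]
    tot_x = sum(c for _, c in xs)
    tot_y = sum(c for _, c in ys)
    sx = 0.0
    for a, c in xs:
        dmin = min(0.0 if a == b else oracle_patristic(phylo, a, b)
                   for b, _ in ys)
        w = c / tot_x if weighted else 1.0 / len(xs)
        sx += w * dmin
    sy = 0.0
    for b, c in ys:
        dmin = min(0.0 if a == b else oracle_patristic(phylo, a, b)
                   for a, _ in xs)
        w = c / tot_y if weighted else 1.0 / len(ys)
        sy += w * dmin
    return 0.5 * (sx + sy)


def oracle_abc_phylo(phylo, s1, s2):
    tree = phylo.tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    e1, e2 = set(), set()
    for lab in s1:
        e1 |= set(_root_path_edges(tree, leaves[lab]))
    for lab in s2:
        e2 |= set(_root_path_edges(tree, leaves[lab]))
    length = lambda s: sum(n.edge.length or 0.0 for n in s)
    return length(e1 & e2), length(e1 - e2), length(e2 - e1)
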