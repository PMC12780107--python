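import numpy as np
import pandas as pd
import pytest

from lowbiome.taxonomy import CountTable, TaxonNode, TaxonomyTree


def make_node(taxon_id, name, rank, clade, direct, parent=None):
    node = TaxonNode(
        taxon_id, name, rank,
        np.atleast_1d(np.asarray(clade, dtype=float)),
        np.atleast_1d(np.asarray(direct, dtype=float)),
        parent,
    )
    if parent is not None:
        parent.children.append(node)
    return node


@pytest.fixture
def toy_tree():
    """root(200) -> O(200, direct 20) -> F(180, direct 30) -> g1(100), g2(50)."""
    root = make_node(1, "root", "root", 200, 0)
    order = make_node(2, "O", "order", 200, 20, root)
    family = make_node(3, "F", "family", 180, 30, order)
    make_node(4, "g1", "genus", 100, 100, family)
    make_node(5, "g2", "genus", 50, 50, family)
    return TaxonomyTree(root, ["s1"])


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        {
            "s1": [100.0, 50.0, 5.0, 0.0],
            "s2": [80.0, 0.0, 10.0, 2.0],
            "s3": [60.0, 30.0, 0.0, 1.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return CountTable(data, "genus")


def random_tree(rng, max_nodes=6):
    """Random small rank-coded tree with integer counts, for oracle checks.

    Returns (TaxonomyTree, nested-dict mirror for the brute-force oracle).
    Ranks strictly decrease along paths; occasional 'no rank' intermediates.
    """
    ranks = ["domain", "phylum", "class", "order", "family"]
    root = make_node(1, "root", "root", 0, 0)
    mirror = {"name": "root", "rank": "root", "clade": 0.0, "children": []}
    nodes = [(root, mirror, 0)]  # (node, mirror, rank idx in `ranks` available from)
    genus_names = []
    next_id = 2
    n_internal = int(rng.integers(1, max_nodes - 1))
    for _ in range(n_internal):
        parent, pm, lo = nodes[int(rng.integers(0, len(nodes)))]
        if lo >= len(ranks):
            continue
        use_norank = rng.uniform() < 0.2
        rank = "no rank" if use_norank else ranks[int(rng.integers(lo, len(ranks)))]
        new_lo = lo if use_norank else ranks.index(rank) + 1
        node = make_node(next_id, f"n{next_id}", rank, 0, 0, parent)
        m = {"name": node.name, "rank": rank, "clade": 0.0, "children": []}
        pm["children"].append(m)
        nodes.append((node, m, new_lo))
        next_id += 1
    n_genera = int(rng.integers(1, 4))
    for _ in range(n_genera):
        parent, pm, _ = nodes[int(rng.integers(0, len(nodes)))]
        count = float(rng.integers(1, 200))
        node = make_node(next_id, f"g{next_id}", "genus", count, count, parent)
        m = {"name": node.name, "rank": "genus", "clade": count, "children": []}
        pm["children"].append(m)
        genus_names.append(node.name)
        next_id += 1
    # direct reads for internal nodes, then propagate clade sums upward
    def fill(node, m):
        direct = float(rng.integers(0, 30)) if node.rank != "genus" else node.direct[0]
        clade = direct + sum(fill(c, cm) for c, cm in zip(node.children, m["children"]))
        if node.rank != "genus":
            node.direct = np.array([direct])
            node.clade = np.array([clade])
            m["clade"] = clade
        return node.clade[0]

    fill(root, mirror)
    return TaxonomyTree(root, ["s1"]), mirror, genus_names
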