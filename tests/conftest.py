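"""Shared fixtures: random tree generation and independent oracles.

The oracles deliberately use different algorithms from the package: pairwise
LCA path walks for distances (vs. the package's single postorder sweep) and
per-edge graph traversal for bipartitions (vs. the package's cached tip
sets), so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from hybridtrace import tree_io  # noqa: E402


def random_newick(rng: np.random.Generator, n_tips: int, allow_polytomy: bool = False) -> str:
    """Random topology by sequential joins with uniform branch lengths."""
    parts = [f"t{i}" + f":{rng.uniform(0.01, 2.0):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        k = 3 if (allow_polytomy and len(parts) >= 3 and rng.random() < 0.2) else 2
        chosen = []
        for _ in range(k):
            chosen.append(parts.pop(int(rng.integers(len(parts)))))
        sub = "(" + ",".join(chosen) + ")"
        if len(parts) == 0:
            parts.append(sub)
        else:
            parts.append(sub + f":{rng.uniform(0.01, 2.0):.6f}")
    return parts[0] + ";"


def lca_path_distance(tree, label_a: str, label_b: str) -> float:
    """Oracle: distance via explicit lowest-common-ancestor path walk."""
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    node = leaves[label_a]
    to_root: dict[int, float] = {}
    d = 0.0
    while node is not None:
        to_root[id(node)] = d
        d += node.edge.length or 0.0
        node = node.parent_node
    node = leaves[label_b]
    d = 0.0
    while id(node) not in to_root:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d + to_root[id(node)]


def all_edge_sides(tree) -> list[frozenset]:
    """Oracle: for every edge, the tip set on the child side, found by a
    fresh traversal that never crosses the edge."""
    neighbors: dict[int, list] = {}
    nodes = {}
    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        neighbors.setdefault(id(node), [])
        for child in node.child_nodes():
            neighbors[id(node)].append(child)
            neighbors.setdefault(id(child), []).append(node)
    sides = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        # block the far end of the removed edge; a tree has no other route
        seen = {id(node), id(parent)}
        stack = [node]
        tips = set()
        while stack:
            cur = stack.pop()
            if cur.is_leaf():
                tips.add(cur.taxon.label)
            for nb in neighbors[id(cur)]:
                if id(nb) not in seen:
                    seen.add(id(nb))
                    stack.append(nb)
        sides.append(frozenset(tips))
    return sides


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_paths():
    from importlib import resources

    toy = resources.files("hybridtrace") / "data" / "toy"
    return {
        "tree": str(toy / "gene_tree.nwk"),
        "meta": str(toy / "meta.tsv"),
        "domains": str(toy / "domains.tsv"),
        "fasta": str(toy / "proteins.faa"),
    }


def parse(nwk: str):
    return tree_io.parse_newick(nwk)
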