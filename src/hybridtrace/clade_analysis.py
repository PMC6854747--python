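"""Monophyly tests, clade purity, and intra-species paralog distances.

All tests use unrooted edge semantics: a tip set is monophyletic when the
removal of a single edge bipartitions the tips into exactly that set versus
the rest.  This is invariant to the arbitrary rooting that ML programs
write, and handles polytomies natively.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from hybridtrace.phylo_distance import DistanceMatrix


@dataclass(frozen=True)
class MonophylyResult:
    labeled: frozenset
    is_monophyletic: bool
    #: tip set on the labeled side of the witnessing edge, when monophyletic
    witness_edge: frozenset | None
    #: unlabeled tips inside the smallest labeled-spanning clade (arbitrary
    #: rooting), when not monophyletic
    intruding_tips: tuple | None


@dataclass(frozen=True)
class PureClade:
    tips: frozenset
    value: str
    size: int


def _tip_sets(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Postorder map node-id -> frozenset of descendant tip labels."""
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set = set()
            for child in node.child_nodes():
                acc |= sets[id(child)]
            sets[id(node)] = frozenset(acc)
    return sets


def is_monophyletic(tree: dendropy.Tree, labeled) -> MonophylyResult:
    """Does some single edge separate exactly ``labeled`` from the rest?

    Singleton sets are trivially monophyletic (their terminal edge is the
    witness).  ``labeled`` must be a non-empty proper subset of the tips.
    """
    labeled = frozenset(labeled)
    sets = _tip_sets(tree)
    all_tips = sets[id(tree.seed_node)]
    if not labeled:
        raise ValueError("labeled set is empty")
    if not labeled <= all_tips:
        raise ValueError(f"labels not in tree: {sorted(labeled - all_tips)}")
    if labeled == all_tips:
        raise ValueError("labeled set equals the full tip set")

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = sets[id(node)]
        if side == labeled or all_tips - side == labeled:
            return MonophylyResult(labeled, True, side, None)

    spanning = min(
        (s for s in sets.values() if labeled <= s), key=len
    )
    return MonophylyResult(labeled, False, None, tuple(sorted(spanning - labeled)))


def maximal_pure_clades(
    tree: dendropy.Tree, meta: pd.DataFrame, attribute: str
) -> list[PureClade]:
    """Maximal unrooted clades whose tips all share one attribute value.

    A clade is one side of an edge bipartition; it is pure when all its tips
    carry the same value of ``attribute`` (e.g. section) and maximal when no
    larger pure clade contains it.  On a tree where sections sort perfectly
    this returns one clade per section; a single transferred tip inside a
    foreign section becomes its own pure clade of size 1.  The maximal pure
    clades always partition the tips.
    """
    sets = _tip_sets(tree)
    all_tips = sets[id(tree.seed_node)]
    values = {t: meta.loc[t, attribute] for t in all_tips}
    distinct = set(values.values())
    if len(distinct) == 1:
        v = next(iter(distinct))
        return [PureClade(all_tips, v, len(all_tips))]

    sides: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = sets[id(node)]
        sides.add(s)
        sides.add(all_tips - s)

    pure = [s for s in sides if s and len({values[t] for t in s}) == 1]
    maximal = [
        s for s in pure if not any(s < other for other in pure)
    ]
    clades = [
        PureClade(s, values[next(iter(s))], len(s)) for s in maximal
    ]
    clades.sort(key=lambda c: (-c.size, min(c.tips)))
    return clades


def paralog_distances(dm: DistanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """All same-species tip pairs with their cophenetic distance, sorted
    descending — large values are the duplication/reacquisition signatures."""
    missing = [t for t in dm.tips if t not in meta.index]
    if missing:
        raise KeyError(f"tips missing from metadata: {missing}")
    rows = []
    by_species: dict[str, list[str]] = {}
    for tip in dm.tips:
        by_species.setdefault(meta.loc[tip, "species"], []).append(tip)
    for species in sorted(by_species):
        tips = sorted(by_species[species])
        for i, a in enumerate(tips):
            for b in tips[i + 1 :]:
                rows.append(
                    {
                        "species": species,
                        "tip_a": a,
                        "tip_b": b,
                        "distance": dm.distance(a, b),
                    }
                )
    df = pd.DataFrame(rows, columns=["species", "tip_a", "tip_b", "distance"])
    return df.sort_values(
        ["distance", "species", "tip_a", "tip_b"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
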