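"""Cophenetic distances and nearest-neighbor section classification.

The cophenetic (patristic) distance between two tips is the sum of branch
lengths along the unique path connecting them; it is a property of the
unrooted tree and independent of root placement.  Classifying each focal
gene's nearest tree neighbor by the taxonomic section of its species turns
the matrix into an HGT screen: under strict vertical inheritance with
section-sorted trees every nearest neighbor is same-section, so a short
distance to a gene from another section is the signature of a candidate
horizontal transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

ASSIGNMENT_COLUMNS = [
    "tip_id",
    "neighbor_tip_id",
    "distance",
    "neighbor_section",
    "neighbor_species",
    "same_section",
    "same_species",
]


@dataclass
class DistanceMatrix:
    """Symmetric tip-distance matrix in substitutions/site along the path."""

    tips: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tips)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match tip list")
        self._index = {t: i for i, t in enumerate(self.tips)}

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tips, columns=self.tips)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="tip_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs path-length matrix of a tree, tips in lexicographic order.

    Single postorder sweep: each node carries the (tip, distance-to-node)
    pairs of its subtree; tip pairs meeting at a node get the sum of their
    two depths.  O(n^2) overall and root-placement independent.
    """
    tips = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    n = len(tips)
    if n < 2:
        raise ValueError("cophenetic matrix needs at least 2 tips")
    index = {t: i for i, t in enumerate(tips)}
    values = np.zeros((n, n))
    carry: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carry[id(node)] = [(index[node.taxon.label], 0.0)]
            continue
        lifted: list[list[tuple[int, float]]] = []
        for child in node.child_nodes():
            sub = carry.pop(id(child))
            edge = child.edge.length or 0.0
            lifted.append([(i, d + edge) for i, d in sub])
        combined: list[tuple[int, float]] = []
        for k, part in enumerate(lifted):
            for other in lifted[k + 1 :]:
                for i, di in part:
                    for j, dj in other:
                        values[i, j] = values[j, i] = di + dj
            combined.extend(part)
        carry[id(node)] = combined
    return DistanceMatrix(tips, values)


def select_tips(meta: pd.DataFrame, **criteria: str | Iterable[str]) -> list[str]:
    """Tips whose metadata matches every criterion (value or set of values),
    e.g. ``select_tips(meta, sm_class={"PKS-NRPS", "NRPS-PKS"})``."""
    mask = pd.Series(True, index=meta.index)
    for col, allowed in criteria.items():
        if isinstance(allowed, str):
            allowed = {allowed}
        mask &= meta[col].isin(set(allowed))
    return list(meta.index[mask])


def nearest_neighbor_origin(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    focal: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Nearest non-self neighbor of each focal tip, classified by section.

    Exact distance ties are broken by lexicographic neighbor id, so the
    result is deterministic and invariant to matrix tip order.  Same-species
    paralogs are eligible neighbors; the ``same_species`` flag lets callers
    filter them out if wanted.
    """
    missing = [t for t in dm.tips if t not in meta.index]
    if missing:
        raise KeyError(f"tips missing from metadata: {missing}")
    if focal is None:
        focal = dm.tips
    focal = sorted(focal)
    if not focal:
        warnings.warn("focal filter selected no tips", stacklevel=2)
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)

    rows = []
    idx = {t: i for i, t in enumerate(dm.tips)}
    for tip in focal:
        i = idx[tip]
        row = dm.values[i].copy()
        row[i] = np.inf
        best = row.min()
        ties = [dm.tips[j] for j in np.flatnonzero(row == best)]
        neighbor = min(ties)
        rows.append(
            {
                "tip_id": tip,
                "neighbor_tip_id": neighbor,
                "distance": float(best),
                "neighbor_section": meta.loc[neighbor, "section"],
                "neighbor_species": meta.loc[neighbor, "species"],
                "same_section": meta.loc[neighbor, "section"] == meta.loc[tip, "section"],
                "same_species": meta.loc[neighbor, "species"] == meta.loc[tip, "species"],
            }
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def flag_candidate_hgt(
    assignments: pd.DataFrame, quantile: float = 0.25
) -> pd.DataFrame:
    """Add a ``candidate_hgt`` column: cross-section nearest neighbor at a
    distance within the given quantile of all nearest-neighbor distances.

    The quantile is a screening knob (default 0.25), not an estimated
    parameter; the cross-section requirement carries the signal.
    """
    out = assignments.copy()
    if out.empty:
        out["candidate_hgt"] = pd.Series(dtype=bool)
        return out
    threshold = float(np.quantile(out["distance"].to_numpy(), quantile))
    out["candidate_hgt"] = (~out["same_section"]) & (out["distance"] <= threshold)
    return out


def section_origin_summary(
    assignments: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per focal species, counts of nearest neighbors by neighbor section —
    the long-format table behind a stacked 'origin of hybrid genes' barplot."""
    if assignments.empty:
        return pd.DataFrame(columns=["species", "neighbor_section", "n_genes"])
    species = assignments["tip_id"].map(meta["species"])
    counts = (
        pd.DataFrame(
            {"species": species, "neighbor_section": assignments["neighbor_section"]}
        )
        .groupby(["species", "neighbor_section"], sort=True)
        .size()
        .reset_index(name="n_genes")
    )
    return counts


def nearest_cross_section_distance(
    dm: DistanceMatrix, meta: pd.DataFrame
) -> pd.Series:
    """Per tip, distance to the nearest tip from a *different* section
    (NaN when the whole tree is one section)."""
    sections = np.array([meta.loc[t, "section"] for t in dm.tips])
    out = {}
    for i, tip in enumerate(dm.tips):
        mask = sections != sections[i]
        out[tip] = float(dm.values[i, mask].min()) if mask.any() else float("nan")
    return pd.Series(out, name="nearest_cross_section_distance")
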