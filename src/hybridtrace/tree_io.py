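"""Newick tree and tip-metadata I/O.

Trees are dendropy :class:`~dendropy.Tree` objects, stored rooted as
written.  All downstream distance and monophyly semantics are unrooted:
maximum-likelihood trees (e.g. from IQ-TREE) are arbitrarily rooted and no
conclusion here may depend on where the root landed.  Numeric labels on
internal nodes are kept as node labels and treated as support values
(IQ-TREE dialect), never as taxa.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from dendropy.calculate import treecompare

REQUIRED_META_COLUMNS = ("species", "section", "sm_class")


class NewickParseError(ValueError):
    """Malformed Newick input (position information comes from the parser)."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree.

    Quoted labels, support values on internal nodes and missing branch
    lengths are all accepted; missing lengths default to 0 with a warning.
    Duplicate tip labels are a parse error (the parser reports line/column).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickParseError(str(exc)) from None
    missing = 0
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            if node is not tree.seed_node:
                missing += 1
            node.edge.length = 0.0
    if missing:
        warnings.warn(
            f"{missing} branch length(s) missing; defaulted to 0", stacklevel=2
        )
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(label is None for label in labels):
        raise NewickParseError("unlabeled tip in tree")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 10 significant digits.

    ``parse_newick(write_newick(t))`` is isomorphic to ``t`` with equal
    branch lengths at that precision; support labels survive the trip.
    """
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"


def write_newick_file(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def load_tip_metadata(path: str | Path) -> pd.DataFrame:
    """Load the tip metadata table (tip_id, species, section, sm_class[,
    compound]) indexed by tip_id; compound defaults to empty."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "tip_id" not in meta.columns:
        raise ValueError(f"{path}: metadata needs a tip_id column")
    for col in REQUIRED_META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata needs a {col} column")
    if "compound" not in meta.columns:
        meta["compound"] = ""
    if meta["tip_id"].duplicated().any():
        dupes = meta.loc[meta["tip_id"].duplicated(), "tip_id"].tolist()
        raise ValueError(f"{path}: duplicate tip_id rows: {dupes}")
    return meta.set_index("tip_id")


def write_tip_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="tip_id")


def validate_tip_metadata(tree: dendropy.Tree, meta: pd.DataFrame) -> None:
    """Every tree tip must have a metadata row; raise naming offenders."""
    missing = [t for t in tip_labels(tree) if t not in meta.index]
    if missing:
        raise KeyError(f"tips missing from metadata: {missing}")


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition) distance between two
    Newick strings over the same tip set."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=tns,
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    b = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=tns,
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


def build_metadata(
    tip_ids: Iterable[str],
    species: Iterable[str],
    section: Iterable[str],
    sm_class: Iterable[str] | str = "",
    compound: Iterable[str] | str = "",
) -> pd.DataFrame:
    """Convenience constructor for in-memory metadata tables."""
    tip_ids = list(tip_ids)
    if isinstance(sm_class, str):
        sm_class = [sm_class] * len(tip_ids)
    if isinstance(compound, str):
        compound = [compound] * len(tip_ids)
    return pd.DataFrame(
        {
            "species": list(species),
            "section": list(section),
            "sm_class": list(sm_class),
            "compound": list(compound),
        },
        index=pd.Index(tip_ids, name="tip_id"),
    )
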