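"""Duplication-transfer-loss (DTL) gene-family simulator with ground truth.

The simulator provides the controlled conditions under which the
nearest-neighbor HGT screen can be validated: a sectioned species tree with
deep inter-section stems and shallow within-section divergences, and gene
families evolving along it under a birth-death-transfer process.  Every
event is logged, and every extant gene copy carries a ground-truth flag for
transferred ancestry, so recall and precision of any downstream detector can
be measured exactly.

Model
-----
* Species tree: sections are monophyletic blocks.  Within a section the
  species coalesce at ages below ``within_section_divergence``; section
  stems join near the root, between 75% and 100% of ``species_tree_height``
  (ages measured back from the present).
* Gene process: each gene lineage duplicates at rate ``dup_rate``, dies at
  rate ``loss_rate`` and emits a transferred copy at rate ``transfer_rate``
  (events per lineage per time unit), with exponential waiting times.  A
  transfer recipient is a contemporaneous species-tree branch, chosen from
  the branches section-disjoint with the donor with probability
  ``transfer_cross_section_prob`` (otherwise from the rest); transfers are
  additive — the donor keeps its copy, matching reacquisition narratives
  where both lineages retain the gene.
* Branch lengths: elapsed time multiplied by i.i.d. lognormal noise with
  mean 1 and coefficient of variation ``branch_length_noise_cv``, a cheap
  stand-in for among-lineage rate heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from hybridtrace import tree_io
from hybridtrace.phylo_distance import (
    DistanceMatrix,
    nearest_cross_section_distance,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults describe a genus with 4 sections of 4 species each, species
    tree height 1.0 (substitutions/site along a clock-like path), sections
    ten times older than the divergence within them, and moderate gene
    turnover.  ``transfer_rate=0.1`` over a height-1 tree leaves roughly 10%
    of extant copies with transferred ancestry;
    ``transfer_cross_section_prob=1`` makes every transfer cross sections.
    """

    n_sections: int = 4
    species_per_section: int = 4
    species_tree_height: float = 1.0
    within_section_divergence: float = 0.1
    dup_rate: float = 0.3
    loss_rate: float = 0.2
    transfer_rate: float = 0.1
    transfer_cross_section_prob: float = 1.0
    root_gene_copies: int = 1
    branch_length_noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "transfer_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.transfer_cross_section_prob <= 1:
            raise ValueError("transfer_cross_section_prob must be in [0,1]")
        if self.n_sections < 1 or self.species_per_section < 1:
            raise ValueError("need at least one section and one species")
        if self.root_gene_copies < 1:
            raise ValueError("root_gene_copies must be >= 1")


@dataclass(frozen=True)
class SimEvent:
    kind: str  # duplication | loss | transfer
    time: float  # time since the root, forward
    donor_lineage: str  # species-tree branch (label of its child node)
    recipient_lineage: str | None  # transfers only
    gene_copy: int

    def __post_init__(self) -> None:
        if self.kind == "transfer" and self.recipient_lineage == self.donor_lineage:
            raise ValueError("transfer donor and recipient must differ")


@dataclass
class SimResult:
    config: SimConfig
    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree | None  # None when the family went extinct
    events: list[SimEvent]
    meta: pd.DataFrame  # per gene tip: species, section, sm_class, compound
    truth: dict[str, bool]  # tip -> transferred ancestry on its lineage path
    extinct: bool
    #: lineage splits at speciation nodes, needed for copy-count bookkeeping
    n_speciation_splits: int = 0


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class _SpNode:
    __slots__ = ("label", "age", "children", "parent")

    def __init__(self, label: str, age: float):
        self.label = label
        self.age = age
        self.children: list[_SpNode] = []
        self.parent: _SpNode | None = None

    def add(self, child: "_SpNode") -> None:
        child.parent = self
        self.children.append(child)


def _sp_to_dendropy(root: _SpNode) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(sp: _SpNode, node: dendropy.Node) -> None:
        node.label = None if sp.children else sp.label
        if not sp.children:
            node.taxon = tns.new_taxon(sp.label)
        for child in sp.children:
            cn = dendropy.Node()
            cn.edge.length = sp.age - child.age
            node.add_child(cn)
            build(child, cn)

    build(root, tree.seed_node)
    tree.seed_node.edge.length = 0.0
    return tree


def simulate_species_tree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Sectioned, ultrametric species tree plus species -> section map.

    Sections are monophyletic by construction.  Within-section coalescences
    happen at ages uniform in (0.2, 1.0) x ``within_section_divergence``;
    section stems join at ages uniform in (0.75, 1.0) x
    ``species_tree_height`` with the root pinned exactly at the height.
    Equal seeds give identical Newick output.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = config.within_section_divergence
    h = config.species_tree_height
    anc_counter = [0]

    def join_all(nodes: list[_SpNode], ages: Iterable[float]) -> _SpNode:
        nodes = list(nodes)
        for age in ages:
            i = int(rng.integers(len(nodes)))
            a = nodes.pop(i)
            j = int(rng.integers(len(nodes)))
            b = nodes.pop(j)
            anc_counter[0] += 1
            parent = _SpNode(f"anc{anc_counter[0]}", age)
            parent.add(a)
            parent.add(b)
            nodes.append(parent)
        return nodes[0]

    section_roots = []
    sections: dict[str, str] = {}
    for s in range(1, config.n_sections + 1):
        sec = f"sec{s}"
        leaves = []
        for j in range(1, config.species_per_section + 1):
            sp = f"{sec}_sp{j}"
            sections[sp] = sec
            leaves.append(_SpNode(sp, 0.0))
        k = len(leaves)
        ages = np.sort(rng.uniform(0.2 * w, w, size=k - 1)) if k > 1 else []
        section_roots.append(join_all(leaves, ages))

    if config.n_sections > 1:
        ages = np.sort(rng.uniform(0.75 * h, h, size=config.n_sections - 1))
        ages[-1] = h
        root = join_all(section_roots, ages)
    else:
        root = section_roots[0]
    return _sp_to_dendropy(root), sections


# ---------------------------------------------------------------------------
# gene family simulation
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("time", "children", "label", "species")

    def __init__(self, time: float):
        self.time = time
        self.children: list[_GNode] = []
        self.label: str | None = None
        self.species: str | None = None


@dataclass(frozen=True)
class _Branch:
    node_key: int  # id() of the dendropy node
    label: str
    t_lo: float  # exclusive
    t_hi: float  # inclusive
    sections: frozenset
    is_leaf: bool
    species: str | None


def _index_species_tree(
    species_tree: dendropy.Tree, sections: dict[str, str]
) -> tuple[dict[int, dict], list[_Branch]]:
    """Per-node times (forward from the root) and the branch table."""
    info: dict[int, dict] = {}
    root = species_tree.seed_node
    anc = 0
    for node in species_tree.preorder_node_iter():
        if node is root:
            t = 0.0
        else:
            t = info[id(node.parent_node)]["t"] + (node.edge.length or 0.0)
        if node.is_leaf():
            label = node.taxon.label
        else:
            anc += 1
            label = node.label or f"anc{anc}"
        info[id(node)] = {"t": t, "label": label, "node": node}
    secsets: dict[int, frozenset] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            secsets[id(node)] = frozenset([sections[node.taxon.label]])
        else:
            acc: set = set()
            for child in node.child_nodes():
                acc |= secsets[id(child)]
            secsets[id(node)] = frozenset(acc)
    branches = []
    for node in species_tree.preorder_node_iter():
        if node is root:
            continue
        branches.append(
            _Branch(
                node_key=id(node),
                label=info[id(node)]["label"],
                t_lo=info[id(node.parent_node)]["t"],
                t_hi=info[id(node)]["t"],
                sections=secsets[id(node)],
                is_leaf=node.is_leaf(),
                species=node.taxon.label if node.is_leaf() else None,
            )
        )
    return info, branches


def simulate_gene_family(
    species_tree: dendropy.Tree,
    config: SimConfig,
    sections: dict[str, str],
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Run the birth-death-transfer process along a species tree.

    With all rates zero and one root copy the gene tree is congruent to the
    species tree.  If every copy dies the result is flagged ``extinct`` with
    ``gene_tree=None``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    info, branches = _index_species_tree(species_tree, sections)
    branch_of = {b.node_key: b for b in branches}
    root = species_tree.seed_node

    lam_d, lam_l, lam_t = config.dup_rate, config.loss_rate, config.transfer_rate
    total_rate = lam_d + lam_l + lam_t

    events: list[SimEvent] = []
    truth: dict[str, bool] = {}
    tip_species: dict[str, str] = {}
    copy_counter = [0]
    n_speciation_splits = 0

    def new_copy() -> int:
        copy_counter[0] += 1
        return copy_counter[0]

    groot = _GNode(0.0)
    # (species node, current time, gene node to attach to, transferred, copy)
    stack: list[tuple[dendropy.Node, float, _GNode, bool, int]] = []
    root_children = root.child_nodes()
    for _ in range(config.root_gene_copies):
        cid = new_copy()
        if not root_children:  # single-species tree: the root is the leaf
            stack.append((root, 0.0, groot, False, cid))
        else:
            origin = _GNode(0.0)
            groot.children.append(origin)
            n_speciation_splits += len(root_children) - 1
            for child in reversed(root_children):
                stack.append((child, 0.0, origin, False, cid))

    while stack:
        sp_node, t0, parent, transferred, copy_id = stack.pop()
        while True:
            t_end = info[id(sp_node)]["t"]
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            t_ev = t0 + wait
            if t_ev >= t_end:
                gnode = _GNode(t_end)
                parent.children.append(gnode)
                if sp_node.is_leaf():
                    species = sp_node.taxon.label
                    label = f"{species}_c{copy_id}"
                    gnode.label = label
                    gnode.species = species
                    truth[label] = transferred
                    tip_species[label] = species
                else:
                    kids = sp_node.child_nodes()
                    n_speciation_splits += len(kids) - 1
                    for child in reversed(kids):
                        stack.append((child, t_end, gnode, transferred, copy_id))
                break
            # an event happened on this branch at t_ev
            u = rng.random() * total_rate
            donor_label = info[id(sp_node)]["label"] if sp_node is not root else "root"
            if u < lam_d:
                cid = new_copy()
                events.append(
                    SimEvent("duplication", t_ev, donor_label, None, cid)
                )
                gnode = _GNode(t_ev)
                parent.children.append(gnode)
                stack.append((sp_node, t_ev, gnode, transferred, cid))
                parent, t0 = gnode, t_ev
            elif u < lam_d + lam_l:
                events.append(SimEvent("loss", t_ev, donor_label, None, copy_id))
                break
            else:
                donor_secs = (
                    branch_of[id(sp_node)].sections
                    if id(sp_node) in branch_of
                    else frozenset()
                )
                alive = [
                    b
                    for b in branches
                    if b.t_lo < t_ev <= b.t_hi and b.node_key != id(sp_node)
                ]
                cross = [b for b in alive if b.sections.isdisjoint(donor_secs)]
                within = [b for b in alive if not b.sections.isdisjoint(donor_secs)]
                want_cross = rng.random() < config.transfer_cross_section_prob
                pool = (cross or within) if want_cross else (within or cross)
                if not pool:
                    t0 = t_ev  # nothing contemporaneous to receive the copy
                    continue
                recipient = pool[int(rng.integers(len(pool)))]
                cid = new_copy()
                events.append(
                    SimEvent("transfer", t_ev, donor_label, recipient.label, cid)
                )
                gnode = _GNode(t_ev)
                parent.children.append(gnode)
                rec_node = _node_by_key(species_tree, recipient.node_key)
                stack.append((rec_node, t_ev, gnode, True, cid))
                parent, t0 = gnode, t_ev

    events.sort(key=lambda e: (e.time, e.gene_copy))
    pruned = _prune(groot)
    if pruned is None:
        gene_tree = None
        meta = tree_io.build_metadata([], [], [], sm_class="hybrid")
    else:
        gene_tree = _gene_to_dendropy(pruned, rng, config.branch_length_noise_cv)
        tips = sorted(truth)
        meta = tree_io.build_metadata(
            tips,
            [tip_species[t] for t in tips],
            [sections[tip_species[t]] for t in tips],
            sm_class="hybrid",
        )
    return SimResult(
        config=config,
        species_tree=species_tree,
        gene_tree=gene_tree,
        events=events,
        meta=meta,
        truth=truth,
        extinct=pruned is None,
        n_speciation_splits=n_speciation_splits,
    )


def _node_by_key(tree: dendropy.Tree, key: int) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if id(node) == key:
            return node
    raise KeyError(key)


def _prune(node: _GNode) -> _GNode | None:
    """Drop extinct subtrees and splice unary chains (times are absolute, so
    path lengths are preserved)."""
    if node.label is not None:
        return node
    kept = []
    for child in node.children:
        p = _prune(child)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _gene_to_dendropy(
    groot: _GNode, rng: np.random.Generator, cv: float
) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        mu = -0.5 * sigma * sigma
        noise = lambda: float(rng.lognormal(mu, sigma))  # noqa: E731
    else:
        noise = lambda: 1.0  # noqa: E731

    def build(g: _GNode, node: dendropy.Node) -> None:
        if g.label is not None:
            node.taxon = tns.new_taxon(g.label)
            return
        for child in g.children:
            cn = dendropy.Node()
            cn.edge.length = (child.time - g.time) * noise()
            node.add_child(cn)
            build(child, cn)

    tree.seed_node.edge.length = 0.0
    build(groot, tree.seed_node)
    return tree


def simulate(config: SimConfig) -> SimResult:
    """Species tree plus one gene family from a single seeded generator;
    equal configs (including seed) give byte-identical outputs."""
    rng = np.random.default_rng(config.seed)
    species_tree, sections = simulate_species_tree(config, rng)
    return simulate_gene_family(species_tree, config, sections, rng)


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    """Detector performance against simulation ground truth.

    ``recall``/``precision`` are None when undefined (no truth positives /
    nothing called).  The distance fields hold per-tip nearest-neighbor
    distances split by truth, plus — when a distance matrix is supplied —
    each tip's distance to the nearest cross-section tip, the quantity whose
    shift signals HGT.
    """

    recall: float | None
    precision: float | None
    n_truth: int
    n_called: int
    n_correct: int
    nn_dist_transferred: np.ndarray = field(default_factory=lambda: np.array([]))
    nn_dist_vertical: np.ndarray = field(default_factory=lambda: np.array([]))
    cross_dist_transferred: np.ndarray = field(default_factory=lambda: np.array([]))
    cross_dist_vertical: np.ndarray = field(default_factory=lambda: np.array([]))


def evaluate_recovery(
    sim: SimResult,
    assignments: pd.DataFrame,
    dm: DistanceMatrix | None = None,
) -> RecoveryResult:
    """Score the cross-section nearest-neighbor call against the event log.

    A tip is called an HGT candidate iff its nearest neighbor belongs to a
    different section; truth is the simulator's transferred-ancestry flag.
    """
    called = set(assignments.loc[~assignments["same_section"], "tip_id"])
    positives = {t for t, v in sim.truth.items() if v}
    correct = called & positives
    recall = len(correct) / len(positives) if positives else None
    precision = len(correct) / len(called) if called else None

    nn = assignments.set_index("tip_id")["distance"]
    t_mask = nn.index.map(lambda t: sim.truth.get(t, False)).to_numpy(dtype=bool)
    res = RecoveryResult(
        recall=recall,
        precision=precision,
        n_truth=len(positives),
        n_called=len(called),
        n_correct=len(correct),
        nn_dist_transferred=nn.to_numpy()[t_mask],
        nn_dist_vertical=nn.to_numpy()[~t_mask],
    )
    if dm is not None:
        cross = nearest_cross_section_distance(dm, sim.meta)
        c_mask = cross.index.map(lambda t: sim.truth.get(t, False)).to_numpy(dtype=bool)
        res.cross_dist_transferred = cross.to_numpy()[c_mask]
        res.cross_dist_vertical = cross.to_numpy()[~c_mask]
    return res


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_sim(sim: SimResult, outdir: str | Path) -> list[Path]:
    """Write species tree, gene tree, tip metadata and event log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "species_tree.nwk"
    tree_io.write_newick_file(sim.species_tree, p)
    written.append(p)
    if sim.gene_tree is not None:
        p = outdir / "gene_tree.nwk"
        tree_io.write_newick_file(sim.gene_tree, p)
        written.append(p)
    p = outdir / "tip_metadata.tsv"
    meta = sim.meta.copy()
    meta["transferred_ancestry"] = [sim.truth[t] for t in meta.index]
    tree_io.write_tip_metadata(meta, p)
    written.append(p)
    p = outdir / "events.tsv"
    with open(p, "w") as fh:
        fh.write("kind\ttime\tdonor_lineage\trecipient_lineage\tgene_copy\n")
        for e in sim.events:
            fh.write(
                f"{e.kind}\t{e.time:.10g}\t{e.donor_lineage}\t"
                f"{e.recipient_lineage or ''}\t{e.gene_copy}\n"
            )
    written.append(p)
    return written


def gene_species_rf(sim: SimResult) -> int:
    """Robinson-Foulds distance between the gene tree (tips renamed to their
    species) and the species tree; requires exactly one extant copy per
    species, as in a null (rate-free) simulation."""
    if sim.gene_tree is None:
        raise ValueError("gene family is extinct")
    species = [sim.meta.loc[t, "species"] for t in sim.meta.index]
    if len(set(species)) != len(species):
        raise ValueError("multiple gene copies per species; RF comparison undefined")
    renamed = tree_io.parse_newick(tree_io.write_newick(sim.gene_tree))
    for leaf in renamed.leaf_node_iter():
        leaf.taxon.label = sim.meta.loc[leaf.taxon.label, "species"]
    gene_nwk = tree_io.write_newick(renamed)
    return tree_io.robinson_foulds(gene_nwk, tree_io.write_newick(sim.species_tree))
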