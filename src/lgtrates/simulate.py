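"""Synthetic reference trees and gene histories with implanted transfers.

Reference trees are birth-death trees conditioned on the number of extant
tips (via dendropy), rescaled so the root sits at the requested age.  Gene
histories place gain events on branches (a Poisson number of gains, at
positions weighted by branch duration), optionally followed by losses
inside the gained subtree.  Gene trees are constructed topologically: each
gain's surviving carriers contribute the induced reference subtree, and
multiple gains are joined at an artificial root, so every implanted
recipient is a monophyletic gene-tree clade.  Supports start at 100 and can
be degraded stochastically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from dendropy.simulate import treesim

from .congruence import induced_subtree
from .errors import LgtratesError, ValidationError
from .trees import (
    DatedTree,
    GeneTree,
    LinkageRecord,
    LinkageTable,
    Node,
    PresenceMatrix,
    Tree,
)

__all__ = [
    "SimulationConfig",
    "TrueGain",
    "TrueLoss",
    "TrueHistory",
    "simulate_reference_tree",
    "simulate_gene_history",
    "degrade_supports",
]


@dataclass
class SimulationConfig:
    n_taxa: int = 32
    birth_rate: float = 1.0  # per lineage per Gy
    death_rate: float = 0.0
    root_age: float = 3.5  # Ga
    transfer_rate: float = 0.3  # gains per Gy of total branch length
    loss_rate: float = 0.0  # per lineage per Gy within a gained subtree
    n_genes: int = 1
    n_linkage_groups: int = 0  # pairs of genes sharing gain events
    support_noise: float = 0.0
    seed: int = 1
    gain_range: tuple[int, int] | None = None  # condition gains into [lo, hi]
    max_retries: int = 200

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("n_taxa must be >= 4")
        for name in ("birth_rate", "death_rate", "transfer_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrueGain:
    gene_group: frozenset[str]
    recipient: frozenset[str]  # leaves subtended by the gained edge
    time: float  # Ga before present


@dataclass(frozen=True)
class TrueLoss:
    gene: str
    lost: frozenset[str]
    time: float


@dataclass
class TrueHistory:
    config: SimulationConfig
    gains: list[TrueGain]
    losses: list[TrueLoss]
    presence: PresenceMatrix
    gene_trees: dict[str, GeneTree]
    linkage: LinkageTable
    carriers: dict[str, dict[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )  # gene -> recipient -> surviving carriers


def simulate_reference_tree(config: SimulationConfig) -> DatedTree:
    """Birth-death tree with ``n_taxa`` extant tips, root at ``root_age`` Ga."""
    rng = random.Random(config.seed)
    last_error = None
    for _ in range(config.max_retries):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_taxa,
                rng=rng,
            )
            break
        except Exception as exc:  # full extinction under high death rates
            last_error = exc
    else:
        raise LgtratesError(
            f"birth-death simulation failed after {config.max_retries} tries: {last_error}"
        )

    def convert(dnode) -> Node:
        node = Node()
        if dnode.taxon is not None:
            node.label = dnode.taxon.label.replace(" ", "_")
        node.length = dnode.edge.length
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    # pad every tip by 10% of the root depth so no terminal has zero duration
    # (the simulator stops exactly at the n-th speciation); ultrametricity and
    # relative node ages are preserved, and everything is rescaled next.
    depth: dict[int, float] = {}

    def fill_depth(node: Node) -> float:
        if node.is_leaf:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = max(fill_depth(c) + (c.length or 0.0) for c in node.children)
        return depth[id(node)]

    total = fill_depth(root)
    pad = 0.1 * total if total > 0 else 1.0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            node.length = (node.length or 0.0) + pad
        stack.extend(node.children)
    fill_depth(root)
    scale = config.root_age / depth[id(root)]
    for key in depth:
        depth[key] *= scale
    stack = [root]
    while stack:
        node = stack.pop()
        node.age = depth[id(node)]
        if node.length is not None:
            node.length *= scale
        stack.extend(node.children)
    root.length = None
    tree = DatedTree(root)
    # deterministic leaf labels t01..tNN in tree order
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"t{i:02d}"
    return DatedTree(tree.root)


def _edge_nodes(tree: DatedTree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _sample_gain_edges(
    tree: DatedTree, n_gains: int, rng: np.random.Generator, max_retries: int
) -> list[Node]:
    """Distinct, mutually non-nested, non-sibling gain edges, none subtending
    all taxa.

    Sibling edges are rejected because two gains on sister branches are
    indistinguishable from a single gain on the parent branch — the implanted
    history would not be identifiable even in principle.
    """
    edges = _edge_nodes(tree)
    durations = np.array([n.parent.age - n.age for n in edges])
    if durations.sum() <= 0:
        raise LgtratesError("tree has no branch time to place gains on")
    weights = durations / durations.sum()
    all_taxa = frozenset(tree.leaf_labels())
    for _ in range(max_retries):
        picks = rng.choice(len(edges), size=n_gains, replace=False, p=weights)
        chosen = [edges[i] for i in picks]
        sets = [tree.leafset(n) for n in chosen]
        if any(s == all_taxa for s in sets):
            continue
        nested = any(
            (sets[i] <= sets[j] or sets[j] <= sets[i])
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        )
        if nested:
            continue
        siblings = any(
            chosen[i].parent is chosen[j].parent
            for i in range(len(chosen))
            for j in range(i + 1, len(chosen))
        )
        if siblings:
            continue
        return chosen
    raise LgtratesError(
        f"could not place {n_gains} non-nested gains in {max_retries} tries"
    )


def _apply_losses(
    tree: DatedTree,
    gain_node: Node,
    gain_time: float,
    loss_rate: float,
    rng: np.random.Generator,
) -> tuple[frozenset[str], list[tuple[frozenset[str], float]]]:
    """Survivor leaves after a Poisson loss process inside the gained subtree."""
    carriers = set(tree.leafset(gain_node))
    losses: list[tuple[frozenset[str], float]] = []
    if loss_rate <= 0:
        return frozenset(carriers), losses

    def walk(node: Node, upper_time: float):
        duration = upper_time - node.age
        n_loss = rng.poisson(loss_rate * max(duration, 0.0))
        if n_loss > 0:
            time = float(rng.uniform(node.age, upper_time))
            lost = tree.leafset(node)
            carriers.difference_update(lost)
            losses.append((lost, time))
            return  # everything below is gone already
        for child in node.children:
            walk(child, node.age)

    walk(gain_node, gain_time)
    return frozenset(carriers), losses


def _build_gene_tree(
    tree: DatedTree, gene: str, clades: list[frozenset[str]]
) -> GeneTree | None:
    subtrees = []
    for clade in clades:
        if not clade:
            continue
        sub = induced_subtree(tree, clade)
        subtrees.append(sub.root)
    if not subtrees:
        return None
    if len(subtrees) == 1:
        root = subtrees[0]
    else:
        root = Node()
        for sub in subtrees:
            sub.parent = None
            if sub.length is None:
                sub.length = 1.0
            root.add_child(sub)
    for node in Tree(root).postorder():
        if not node.is_leaf and node.parent is not None:
            node.support_primary = 100.0
    return GeneTree(root, gene_name=gene, rooting_state="rooted")


def simulate_gene_history(tree: DatedTree, config: SimulationConfig) -> TrueHistory:
    """Implant gains (and optional losses) for ``n_genes`` genes on ``tree``.

    Genes paired into linkage groups share their gain events and receive
    adjacency records (gap 0) for every carrier taxon.
    """
    rng = np.random.default_rng(config.seed)
    edges = _edge_nodes(tree)
    total_time = sum(n.parent.age - n.age for n in edges)

    gene_names = [f"g{i + 1}" for i in range(config.n_genes)]
    # linked pairs: (g1,g2), (g3,g4), ... up to n_linkage_groups pairs
    follower_of: dict[str, str] = {}
    for k in range(config.n_linkage_groups):
        a, b = 2 * k, 2 * k + 1
        if b < len(gene_names):
            follower_of[gene_names[b]] = gene_names[a]

    gains: list[TrueGain] = []
    losses: list[TrueLoss] = []
    presence_data: dict[str, dict[str, int]] = {g: {} for g in gene_names}
    gene_trees: dict[str, GeneTree] = {}
    linkage_records: list[LinkageRecord] = []
    carriers_map: dict[str, dict[frozenset[str], frozenset[str]]] = {}
    gain_edges_of: dict[str, list[tuple[Node, float]]] = {}

    for gene in gene_names:
        if gene in follower_of:
            gain_edges_of[gene] = gain_edges_of[follower_of[gene]]
            continue
        for _ in range(config.max_retries):
            n_gains = int(rng.poisson(config.transfer_rate * total_time))
            if config.gain_range is None:
                break
            lo, hi = config.gain_range
            if lo <= n_gains <= hi:
                break
        else:
            raise LgtratesError("could not draw a gain count in the requested range")
        if n_gains == 0:
            gain_edges_of[gene] = []
            continue
        chosen = _sample_gain_edges(tree, n_gains, rng, config.max_retries)
        with_times = []
        for node in chosen:
            time = float(rng.uniform(node.age, node.parent.age))
            with_times.append((node, time))
        gain_edges_of[gene] = with_times

    for gene in gene_names:
        clades: list[frozenset[str]] = []
        carriers_map[gene] = {}
        group = frozenset(
            [gene] + [g for g, leader in follower_of.items() if leader == gene]
        ) if gene not in follower_of else frozenset([follower_of[gene], gene])
        for node, time in gain_edges_of[gene]:
            recipient = tree.leafset(node)
            survivors, local_losses = _apply_losses(
                tree, node, time, config.loss_rate, rng
            )
            if gene not in follower_of:
                gains.append(TrueGain(gene_group=group, recipient=recipient, time=time))
            for lost, lt in local_losses:
                losses.append(TrueLoss(gene=gene, lost=lost, time=lt))
            carriers_map[gene][recipient] = survivors
            if survivors:
                clades.append(survivors)
        all_carriers = frozenset().union(*clades) if clades else frozenset()
        for taxon in tree.leaf_labels():
            presence_data[gene][taxon] = 1 if taxon in all_carriers else 0
        gene_tree = _build_gene_tree(tree, gene, clades)
        if gene_tree is not None:
            if config.support_noise > 0:
                gene_tree = degrade_supports(
                    gene_tree, config.support_noise, seed=config.seed
                )
            gene_trees[gene] = gene_tree
        if gene in follower_of:
            leader = follower_of[gene]
            for taxon in sorted(all_carriers):
                linkage_records.append(LinkageRecord(taxon, leader, gene, 0))

    presence = PresenceMatrix.from_dict(presence_data)
    return TrueHistory(
        config=config,
        gains=gains,
        losses=losses,
        presence=presence,
        gene_trees=gene_trees,
        linkage=LinkageTable(linkage_records),
        carriers=carriers_map,
    )


def degrade_supports(gene_tree: GeneTree, noise: float, seed: int = 1) -> GeneTree:
    """Resample supports downward; noise 0 is the identity, noise 1 pushes
    every support below the 70 threshold.  Topology is untouched."""
    if not (0.0 <= noise <= 1.0):
        raise ValidationError("noise level must be in [0, 1]")
    clone = GeneTree(
        _copy_root(gene_tree),
        gene_name=gene_tree.gene_name,
        copy_to_taxon=gene_tree.copy_to_taxon,
        rooting_state=gene_tree.rooting_state,
        outgroup=gene_tree.outgroup,
    )
    if noise == 0:
        return clone
    rng = np.random.default_rng(seed)
    for node in clone.postorder():
        if node.is_leaf:
            continue
        for attr in ("support_primary", "support_secondary"):
            value = getattr(node, attr)
            if value is None:
                continue
            degraded = (1.0 - noise) * value + noise * float(rng.uniform(0.0, 69.0))
            setattr(node, attr, degraded)
    return clone


def _copy_root(tree: Tree) -> Node:
    def rec(node: Node) -> Node:
        clone = Node(
            label=node.label,
            length=node.length,
            age=node.age,
            support_primary=node.support_primary,
            support_secondary=node.support_secondary,
        )
        for child in node.children:
            clone.add_child(rec(child))
        return clone

    return rec(tree.root)
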