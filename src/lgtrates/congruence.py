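"""Gene-tree vs reference-tree congruence assessment.

A gene clade is judged per the confirmation rule: bipartitions inside the
clade that are incompatible with the reference topology (restricted to the
same taxa) and supported at or above the threshold make it a
``supported_conflict``; a clade whose unrooted topology matches the
reference but whose basal split differs is an ``alternative_rooting``;
otherwise it is ``congruent``.  Clades with fewer than four shared taxa, or
with no support values at all on their internal branches, are
``unresolved``.  A branch counts as supported when EITHER support track
meets the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .trees import DatedTree, GeneTree, Node, Tree

__all__ = [
    "CladeAssessment",
    "induced_subtree",
    "tree_bipartitions",
    "bipartitions_compatible",
    "split_compatible_with_tree",
    "supported_conflicts",
    "alternative_rooting",
    "assess_clade",
]

VERDICTS = ("congruent", "supported_conflict", "alternative_rooting", "unresolved")


@dataclass
class CladeAssessment:
    gene_name: str
    clade_id: str
    taxa: frozenset[str]
    verdict: str
    conflicts: list[tuple[frozenset[str], float]] = field(default_factory=list)
    max_conflict_support: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")


# ---------------------------------------------------------------------------
# induced subtrees and bipartitions
# ---------------------------------------------------------------------------

def induced_subtree(ref: Tree, taxa: Iterable[str]) -> Tree:
    """Restriction of ``ref`` to ``taxa``: prune, then suppress degree-2 nodes.

    Node ages are carried over unchanged, so relative ages are preserved.
    """
    keep = frozenset(taxa)
    unknown = keep - frozenset(ref.leaf_labels())
    if unknown:
        raise ValidationError(f"unknown taxa: {sorted(unknown)}")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(
                    label=node.label, length=node.length, age=node.age,
                )
            return None
        kept_children = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            # suppress degree-2 node: splice child through, summing lengths
            child = kept_children[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None and child.length is None:
                child.length = node.length
            return child
        clone = Node(
            label=node.label,
            length=node.length,
            age=node.age,
            support_primary=node.support_primary,
            support_secondary=node.support_secondary,
        )
        for c in kept_children:
            clone.add_child(c)
        return clone

    root = build(ref.root)
    if root is None:
        raise ValidationError("restriction to empty taxon set")
    root.length = None
    return Tree(root)


def _canonical_split(
    side: frozenset[str], leafset: frozenset[str]
) -> frozenset[str] | None:
    """Canonicalise a split to the side NOT containing the lexicographic anchor.

    Returns None for trivial splits (a side with < 2 taxa).
    """
    other = leafset - side
    if len(side) < 2 or len(other) < 2:
        return None
    anchor = min(leafset)
    return side if anchor not in side else other


def tree_bipartitions(
    tree: Tree, relabel: dict[str, str] | None = None
) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each as its canonical side.

    ``relabel`` optionally maps leaf labels (e.g. copy ids -> taxa) before
    splitting; splits that place one taxon on both sides are dropped.
    """
    labels = [relabel.get(l, l) if relabel else l for l in tree.leaf_labels()]
    leafset = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        raw = tree.leafset(node)
        side = frozenset(relabel.get(l, l) if relabel else l for l in raw)
        other = leafset - side
        mapped_other = frozenset(
            relabel.get(l, l) if relabel else l
            for l in (frozenset(tree.leaf_labels()) - raw)
        )
        if side & mapped_other:
            continue  # a taxon with copies on both sides: unresolvable split
        canon = _canonical_split(side, leafset)
        if canon is not None:
            out.add(canon)
    return out


def bipartitions_compatible(
    split_a: frozenset[str], split_b: frozenset[str], leafset: frozenset[str]
) -> bool:
    """Two splits of ``leafset`` are compatible iff some pairwise side
    intersection is empty."""
    a1, a2 = split_a, leafset - split_a
    b1, b2 = split_b, leafset - split_b
    return not (a1 & b1) or not (a1 & b2) or not (a2 & b1) or not (a2 & b2)


def split_compatible_with_tree(
    split: frozenset[str], tree_splits: set[frozenset[str]], leafset: frozenset[str]
) -> bool:
    """A split is displayed jointly with a tree iff it is pairwise compatible
    with every split of the tree (splits of a tree form a compatible system)."""
    return all(bipartitions_compatible(split, s, leafset) for s in tree_splits)


# ---------------------------------------------------------------------------
# supported conflicts / alternative rooting / verdicts
# ---------------------------------------------------------------------------

def _support_of(node: Node) -> float | None:
    return node.support


def _gene_splits_with_support(
    tree: Tree, relabel: dict[str, str], shared: frozenset[str]
) -> list[tuple[frozenset[str], float | None]]:
    """Splits of a gene (sub)tree restricted to shared taxa, with supports."""
    out = []
    all_taxa = frozenset(relabel.get(l, l) for l in tree.leaf_labels())
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        raw = tree.leafset(node)
        side = frozenset(relabel.get(l, l) for l in raw) & shared
        other_raw = frozenset(tree.leaf_labels()) - raw
        other = frozenset(relabel.get(l, l) for l in other_raw) & shared
        if side & other:
            continue
        canon = _canonical_split(side, shared)
        if canon is None:
            continue
        out.append((canon, _support_of(node)))
    return out


def supported_conflicts(
    gene: GeneTree,
    ref: DatedTree,
    threshold: float = 70.0,
    subtree: Tree | None = None,
) -> list[tuple[frozenset[str], float]]:
    """Gene-tree bipartitions supported at >= threshold that are incompatible
    with the reference restricted to the shared taxa.

    ``subtree`` limits the test to a clade of the gene tree.
    """
    tree: Tree = subtree if subtree is not None else gene
    relabel = dict(gene.copy_to_taxon)
    gene_taxa = frozenset(
        relabel.get(l, l) for l in tree.leaf_labels() if l not in gene.outgroup
    )
    shared = gene_taxa & frozenset(ref.leaf_labels())
    if len(shared) < 4:
        return []
    ref_splits = tree_bipartitions(induced_subtree(ref, shared))
    conflicts = []
    for split, support in _gene_splits_with_support(tree, relabel, shared):
        if support is None or support < threshold:
            continue
        if not split_compatible_with_tree(split, ref_splits, shared):
            conflicts.append((split, support))
    conflicts.sort(key=lambda pair: (-pair[1], sorted(pair[0])))
    return conflicts


def _root_partition(tree: Tree, relabel: dict[str, str] | None = None) -> frozenset[frozenset[str]]:
    parts = []
    for child in tree.root.children:
        raw = tree.leafset(child)
        parts.append(
            frozenset(relabel.get(l, l) if relabel else l for l in raw)
        )
    return frozenset(parts)


def alternative_rooting(
    gene_clade: Tree,
    ref: DatedTree,
    relabel: dict[str, str] | None = None,
) -> bool:
    """True iff the clade is unrooted-compatible with the reference restricted
    to its taxa, but its rooted basal split differs from the reference's.

    The basal comparison is support-free: any difference in the root
    partition counts.
    """
    relabel = relabel or {}
    taxa = frozenset(relabel.get(l, l) for l in gene_clade.leaf_labels())
    if len(taxa) < 3:
        return False
    shared = taxa & frozenset(ref.leaf_labels())
    if len(shared) < 3:
        return False
    ref_sub = induced_subtree(ref, shared)
    ref_splits = tree_bipartitions(ref_sub)
    for split in tree_bipartitions(gene_clade, relabel=relabel):
        if not split_compatible_with_tree(split, ref_splits, shared):
            return False
    gene_parts = _root_partition(gene_clade, relabel)
    ref_parts = _root_partition(ref_sub)
    return gene_parts != ref_parts


def _clade_subtree(gene: GeneTree, copies: Iterable[str]) -> Tree:
    copies = frozenset(copies)
    unknown = copies - frozenset(gene.leaf_labels())
    if unknown:
        raise ValidationError(f"unknown gene copies: {sorted(unknown)}")
    node = gene.mrca(copies)
    return Tree(node)


def _has_any_support(tree: Tree) -> bool:
    return any(
        n.support is not None
        for n in tree.postorder()
        if not n.is_leaf and n.parent is not None
    )


def assess_clade(
    gene: GeneTree,
    ref: DatedTree,
    clade_id: str,
    copies: Iterable[str],
    threshold: float = 70.0,
) -> CladeAssessment:
    """Assess one gene-tree clade (a monophyletic group of in-domain copies).

    Verdict precedence: supported_conflict > alternative_rooting > congruent;
    unresolved when the clade has < 4 shared taxa or carries no support data.
    """
    subtree = _clade_subtree(gene, copies)
    relabel = dict(gene.copy_to_taxon)
    taxa = frozenset(
        relabel.get(l, l) for l in subtree.leaf_labels() if l not in gene.outgroup
    )
    shared = taxa & frozenset(ref.leaf_labels())
    flags: list[str] = []

    if len(shared) < 4:
        return CladeAssessment(
            gene_name=gene.gene_name,
            clade_id=clade_id,
            taxa=taxa,
            verdict="unresolved",
            flags=["fewer_than_4_shared_taxa"],
        )
    if not _has_any_support(subtree):
        return CladeAssessment(
            gene_name=gene.gene_name,
            clade_id=clade_id,
            taxa=taxa,
            verdict="unresolved",
            flags=["no_support_data"],
        )

    conflicts = supported_conflicts(gene, ref, threshold=threshold, subtree=subtree)
    if conflicts:
        return CladeAssessment(
            gene_name=gene.gene_name,
            clade_id=clade_id,
            taxa=taxa,
            verdict="supported_conflict",
            conflicts=conflicts,
            max_conflict_support=max(s for _, s in conflicts),
        )
    rootable = gene.rooting_state == "rooted" or bool(gene.outgroup)
    if rootable and alternative_rooting(subtree, ref, relabel=relabel):
        return CladeAssessment(
            gene_name=gene.gene_name,
            clade_id=clade_id,
            taxa=taxa,
            verdict="alternative_rooting",
        )
    # surface unsupported incompatibilities without promoting them
    all_splits = tree_bipartitions(subtree, relabel=relabel)
    ref_splits = tree_bipartitions(induced_subtree(ref, shared))
    unsupported = [
        s
        for s in all_splits
        if not split_compatible_with_tree(s, ref_splits, shared)
    ]
    if unsupported:
        flags.append("unsupported_incongruence")
    return CladeAssessment(
        gene_name=gene.gene_name,
        clade_id=clade_id,
        taxa=taxa,
        verdict="congruent",
        flags=flags,
    )
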