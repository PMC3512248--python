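"""Tree data model and I/O for reference trees, gene trees, and tabular inputs.

Trees are parsed with dendropy and converted into a small mutable node
structure that the rest of the package traverses directly.  Two Newick
support dialects are accepted: numeric internal-node labels (the common
"((A,B)97:1,C);" form, optionally "97/0.95" carrying two support tracks)
and bracketed node comments ("((A,B)[97]:1,C);").  When both are present
the node label wins.  Supports are normalised to the 0-100 percent scale:
any value in [0, 1] is multiplied by 100.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .errors import NewickParseError, ValidationError

__all__ = [
    "Node",
    "Tree",
    "DatedTree",
    "GeneTree",
    "PresenceMatrix",
    "LinkageRecord",
    "LinkageTable",
    "AgeConstraint",
    "AgeConstraintTable",
    "parse_tree",
    "write_tree",
    "normalize_supports",
    "read_presence_matrix",
    "read_linkage_table",
    "read_age_constraints",
]


class Node:
    """A node in a rooted tree.

    ``length`` is the branch length above this node (substitutions/site or
    any relative unit); ``age`` is the node's age in Ga before present.
    ``support_primary`` / ``support_secondary`` hold the two support tracks
    (e.g. parsimony bootstrap and Bayesian posterior), both on 0-100.
    """

    __slots__ = (
        "label",
        "length",
        "age",
        "support_primary",
        "support_secondary",
        "children",
        "parent",
    )

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        age: float | None = None,
        support_primary: float | None = None,
        support_secondary: float | None = None,
    ):
        self.label = label
        self.length = length
        self.age = age
        self.support_primary = support_primary
        self.support_secondary = support_secondary
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> float | None:
        """Effective support: max of the two tracks (either may be absent)."""
        vals = [v for v in (self.support_primary, self.support_secondary) if v is not None]
        return max(vals) if vals else None

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Node {self.label or '*'} n_children={len(self.children)}>"


class Tree:
    """A rooted tree with traversal helpers shared by DatedTree and GeneTree."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        def _walk(node: Node) -> Iterator[Node]:
            for child in node.children:
                yield from _walk(child)
            yield node

        return _walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def _walk(node: Node) -> Iterator[Node]:
            yield node
            for child in node.children:
                yield from _walk(child)

        return _walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def leafset(self, node: Node) -> frozenset[str]:
        """Labels of the leaves subtended by ``node``."""
        if node.is_leaf:
            return frozenset([node.label])
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def mrca(self, taxa: Iterable[str]) -> Node:
        want = frozenset(taxa)
        missing = want - frozenset(self.leaf_labels())
        if missing:
            raise ValidationError(f"unknown taxa: {sorted(missing)}")
        node = self.root
        while True:
            next_node = None
            for child in node.children:
                ls = self.leafset(child)
                if want <= ls:
                    next_node = child
                    break
            if next_node is None:
                return node
            node = next_node

    def copy(self) -> "Tree":
        return type(self)(_copy_subtree(self.root))

    def __len__(self) -> int:
        return len(self.leaves())


def _copy_subtree(node: Node) -> Node:
    clone = Node(
        label=node.label,
        length=node.length,
        age=node.age,
        support_primary=node.support_primary,
        support_secondary=node.support_secondary,
    )
    for child in node.children:
        clone.add_child(_copy_subtree(child))
    return clone


class DatedTree(Tree):
    """Reference ("genome") tree: optionally dated, with named clades.

    Invariants enforced on :meth:`validate`:

    * leaf labels unique;
    * supports within [0, 100];
    * when ages are present, every internal node is at least as old as each
      of its children.
    """

    def __init__(self, root: Node, clade_labels: Mapping[str, frozenset[str]] | None = None):
        super().__init__(root)
        self.clade_labels: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in (clade_labels or {}).items()
        }
        self.validate()

    def validate(self) -> None:
        labels = self.leaf_labels()
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.postorder():
            for s in (node.support_primary, node.support_secondary):
                if s is not None and not (0.0 <= s <= 100.0):
                    raise ValidationError(f"support {s} outside [0, 100]")
            if node.age is not None and node.age < 0:
                raise ValidationError(f"negative node age {node.age}")
            if node.age is not None:
                for child in node.children:
                    if child.age is not None and node.age < child.age - 1e-12:
                        raise ValidationError(
                            f"node age {node.age} younger than child age {child.age}"
                        )
        for name, taxa in self.clade_labels.items():
            missing = taxa - frozenset(labels)
            if missing:
                raise ValidationError(
                    f"clade label {name!r} references unknown taxa {sorted(missing)}"
                )

    @property
    def is_dated(self) -> bool:
        return all(n.age is not None for n in self.postorder() if not n.is_leaf)

    def set_ages_from_lengths(self) -> None:
        """Treat branch lengths as time and set ultrametric-style ages."""
        depth: dict[int, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = max(
                    depth[id(c)] + (c.length or 0.0) for c in node.children
                )
        for node in self.postorder():
            node.age = depth[id(node)]

    def branch_duration(self, node: Node) -> float | None:
        """Time elapsed along the branch above ``node`` (Ga), if dated."""
        if node.parent is None:
            return None
        if node.parent.age is None or node.age is None:
            return None
        return node.parent.age - node.age

    def resolve_clade(self, name: str) -> frozenset[str]:
        try:
            return self.clade_labels[name]
        except KeyError:
            raise ValidationError(f"unknown clade label {name!r}") from None


class GeneTree(Tree):
    """Per-gene tree over copy identifiers, with a copy -> taxon mapping."""

    def __init__(
        self,
        root: Node,
        gene_name: str = "",
        copy_to_taxon: Mapping[str, str] | None = None,
        rooting_state: str = "rooted",
        outgroup: frozenset[str] | None = None,
    ):
        super().__init__(root)
        self.gene_name = gene_name
        # default: copy identifiers ARE taxon labels
        self.copy_to_taxon: dict[str, str] = dict(
            copy_to_taxon or {l: l for l in self.leaf_labels()}
        )
        if rooting_state not in ("rooted", "unrooted"):
            raise ValidationError(f"bad rooting_state {rooting_state!r}")
        self.rooting_state = rooting_state
        self.outgroup: frozenset[str] = frozenset(outgroup or ())
        self.validate()

    def validate(self) -> None:
        for node in self.postorder():
            for s in (node.support_primary, node.support_secondary):
                if s is not None and not (0.0 <= s <= 100.0):
                    raise ValidationError(f"support {s} outside [0, 100]")
        unmapped = set(self.leaf_labels()) - set(self.copy_to_taxon) - self.outgroup
        if unmapped:
            raise ValidationError(
                f"gene tree copies with no taxon mapping: {sorted(unmapped)}"
            )

    def taxa_of(self, copies: Iterable[str]) -> frozenset[str]:
        return frozenset(self.copy_to_taxon[c] for c in copies if c in self.copy_to_taxon)

    def validate_against(self, reference: DatedTree) -> None:
        ref_taxa = frozenset(reference.leaf_labels())
        bad = {
            t
            for c, t in self.copy_to_taxon.items()
            if t not in ref_taxa and c not in self.outgroup
        }
        if bad:
            raise ValidationError(
                f"gene {self.gene_name!r}: copies map to taxa absent from the "
                f"reference tree: {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_SUPPORT_PAIR_RE = re.compile(
    r"^([+-]?(?:\d+\.?\d*|\.\d+))/([+-]?(?:\d+\.?\d*|\.\d+))$"
)


def normalize_supports(tree: "Tree") -> "Tree":
    """Rescale fraction-scale support tracks onto 0-100, in place.

    Each track (primary/secondary) is judged across the whole tree: if every
    value on a track lies in [0, 1] (and at least one exceeds 0.01, so a
    rescaled track is never mistaken for fractions again) the track is
    multiplied by 100.  Idempotent.
    """
    for attr in ("support_primary", "support_secondary"):
        values = [
            getattr(n, attr) for n in tree.postorder() if getattr(n, attr) is not None
        ]
        if values and max(values) <= 1.0 and max(values) > 0.01:
            for node in tree.postorder():
                value = getattr(node, attr)
                if value is not None:
                    setattr(node, attr, value * 100.0)
    return tree


def _extract_supports(raw: str) -> tuple[float, float | None] | None:
    """Parse a node label into raw (primary, secondary) supports, or None."""
    m = _SUPPORT_PAIR_RE.match(raw)
    if m:
        return float(m.group(1)), float(m.group(2))
    if _NUMERIC_RE.match(raw):
        return float(raw), None
    return None


def _comment_support(comments: Sequence[str]) -> tuple[float, float | None] | None:
    for comment in comments:
        text = comment.strip().lstrip("&")
        if text.startswith("support="):
            text = text[len("support=") :]
        got = _extract_supports(text)
        if got is not None:
            return got
    return None


def parse_tree(
    text: str,
    support_convention: str = "auto",
    kind: str = "dated",
    gene_name: str = "",
    copy_to_taxon: Mapping[str, str] | None = None,
    clade_labels: Mapping[str, frozenset[str]] | None = None,
    rooting_state: str = "rooted",
    outgroup: Iterable[str] | None = None,
) -> DatedTree | GeneTree:
    """Parse a Newick string into a :class:`DatedTree` or :class:`GeneTree`.

    ``support_convention`` is one of ``branch_label``, ``node_comment`` or
    ``auto`` (both accepted, node label taking precedence).
    """
    if support_convention not in ("auto", "branch_label", "node_comment"):
        raise ValueError(f"bad support_convention {support_convention!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        offset = getattr(exc, "column_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from exc

    def convert(dnode) -> Node:
        node = Node()
        if dnode.taxon is not None:
            node.label = dnode.taxon.label
        elif dnode.label is not None:
            node.label = dnode.label
        node.length = dnode.edge.length
        if not dnode.is_leaf():
            supports = None
            if support_convention in ("auto", "branch_label") and dnode.label:
                supports = _extract_supports(dnode.label)
                if supports is not None:
                    node.label = None
            if supports is None and support_convention in ("auto", "node_comment"):
                supports = _comment_support(dnode.comments or [])
            if supports is not None:
                node.support_primary, node.support_secondary = supports
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    normalize_supports(Tree(root))
    if kind == "dated":
        return DatedTree(root, clade_labels=clade_labels)
    if kind == "gene":
        return GeneTree(
            root,
            gene_name=gene_name,
            copy_to_taxon=copy_to_taxon,
            rooting_state=rooting_state,
            outgroup=frozenset(outgroup or ()),
        )
    raise ValueError(f"bad kind {kind!r}")


def _fmt_num(value: float) -> str:
    out = f"{value:.12g}"
    return out


def _node_to_newick(node: Node) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        inner = ",".join(_node_to_newick(c) for c in node.children)
        if node.support_primary is not None and node.support_secondary is not None:
            label = f"{_fmt_num(node.support_primary)}/{_fmt_num(node.support_secondary)}"
        elif node.support_primary is not None:
            label = _fmt_num(node.support_primary)
        else:
            label = node.label or ""
        body = f"({inner}){label}"
    if node.length is not None:
        body += f":{_fmt_num(node.length)}"
    return body


def write_tree(tree: Tree) -> str:
    """Serialise a tree to Newick; inverse of :func:`parse_tree`."""
    return _node_to_newick(tree.root) + ";"


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Taxon x gene binary matrix. Row/column order is preserved from input."""

    taxa: list[str]
    genes: list[str]
    cells: "pd.DataFrame"

    def __post_init__(self):
        for gene in self.genes:
            col = self.cells[gene]
            bad = col[~col.isin((0, 1))]
            if len(bad):
                row = bad.index[0]
                raise ValidationError(
                    f"non-binary cell at taxon {row!r}, gene {gene!r}: {bad.iloc[0]!r}"
                )

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, int]]) -> "PresenceMatrix":
        """Build from {gene: {taxon: 0/1}}; missing cells default to 0."""
        genes = list(data)
        taxa: list[str] = []
        for gene in genes:
            for taxon in data[gene]:
                if taxon not in taxa:
                    taxa.append(taxon)
        frame = pd.DataFrame(0, index=taxa, columns=genes, dtype=int)
        for gene in genes:
            for taxon, value in data[gene].items():
                frame.loc[taxon, gene] = int(value)
        return cls(taxa=taxa, genes=genes, cells=frame)

    def states(self, gene: str, taxa: Iterable[str] | None = None) -> dict[str, int]:
        if gene not in self.genes:
            raise ValidationError(f"unknown gene {gene!r}")
        col = self.cells[gene]
        use = list(taxa) if taxa is not None else self.taxa
        return {t: int(col[t]) for t in use}

    def carriers(self, gene: str) -> frozenset[str]:
        return frozenset(t for t, v in self.states(gene).items() if v == 1)

    def check_against(self, reference: DatedTree, allow_missing: Iterable[str] = ()):
        ref = frozenset(reference.leaf_labels())
        allowed = frozenset(allow_missing)
        extra = frozenset(self.taxa) - ref
        if extra:
            raise ValidationError(f"matrix taxa absent from reference tree: {sorted(extra)}")
        missing = ref - frozenset(self.taxa) - allowed
        if missing:
            raise ValidationError(
                f"reference taxa missing from matrix (not declared): {sorted(missing)}"
            )


def _read_delimited(path_or_buffer, **kwargs) -> pd.DataFrame:
    """Read TSV (default) falling back to comma-separated."""
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r") as fh:
            text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else "," if text.strip() else "\t"
    return pd.read_csv(io.StringIO(text), sep=sep, **kwargs)


def read_presence_matrix(path) -> PresenceMatrix:
    """Read a taxon x gene matrix; first column holds taxon labels."""
    frame = _read_delimited(path, index_col=0)
    frame.index = frame.index.map(str)
    genes = [str(c) for c in frame.columns]
    frame.columns = genes
    for gene in genes:
        col = frame[gene]
        for taxon, value in col.items():
            if value not in (0, 1):
                raise ValidationError(
                    f"non-binary cell at taxon {taxon!r}, gene {gene!r}: {value!r}"
                )
    return PresenceMatrix(taxa=list(frame.index), genes=genes, cells=frame.astype(int))


# ---------------------------------------------------------------------------
# Linkage table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageRecord:
    taxon: str
    copy_a: str
    copy_b: str
    gap_orfs: int = 0

    def __post_init__(self):
        if self.gap_orfs < 0:
            raise ValidationError(f"negative gap_orfs {self.gap_orfs}")

    def canonical(self) -> "LinkageRecord":
        a, b = sorted((self.copy_a, self.copy_b))
        return LinkageRecord(self.taxon, a, b, self.gap_orfs)


class LinkageTable:
    """Declared genomic adjacencies among gene copies, symmetric and deduplicated."""

    def __init__(self, records: Iterable[LinkageRecord] = ()):
        seen: dict[tuple[str, str, str], LinkageRecord] = {}
        for rec in records:
            canon = rec.canonical()
            key = (canon.taxon, canon.copy_a, canon.copy_b)
            prev = seen.get(key)
            if prev is None or canon.gap_orfs < prev.gap_orfs:
                seen[key] = canon
        self.records: list[LinkageRecord] = sorted(
            seen.values(), key=lambda r: (r.taxon, r.copy_a, r.copy_b)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LinkageRecord]:
        return iter(self.records)

    def linked(
        self,
        copies_a: Iterable[str],
        copies_b: Iterable[str],
        max_gap_orfs: int = 1,
        within_taxa: Iterable[str] | None = None,
    ) -> bool:
        """True if some record joins a copy from each group with gap <= max_gap_orfs.

        ``within_taxa`` restricts the search to records observed in those taxa
        (the recipient clade, when merging transfer events).
        """
        set_a, set_b = frozenset(copies_a), frozenset(copies_b)
        allowed = frozenset(within_taxa) if within_taxa is not None else None
        for rec in self.records:
            if rec.gap_orfs > max_gap_orfs:
                continue
            if allowed is not None and rec.taxon not in allowed:
                continue
            if (rec.copy_a in set_a and rec.copy_b in set_b) or (
                rec.copy_a in set_b and rec.copy_b in set_a
            ):
                return True
        return False

    def validate_copies(self, known_copies: Iterable[str]) -> None:
        known = frozenset(known_copies)
        for rec in self.records:
            for copy_id in (rec.copy_a, rec.copy_b):
                if copy_id not in known:
                    raise ValidationError(f"linkage references unknown copy {copy_id!r}")


def read_linkage_table(path) -> LinkageTable:
    """Read a linkage table: columns taxon, copy_a, copy_b, gap_orfs."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r") as fh:
            text = fh.read()
    if not text.strip():
        return LinkageTable()
    frame = _read_delimited(io.StringIO(text))
    required = {"taxon", "copy_a", "copy_b"}
    if not required <= set(frame.columns):
        raise ValidationError(
            f"linkage table must have columns {sorted(required)}; got {list(frame.columns)}"
        )
    records = []
    for _, row in frame.iterrows():
        gap = int(row["gap_orfs"]) if "gap_orfs" in frame.columns and not pd.isna(row.get("gap_orfs")) else 0
        records.append(LinkageRecord(str(row["taxon"]), str(row["copy_a"]), str(row["copy_b"]), gap))
    return LinkageTable(records)


# ---------------------------------------------------------------------------
# Age constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeConstraint:
    clade_name: str
    min_age: float | None = None  # Ga
    max_age: float | None = None  # Ga

    def __post_init__(self):
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValidationError(
                f"constraint on {self.clade_name!r}: min {self.min_age} > max {self.max_age}"
            )


class AgeConstraintTable:
    def __init__(self, records: Iterable[AgeConstraint] = ()):
        self.records: list[AgeConstraint] = list(records)

    def __iter__(self) -> Iterator[AgeConstraint]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_age_constraints(path) -> AgeConstraintTable:
    """Read constraints: columns clade_name, min_age, max_age (Ga; blanks allowed)."""
    frame = _read_delimited(path)
    records = []
    for _, row in frame.iterrows():
        min_age = None if pd.isna(row.get("min_age")) else float(row["min_age"])
        max_age = None if pd.isna(row.get("max_age")) else float(row["max_age"])
        records.append(AgeConstraint(str(row["clade_name"]), min_age, max_age))
    return AgeConstraintTable(records)
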