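"""Configuration-driven orchestration and summary-table emission.

``run_pipeline`` wires the stages together for a YAML-described input
bundle: per-gene ancestral-state reconstruction proposes candidate gains,
gene-tree clades subtended by those gains are assessed against the
reference, events are collapsed over genomic linkage, duplication flags
yield min/max counts, and the result is summarised per category (plus
group totals) with rates over the domain age.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .asr import GainEdge, candidate_gain_edges, fit_q, marginal_asr
from .congruence import CladeAssessment, assess_clade
from .errors import ValidationError
from .events import (
    DuplicationFlag,
    TransferEventSet,
    apply_duplication_flags,
    collapse_linked,
    propose_events,
    transfer_rate,
)
from .trees import (
    DatedTree,
    GeneTree,
    LinkageTable,
    PresenceMatrix,
    parse_tree,
    read_linkage_table,
    read_presence_matrix,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "detect_events",
    "run_pipeline",
    "write_summary",
    "render_count",
]


@dataclass
class PipelineConfig:
    reference_tree: str
    presence_matrix: str
    gene_trees: dict[str, str] = field(default_factory=dict)  # gene -> newick path
    linkage: str | None = None
    flags: list[DuplicationFlag] = field(default_factory=list)
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    support_threshold: float = 70.0
    present_threshold: float = 0.7
    absent_threshold: float = 0.3
    max_gap_orfs: int = 1
    domain_age: float = 3.5
    admit_taxonomic_restriction: bool = True
    seed: int = 1
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.get("thresholds", {})
        flags = [
            DuplicationFlag(
                gene=f["gene"], family=f["family"], anchor=bool(f.get("anchor", False))
            )
            for f in raw.get("flags", [])
        ]
        config = cls(
            reference_tree=raw["reference_tree"],
            presence_matrix=raw["presence_matrix"],
            gene_trees={k: v for k, v in (raw.get("gene_trees") or {}).items()},
            linkage=raw.get("linkage"),
            flags=flags,
            categories={k: tuple(v) for k, v in (raw.get("categories") or {}).items()},
            groups={k: tuple(v) for k, v in (raw.get("groups") or {}).items()},
            support_threshold=float(thresholds.get("support", 70.0)),
            present_threshold=float(thresholds.get("present", 0.7)),
            absent_threshold=float(thresholds.get("absent", 0.3)),
            max_gap_orfs=int(thresholds.get("max_gap_orfs", 1)),
            domain_age=float(raw.get("domain_age", 3.5)),
            admit_taxonomic_restriction=bool(raw.get("admit_taxonomic_restriction", True)),
            seed=int(raw.get("seed", 1)),
            base_dir=path.parent,
        )
        config.validate_paths()
        return config

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def validate_paths(self) -> None:
        paths = [self.reference_tree, self.presence_matrix]
        paths += list(self.gene_trees.values())
        if self.linkage:
            paths.append(self.linkage)
        for p in paths:
            if not self.resolve(p).exists():
                raise ValidationError(f"configured input does not exist: {p}")


@dataclass
class PipelineResult:
    event_set: TransferEventSet
    summary: pd.DataFrame
    events_frame: pd.DataFrame
    logs: list[str]


def _gene_clades_from_gains(
    gene_tree: GeneTree, gains: Sequence[GainEdge]
) -> list[tuple[str, list[str]]]:
    """For each gain edge, the copies it subtends if they are monophyletic."""
    clades = []
    for i, gain in enumerate(gains, start=1):
        copies = [
            c
            for c in gene_tree.leaf_labels()
            if gene_tree.copy_to_taxon.get(c, c) in gain.child_taxa
        ]
        if not copies:
            continue
        mrca_taxa = gene_tree.taxa_of(gene_tree.leafset(gene_tree.mrca(copies)))
        if mrca_taxa <= gain.child_taxa:
            clades.append((f"{gene_tree.gene_name}_gain{i}", copies))
    return clades


def detect_events(
    ref: DatedTree,
    presence: PresenceMatrix,
    gene_trees: Mapping[str, GeneTree],
    linkage: LinkageTable | None = None,
    support_threshold: float = 70.0,
    present_threshold: float = 0.7,
    absent_threshold: float = 0.3,
    max_gap_orfs: int = 1,
    admit_taxonomic_restriction: bool = True,
    domain_age: float = 3.5,
    logs: list[str] | None = None,
) -> TransferEventSet:
    """Run ASR + congruence + linkage collapsing over a full input bundle."""
    linkage = linkage or LinkageTable()
    logs = logs if logs is not None else []
    gains: dict[str, list[GainEdge]] = {}
    assessments: dict[str, list[CladeAssessment]] = {}
    for gene in presence.genes:
        tips = presence.states(gene, ref.leaf_labels())
        if all(v == 0 for v in tips.values()):
            logs.append(f"{gene}: absent everywhere, skipped")
            continue
        fit = fit_q(ref, tips)
        asr = marginal_asr(
            ref,
            tips,
            fit.model,
            present_threshold=present_threshold,
            absent_threshold=absent_threshold,
        )
        edges = candidate_gain_edges(ref, asr)
        gains[gene] = edges
        logs.append(f"{gene}: q_hat={fit.model.q:.4g}, {len(edges)} candidate gain edge(s)")
        tree = gene_trees.get(gene)
        if tree is None:
            continue
        tree.validate_against(ref)
        gene_assessments = []
        for clade_id, copies in _gene_clades_from_gains(tree, edges):
            assessment = assess_clade(tree, ref, clade_id, copies, threshold=support_threshold)
            gene_assessments.append(assessment)
            logs.append(f"{gene}/{clade_id}: verdict={assessment.verdict}")
        assessments[gene] = gene_assessments
    raw = propose_events(
        gains,
        assessments,
        domain_taxa=frozenset(ref.leaf_labels()),
        admit_taxonomic_restriction=admit_taxonomic_restriction,
    )
    logs.append(f"{len(raw)} raw event(s) proposed")
    event_set = collapse_linked(raw, linkage, max_gap_orfs=max_gap_orfs, domain_age=domain_age)
    logs.append(f"{len(event_set.events)} event(s) after linkage collapsing")
    return event_set


def render_count(n_min: int, n_max: int) -> str:
    return str(n_min) if n_min == n_max else f"{n_min}-{n_max}"


def _render_rate(n_min: int, n_max: int, domain_age: float) -> str:
    lo, hi = transfer_rate(n_min, domain_age), transfer_rate(n_max, domain_age)
    return f"{lo:.1f}" if n_min == n_max else f"{lo:.1f}-{hi:.1f}"


def write_summary(
    event_set: TransferEventSet,
    categories: Mapping[str, Sequence[str]],
    groups: Mapping[str, Sequence[str]] | None = None,
    domain_age: float | None = None,
) -> pd.DataFrame:
    """Per-category min/max counts and rates, with group total rows.

    Group totals are asserted to equal the sum of their member rows.
    """
    domain_age = domain_age if domain_age is not None else event_set.domain_age
    rows = []
    per_category: dict[str, tuple[int, int]] = {}
    for category, genes in categories.items():
        n_min = event_set.min_count(genes)
        n_max = event_set.max_count(genes)
        per_category[category] = (n_min, n_max)
        rows.append(
            {
                "category": category,
                "n_min": n_min,
                "n_max": n_max,
                "events": render_count(n_min, n_max),
                "rate_min": transfer_rate(n_min, domain_age),
                "rate_max": transfer_rate(n_max, domain_age),
                "rate": _render_rate(n_min, n_max, domain_age),
            }
        )
    for group, members in (groups or {}).items():
        unknown = [m for m in members if m not in per_category]
        if unknown:
            raise ValidationError(f"group {group!r} references unknown categories {unknown}")
        n_min = sum(per_category[m][0] for m in members)
        n_max = sum(per_category[m][1] for m in members)
        assert n_min == sum(per_category[m][0] for m in members)
        rows.append(
            {
                "category": group,
                "n_min": n_min,
                "n_max": n_max,
                "events": render_count(n_min, n_max),
                "rate_min": transfer_rate(n_min, domain_age),
                "rate_max": transfer_rate(n_max, domain_age),
                "rate": _render_rate(n_min, n_max, domain_age),
            }
        )
    return pd.DataFrame(rows)


def events_frame(event_set: TransferEventSet) -> pd.DataFrame:
    rows = []
    for event in event_set.events:
        rows.append(
            {
                "event_id": event.event_id,
                "genes": ";".join(sorted(event.gene_group)),
                "recipient": ";".join(sorted(event.recipient)),
                "evidence": event.evidence,
                "ambiguity": event.ambiguity,
                "family": event.duplication_family or "",
                "confirmed": int(event.confirmed),
                "age_lo": "" if event.age_lo is None else event.age_lo,
                "age_hi": "" if event.age_hi is None else event.age_hi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "genes", "recipient", "evidence", "ambiguity",
            "family", "confirmed", "age_lo", "age_hi",
        ],
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the detection pipeline described by ``config``."""
    logs: list[str] = [f"seed={config.seed}"]
    with open(config.resolve(config.reference_tree)) as fh:
        ref = parse_tree(fh.read(), kind="dated")
    if not ref.is_dated:
        ref.set_ages_from_lengths()
    presence = read_presence_matrix(config.resolve(config.presence_matrix))
    gene_trees: dict[str, GeneTree] = {}
    for gene, rel in config.gene_trees.items():
        with open(config.resolve(rel)) as fh:
            gene_trees[gene] = parse_tree(fh.read(), kind="gene", gene_name=gene)
    linkage = (
        read_linkage_table(config.resolve(config.linkage))
        if config.linkage
        else LinkageTable()
    )
    event_set = detect_events(
        ref,
        presence,
        gene_trees,
        linkage,
        support_threshold=config.support_threshold,
        present_threshold=config.present_threshold,
        absent_threshold=config.absent_threshold,
        max_gap_orfs=config.max_gap_orfs,
        admit_taxonomic_restriction=config.admit_taxonomic_restriction,
        domain_age=config.domain_age,
        logs=logs,
    )
    if config.flags:
        event_set = apply_duplication_flags(event_set, config.flags)
        logs.append(f"{len(config.flags)} duplication flag(s) applied")
    categories = config.categories or {"all genes": tuple(presence.genes)}
    uncovered = set(presence.genes) - {g for genes in categories.values() for g in genes}
    if uncovered:
        logs.append(f"warning: genes not covered by any category: {sorted(uncovered)}")
    summary = write_summary(event_set, categories, config.groups, config.domain_age)
    return PipelineResult(
        event_set=event_set,
        summary=summary,
        events_frame=events_frame(event_set),
        logs=logs,
    )
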