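"""From candidate gains + clade assessments + linkage to transfer events.

The pipeline is: :func:`propose_events` pairs each ancestral-state gain edge
with an assessed gene-tree clade it subtends; :func:`collapse_linked` merges
events whose genes are genomically adjacent in the recipient (one transfer
moved the whole cluster); :func:`apply_duplication_flags` turns
possible-duplication families into min/max counts; :func:`transfer_rate`
converts counts into events per billion years over the domain's age span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .asr import GainEdge
from .congruence import CladeAssessment
from .dating import Chronogram
from .errors import ValidationError
from .trees import DatedTree, LinkageTable

__all__ = [
    "TransferEvent",
    "TransferEventSet",
    "DuplicationFlag",
    "propose_events",
    "collapse_linked",
    "apply_duplication_flags",
    "date_events",
    "transfer_rate",
]

EVIDENCE_KINDS = (
    "asr_gain",
    "supported_conflict",
    "alternative_rooting",
    "taxonomic_restriction",
)


@dataclass
class TransferEvent:
    event_id: str
    gene_group: frozenset[str]
    recipient: frozenset[str]
    evidence: str
    ambiguity: str = "firm"  # firm | possible_duplication
    duplication_family: str | None = None
    confirmed: bool = True  # False: ASR-only evidence, reported separately
    age_lo: float | None = None  # Ga, recipient crown age
    age_hi: float | None = None  # Ga, recipient stem parent age

    def __post_init__(self):
        if not self.gene_group:
            raise ValidationError("event with empty gene group")
        if self.evidence not in EVIDENCE_KINDS:
            raise ValidationError(f"unknown evidence kind {self.evidence!r}")
        if self.ambiguity not in ("firm", "possible_duplication"):
            raise ValidationError(f"unknown ambiguity {self.ambiguity!r}")


@dataclass
class TransferEventSet:
    events: list[TransferEvent] = field(default_factory=list)
    domain_age: float = 3.5  # Gy

    def confirmed_events(self) -> list[TransferEvent]:
        return [e for e in self.events if e.confirmed]

    def unconfirmed_events(self) -> list[TransferEvent]:
        return [e for e in self.events if not e.confirmed]

    def _min_counted(self, events: Sequence[TransferEvent]) -> list[TransferEvent]:
        """Events contributing to the minimum: firm ones, plus one promoted
        member of any duplication family with no firm member."""
        out = [e for e in events if e.ambiguity == "firm"]
        families: dict[str, list[TransferEvent]] = {}
        for e in events:
            if e.ambiguity == "possible_duplication" and e.duplication_family:
                families.setdefault(e.duplication_family, []).append(e)
        firm_families = {
            e.duplication_family
            for e in events
            if e.ambiguity == "firm" and e.duplication_family
        }
        for family, members in sorted(families.items()):
            if family not in firm_families:
                out.append(sorted(members, key=lambda e: e.event_id)[0])
        return out

    def min_count(self, genes: Iterable[str] | None = None) -> int:
        return len(self._min_counted(self._select(genes)))

    def max_count(self, genes: Iterable[str] | None = None) -> int:
        return len(self._select(genes))

    def _select(self, genes: Iterable[str] | None) -> list[TransferEvent]:
        events = self.confirmed_events()
        if genes is None:
            return events
        wanted = frozenset(genes)
        return [e for e in events if e.gene_group & wanted]


@dataclass(frozen=True)
class DuplicationFlag:
    """Marks the event carrying ``gene`` as a possible duplication within a
    named sister-clade family.

    An ``anchor`` flag places the event in the family without questioning it:
    the firm member the flagged copies may be duplicates of.
    """

    gene: str
    family: str
    anchor: bool = False


def _match_gain(gains: Sequence[GainEdge], clade_taxa: frozenset[str]) -> GainEdge | None:
    """The tightest gain edge subtending the clade, if any."""
    covering = [g for g in gains if clade_taxa <= g.child_taxa]
    if not covering:
        return None
    return min(covering, key=lambda g: len(g.child_taxa))


def propose_events(
    gains: Mapping[str, Sequence[GainEdge]],
    assessments: Mapping[str, Sequence[CladeAssessment]],
    domain_taxa: frozenset[str],
    admit_taxonomic_restriction: bool = True,
) -> list[TransferEvent]:
    """One raw event per (gene, clade) with a subtending gain edge and a
    transfer-compatible verdict.

    Verdict handling: ``supported_conflict`` and ``alternative_rooting`` are
    direct evidence; ``congruent`` or ``unresolved`` clades qualify as
    ``taxonomic_restriction`` evidence when the trait does not span the whole
    domain (configurable off).  Gain edges matching no assessed clade are
    emitted as unconfirmed ``asr_gain`` events.
    """
    events: list[TransferEvent] = []
    counter = 0
    genes = sorted(set(gains) | set(assessments))
    for gene in genes:
        gene_gains = list(gains.get(gene, ()))
        matched: set[int] = set()
        for assessment in assessments.get(gene, ()):
            gain = _match_gain(gene_gains, assessment.taxa)
            if gain is None:
                continue
            matched.add(id(gain))
            if assessment.verdict in ("supported_conflict", "alternative_rooting"):
                evidence = assessment.verdict
            elif assessment.verdict in ("congruent", "unresolved"):
                if not admit_taxonomic_restriction:
                    continue
                if assessment.taxa >= domain_taxa:
                    continue  # trait spans the domain: no transfer implied
                evidence = "taxonomic_restriction"
            else:  # pragma: no cover - exhaustive verdicts
                continue
            counter += 1
            events.append(
                TransferEvent(
                    event_id=f"E{counter:03d}",
                    gene_group=frozenset([gene]),
                    recipient=assessment.taxa,
                    evidence=evidence,
                )
            )
        for gain in gene_gains:
            if id(gain) in matched:
                continue
            if any(gain.child_taxa < e.recipient and gene in e.gene_group for e in events):
                continue
            counter += 1
            events.append(
                TransferEvent(
                    event_id=f"E{counter:03d}",
                    gene_group=frozenset([gene]),
                    recipient=gain.child_taxa,
                    evidence="asr_gain",
                    confirmed=False,
                )
            )
    return events


def collapse_linked(
    events: Iterable[TransferEvent],
    linkage: LinkageTable,
    max_gap_orfs: int = 1,
    domain_age: float = 3.5,
) -> TransferEventSet:
    """Merge events of different genes with identical recipient clades when
    some taxon shows their copies genomically linked (gap <= max_gap_orfs).

    Merging is transitive (union-find); the count never increases and the
    result is invariant to the input event order.
    """
    events = sorted(events, key=lambda e: (sorted(e.recipient), sorted(e.gene_group)))
    parent = list(range(len(events)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            a, b = events[i], events[j]
            if a.recipient != b.recipient or a.confirmed != b.confirmed:
                continue
            if linkage.linked(
                a.gene_group, b.gene_group, max_gap_orfs, within_taxa=a.recipient
            ):
                union(i, j)

    groups: dict[int, list[TransferEvent]] = {}
    for i in range(len(events)):
        groups.setdefault(find(i), []).append(events[i])

    _EVIDENCE_RANK = {
        "supported_conflict": 0,
        "alternative_rooting": 1,
        "taxonomic_restriction": 2,
        "asr_gain": 3,
    }
    merged: list[TransferEvent] = []
    for members in groups.values():
        members = sorted(members, key=lambda e: sorted(e.gene_group))
        gene_group = frozenset().union(*(e.gene_group for e in members))
        evidence = min((e.evidence for e in members), key=_EVIDENCE_RANK.__getitem__)
        ambiguity = (
            "possible_duplication"
            if all(e.ambiguity == "possible_duplication" for e in members)
            else "firm"
        )
        family = next((e.duplication_family for e in members if e.duplication_family), None)
        merged.append(
            TransferEvent(
                event_id="",
                gene_group=gene_group,
                recipient=members[0].recipient,
                evidence=evidence,
                ambiguity=ambiguity,
                duplication_family=family,
                confirmed=members[0].confirmed,
            )
        )
    merged.sort(key=lambda e: (sorted(e.recipient), sorted(e.gene_group)))
    for i, event in enumerate(merged, start=1):
        event.event_id = f"E{i:03d}"
    return TransferEventSet(events=merged, domain_age=domain_age)


def apply_duplication_flags(
    event_set: TransferEventSet, flags: Iterable[DuplicationFlag]
) -> TransferEventSet:
    """Mark flagged events ``possible_duplication`` within their families.

    Flagged events count only toward the maximum; a family with no firm
    member still contributes one event to the minimum.
    """
    events = [replace(e) for e in event_set.events]
    for flag in flags:
        hits = [e for e in events if flag.gene in e.gene_group]
        if not hits:
            raise ValidationError(f"duplication flag on unknown gene {flag.gene!r}")
        for event in hits:
            event.duplication_family = flag.family
            if not flag.anchor:
                event.ambiguity = "possible_duplication"
    return TransferEventSet(events=events, domain_age=event_set.domain_age)


def date_events(event_set: TransferEventSet, chronogram: Chronogram) -> TransferEventSet:
    """Attach [crown age, stem parent age] intervals (Ga) to each event."""
    tree = chronogram.tree
    ref_taxa = frozenset(tree.leaf_labels())
    events = []
    for event in event_set.events:
        clade = event.recipient & ref_taxa
        if not clade:
            raise ValidationError(
                f"event {event.event_id}: recipient not on the chronogram"
            )
        node = tree.mrca(clade)
        if tree.leafset(node) != frozenset(clade):
            raise ValidationError(
                f"event {event.event_id}: recipient clade not monophyletic "
                f"in reference tree (taxa {sorted(clade)})"
            )
        lo = node.age if node.age is not None else 0.0
        hi = node.parent.age if node.parent is not None else node.age
        events.append(replace(event, age_lo=lo, age_hi=hi))
    return TransferEventSet(events=events, domain_age=event_set.domain_age)


def transfer_rate(n_events: int, domain_age: float = 3.5) -> float:
    """Events per Gy, rounded half-away-from-zero to one decimal."""
    if domain_age <= 0:
        raise ValidationError(f"domain age must be positive, got {domain_age}")
    if n_events < 0:
        raise ValidationError(f"negative event count {n_events}")
    value = n_events / domain_age
    return math.floor(value * 10 + 0.5) / 10
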