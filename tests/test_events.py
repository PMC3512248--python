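import random

import pytest

from lgtrates.asr import GainEdge
from lgtrates.congruence import CladeAssessment
from lgtrates.dating import Chronogram
from lgtrates.errors import ValidationError
from lgtrates.events import (
    DuplicationFlag,
    TransferEvent,
    TransferEventSet,
    apply_duplication_flags,
    collapse_linked,
    date_events,
    propose_events,
    transfer_rate,
)
from lgtrates.trees import LinkageRecord, LinkageTable
from lgtrates import datasets


def _gain(taxa):
    return GainEdge(
        parent_taxa=frozenset(), child_taxa=frozenset(taxa), parent_p1=0.0, child_p1=1.0
    )


def _assessment(gene, clade_id, taxa, verdict):
    return CladeAssessment(
        gene_name=gene, clade_id=clade_id, taxa=frozenset(taxa), verdict=verdict
    )


DOMAIN = frozenset("ABCDEFGH")


class TestProposeEvents:
    def test_trait_everywhere_no_events(self):
        # congruent clade spanning the domain, no gain edge: nothing proposed
        events = propose_events(
            {"g": []},
            {"g": [_assessment("g", "c", DOMAIN, "congruent")]},
            DOMAIN,
        )
        assert events == []

    def test_domain_spanning_congruent_clade_excluded_even_with_gain(self):
        events = propose_events(
            {"g": [_gain(DOMAIN)]},
            {"g": [_assessment("g", "c", DOMAIN, "congruent")]},
            DOMAIN,
        )
        assert [e for e in events if e.confirmed] == []

    def test_two_restricted_clades_two_events(self):
        # two disjoint clades, each under its own gain: 2 raw events
        gains = {"SOR": [_gain({"A", "B"}), _gain({"E", "F", "G"})]}
        assessments = {
            "SOR": [
                _assessment("SOR", "c1", {"A", "B"}, "unresolved"),
                _assessment("SOR", "c2", {"E", "F", "G"}, "congruent"),
            ]
        }
        events = propose_events(gains, assessments, DOMAIN)
        assert len(events) == 2
        assert all(e.confirmed for e in events)
        assert {e.evidence for e in events} == {"taxonomic_restriction"}

    def test_conflict_and_rooting_evidence_kinds(self):
        gains = {"g": [_gain({"A", "B", "C"}), _gain({"E", "F"})]}
        assessments = {
            "g": [
                _assessment("g", "c1", {"A", "B", "C"}, "supported_conflict"),
                _assessment("g", "c2", {"E", "F"}, "alternative_rooting"),
            ]
        }
        events = propose_events(gains, assessments, DOMAIN)
        assert {e.evidence for e in events} == {
            "supported_conflict",
            "alternative_rooting",
        }

    def test_gain_without_assessment_is_unconfirmed(self):
        events = propose_events({"g": [_gain({"A", "B"})]}, {}, DOMAIN)
        assert len(events) == 1
        assert events[0].evidence == "asr_gain"
        assert not events[0].confirmed

    def test_taxonomic_restriction_configurable_off(self):
        gains = {"g": [_gain({"A", "B"})]}
        assessments = {"g": [_assessment("g", "c", {"A", "B"}, "unresolved")]}
        events = propose_events(
            gains, assessments, DOMAIN, admit_taxonomic_restriction=False
        )
        assert [e for e in events if e.confirmed] == []


class TestCollapseLinked:
    def _events(self):
        return [
            TransferEvent("E1", frozenset({"CoxA1"}), frozenset({"H1", "H2"}), "alternative_rooting"),
            TransferEvent("E2", frozenset({"CoxB1"}), frozenset({"H1", "H2"}), "alternative_rooting"),
            TransferEvent("E3", frozenset({"CoxA2"}), frozenset({"H1"}), "taxonomic_restriction"),
        ]

    def test_linked_same_recipient_merges(self):
        linkage = LinkageTable([LinkageRecord("H1", "CoxA1", "CoxB1", 0)])
        result = collapse_linked(self._events(), linkage)
        assert len(result.events) == 2
        merged = [e for e in result.events if len(e.gene_group) == 2]
        assert merged and merged[0].gene_group == frozenset({"CoxA1", "CoxB1"})

    def test_gap_threshold_respected(self):
        linkage = LinkageTable([LinkageRecord("H1", "CoxA1", "CoxB1", 2)])
        assert len(collapse_linked(self._events(), linkage, max_gap_orfs=1).events) == 3
        assert len(collapse_linked(self._events(), linkage, max_gap_orfs=2).events) == 2

    def test_single_orf_gap_merges_at_default(self):
        linkage = LinkageTable([LinkageRecord("H1", "CoxA1", "CoxB1", 1)])
        assert len(collapse_linked(self._events(), linkage).events) == 2

    def test_different_recipients_never_merge(self):
        linkage = LinkageTable([LinkageRecord("H1", "CoxA1", "CoxA2", 0)])
        assert len(collapse_linked(self._events(), linkage).events) == 3

    def test_empty_linkage_identity(self):
        result = collapse_linked(self._events(), LinkageTable())
        assert len(result.events) == 3

    def test_transitive_merging(self):
        events = self._events() + [
            TransferEvent("E4", frozenset({"CoxC1"}), frozenset({"H1", "H2"}), "alternative_rooting"),
        ]
        linkage = LinkageTable(
            [
                LinkageRecord("H1", "CoxA1", "CoxB1", 0),
                LinkageRecord("H2", "CoxB1", "CoxC1", 0),
            ]
        )
        result = collapse_linked(events, linkage)
        assert len(result.events) == 2
        big = max(result.events, key=lambda e: len(e.gene_group))
        assert big.gene_group == frozenset({"CoxA1", "CoxB1", "CoxC1"})

    def test_idempotent(self):
        linkage = LinkageTable([LinkageRecord("H1", "CoxA1", "CoxB1", 0)])
        once = collapse_linked(self._events(), linkage)
        twice = collapse_linked(once.events, linkage)
        assert [(e.gene_group, e.recipient) for e in once.events] == [
            (e.gene_group, e.recipient) for e in twice.events
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_order_invariance(self, seed):
        rng = random.Random(seed)
        events = self._events() + [
            TransferEvent("E4", frozenset({"CoxC1"}), frozenset({"H1", "H2"}), "congruent" if False else "alternative_rooting"),
        ]
        linkage = LinkageTable(
            [
                LinkageRecord("H1", "CoxA1", "CoxB1", 0),
                LinkageRecord("H2", "CoxB1", "CoxC1", 0),
            ]
        )
        shuffled = events[:]
        rng.shuffle(shuffled)
        a = collapse_linked(events, linkage)
        b = collapse_linked(shuffled, linkage)
        assert [(e.gene_group, e.recipient) for e in a.events] == [
            (e.gene_group, e.recipient) for e in b.events
        ]

    def test_linkage_taxon_outside_recipient_ignored(self):
        # the adjacency is observed only in a taxon outside the recipients
        linkage = LinkageTable([LinkageRecord("Z9", "CoxA1", "CoxB1", 0)])
        assert len(collapse_linked(self._events(), linkage).events) == 3


class TestDuplicationFlags:
    def _set(self):
        events = [
            TransferEvent("E1", frozenset({"SoxM"}), frozenset({"S1", "S2"}), "supported_conflict"),
            TransferEvent("E2", frozenset({"SoxB"}), frozenset({"S1", "S2", "S3"}), "taxonomic_restriction"),
            TransferEvent("E3", frozenset({"DoxB"}), frozenset({"S3", "S4"}), "taxonomic_restriction"),
            TransferEvent("E4", frozenset({"FoxA"}), frozenset({"S4"}), "taxonomic_restriction"),
        ]
        return TransferEventSet(events=events)

    def test_sulfolobales_style_min_two_max_four(self):
        flags = [
            DuplicationFlag("SoxB", "famB", anchor=True),
            DuplicationFlag("DoxB", "famB"),
            DuplicationFlag("FoxA", "famB"),
        ]
        result = apply_duplication_flags(self._set(), flags)
        assert result.min_count() == 2
        assert result.max_count() == 4

    def test_no_flags_min_equals_max(self):
        result = self._set()
        assert result.min_count() == result.max_count() == 4

    def test_all_flagged_single_family_min_one(self):
        flags = [
            DuplicationFlag("SoxM", "fam"),
            DuplicationFlag("SoxB", "fam"),
            DuplicationFlag("DoxB", "fam"),
            DuplicationFlag("FoxA", "fam"),
        ]
        result = apply_duplication_flags(self._set(), flags)
        assert result.min_count() == 1
        assert result.max_count() == 4

    def test_flag_on_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            apply_duplication_flags(self._set(), [DuplicationFlag("nope", "f")])

    def test_min_never_exceeds_max_per_gene_subset(self):
        flags = [
            DuplicationFlag("SoxB", "famB", anchor=True),
            DuplicationFlag("DoxB", "famB"),
            DuplicationFlag("FoxA", "famB"),
        ]
        result = apply_duplication_flags(self._set(), flags)
        for genes in (["SoxM"], ["SoxB", "DoxB"], ["FoxA"], None):
            assert result.min_count(genes) <= result.max_count(genes)

    def test_uncertain_single_vs_double_gain(self):
        # a second, doubtful gain (one clade vs two-gain reading): min 1 max 2
        events = [
            TransferEvent("E1", frozenset({"NirK"}), frozenset({"H1", "H2", "H3"}), "taxonomic_restriction"),
            TransferEvent("E2", frozenset({"NirK2"}), frozenset({"H2", "H3"}), "taxonomic_restriction"),
        ]
        flagged = apply_duplication_flags(
            TransferEventSet(events=events),
            [DuplicationFlag("NirK", "nirk", anchor=True), DuplicationFlag("NirK2", "nirk")],
        )
        assert flagged.min_count() == 1
        assert flagged.max_count() == 2


class TestDateEvents:
    def test_intervals_from_chronogram(self):
        tree = datasets.reference_tree()
        chronogram = Chronogram(tree=tree, rates={}, objective=0.0, seed=1)
        fp = frozenset({"Ferroplasma", "Picrophilus"})
        events = TransferEventSet(
            events=[TransferEvent("E1", frozenset({"CoxAC"}), fp, "taxonomic_restriction")]
        )
        dated = date_events(events, chronogram)
        (event,) = dated.events
        assert event.age_lo == pytest.approx(0.7)
        assert event.age_hi == pytest.approx(1.8)  # stem parent

    def test_root_child_upper_bound_is_root_age(self):
        tree = datasets.reference_tree()
        chronogram = Chronogram(tree=tree, rates={}, objective=0.0, seed=1)
        eury = tree.leafset(tree.root.children[0])
        events = TransferEventSet(
            events=[TransferEvent("E1", frozenset({"g"}), eury, "taxonomic_restriction")]
        )
        dated = date_events(events, chronogram)
        assert dated.events[0].age_hi == pytest.approx(3.5)

    def test_non_monophyletic_recipient_rejected(self):
        tree = datasets.reference_tree()
        chronogram = Chronogram(tree=tree, rates={}, objective=0.0, seed=1)
        bad = frozenset({"Ferroplasma", "Halobacterium"})
        events = TransferEventSet(
            events=[TransferEvent("E1", frozenset({"g"}), bad, "taxonomic_restriction")]
        )
        with pytest.raises(ValidationError):
            date_events(events, chronogram)

    def test_simulated_insertion_time_inside_interval(self):
        from lgtrates.simulate import (
            SimulationConfig,
            simulate_gene_history,
            simulate_reference_tree,
        )

        hits = total = 0
        for seed in range(20):
            config = SimulationConfig(
                n_taxa=24, seed=seed, transfer_rate=0.03, gain_range=(1, 3)
            )
            tree = simulate_reference_tree(config)
            history = simulate_gene_history(tree, config)
            chronogram = Chronogram(tree=tree, rates={}, objective=0.0, seed=seed)
            for gain in history.gains:
                events = TransferEventSet(
                    events=[
                        TransferEvent("E1", gain.gene_group, gain.recipient, "taxonomic_restriction")
                    ]
                )
                dated = date_events(events, chronogram)
                event = dated.events[0]
                total += 1
                if event.age_lo - 1e-9 <= gain.time <= event.age_hi + 1e-9:
                    hits += 1
        assert total >= 20
        assert hits / total >= 0.95


class TestTransferRate:
    @pytest.mark.parametrize(
        "n,expected",
        [(11, 3.1), (0, 0.0), (8, 2.3), (3, 0.9), (7, 2.0), (2, 0.6), (12, 3.4), (14, 4.0)],
    )
    def test_rates(self, n, expected):
        assert transfer_rate(n, 3.5) == expected

    def test_half_rounds_away_from_zero(self):
        assert transfer_rate(1, 4.0) == 0.3  # 0.25 -> 0.3
        assert transfer_rate(3, 4.0) == 0.8  # 0.75 -> 0.8

    def test_bad_domain_age(self):
        with pytest.raises(ValidationError):
            transfer_rate(1, 0.0)

    def test_rate_monotone_in_count(self):
        rates = [transfer_rate(n, 3.5) for n in range(30)]
        assert rates == sorted(rates)
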