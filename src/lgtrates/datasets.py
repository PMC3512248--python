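"""Bundled survey of metabolic gene clades across cultured Archaea.

This module encodes, as plain data, a curated per-gene survey over an
archaeal reference phylogeny: for every gene family, the monophyletic
clades its copies form, a verdict describing how each clade relates to the
reference topology, genomic linkage among co-located copies, and
duplication-ambiguity flags.  It also bundles a small dated reference tree
with a cytochrome-oxidase presence vector for the ancestral-state demo.

The survey feeds the event-inference pipeline in tests, the example CLI
configuration, and the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .asr import GainEdge
from .congruence import CladeAssessment
from .events import DuplicationFlag
from .trees import DatedTree, LinkageRecord, LinkageTable, Node, PresenceMatrix

__all__ = [
    "CladeRecord",
    "SURVEY_CLADES",
    "SURVEY_LINKAGE",
    "SURVEY_FLAGS",
    "CATEGORIES",
    "CATEGORY_GROUPS",
    "DOMAIN_AGE_GY",
    "EURYARCHAEOTA_TAXA",
    "CRENARCHAEOTA_TAXA",
    "SULFOLOBALES_TAXA",
    "survey_gains",
    "survey_assessments",
    "survey_linkage_table",
    "survey_flags",
    "domain_taxa",
    "reference_tree",
    "cox_presence",
]

DOMAIN_AGE_GY = 3.5


@dataclass(frozen=True)
class CladeRecord:
    """One monophyletic clade of copies of ``gene`` with its verdict."""

    gene: str
    clade_id: str
    taxa: tuple[str, ...]
    verdict: str  # congruent | supported_conflict | alternative_rooting | unresolved


# ---------------------------------------------------------------------------
# taxon sets (genus- or strain-level labels; consistent across genes)
# ---------------------------------------------------------------------------

HALO_COXA1 = ("Halobacterium", "Haloarcula", "Haloferax", "Halorubrum", "Halogeometricum")
HALO_COXA2 = ("Halorubrum", "Haloterrigena", "Haloarcula", "Haloferax", "Halogeometricum")
HALO_COXA3 = ("Halobacterium", "Haloarcula", "Halorubrum", "Haloterrigena")
HALO_QOX = ("Halobacterium", "Haloarcula", "Haloferax", "Halorubrum")
HALO_SSEA = ("Haloarcula", "Haloferax", "Halogeometricum", "Halorubrum", "Haloterrigena")
HALO_NARG = ("Haloarcula", "Haloferax", "Halogeometricum", "Halomicrobium", "Halorhabdus", "Halorubrum")
HALO_NIRK = (
    "Haloarcula", "Halobiforma", "Haloferax", "Halogeometricum", "Halomicrobium",
    "Halopiger", "Halorhabdus", "Haloterrigena", "Natrinema", "Natronomonas",
)
HALO_NORB = (
    "Haladaptatus", "Haloarcula", "Halobiforma", "Haloferax", "Halogeometricum",
    "Halomicrobium", "Halopiger", "Halorubrum", "Haloterrigena", "Natrinema",
)
HALO_NOSZ = (
    "Haloarcula", "Halobacterium", "Halobiforma", "Haloferax", "Halogeometricum",
    "Halopiger", "Halorubrum",
)
HALO_CHIA = (
    "Halobacterium", "Haloferax", "Haloterrigena", "Halogeometricum", "Halobiforma", "Halopiger",
)

FERRO_PICRO = ("Ferroplasma", "Picrophilus")
THERMOPLASMATALES = ("Ferroplasma", "Picrophilus", "Thermoplasma_acidophilum", "Thermoplasma_volcanium")

PYRO_COXA = ("Pyrobaculum_calidifontis", "Pyrobaculum_oguniense", "Pyrobaculum_sp_1860", "Pyrobaculum_aerophilum")
PYRO_COXAC = PYRO_COXA + ("Thermoproteus_uzoniensis",)
THERMOPROTEALES_QOX = (
    "Caldivirga", "Vulcanisaeta_distributa", "Vulcanisaeta_moutnovskia",
    "Thermoproteus_uzoniensis", "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis",
    "Pyrobaculum_oguniense", "Pyrobaculum_arsenaticum",
)
THERMOPROTEALES_DSR = (
    "Caldivirga", "Vulcanisaeta_distributa", "Vulcanisaeta_moutnovskia",
    "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis", "Pyrobaculum_oguniense",
    "Pyrobaculum_arsenaticum", "Thermoproteus_uzoniensis",
)
THERMOPROTEALES_SSEA = (
    "Caldivirga", "Vulcanisaeta_distributa", "Thermoproteus_uzoniensis",
    "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis", "Pyrobaculum_oguniense",
    "Pyrobaculum_sp_1860",
)
THERMOPROTEALES_FCSD = (
    "Caldivirga", "Vulcanisaeta_distributa", "Pyrobaculum_aerophilum",
    "Pyrobaculum_calidifontis", "Thermoproteus_uzoniensis",
)
THERMOPROTEALES_NORB = (
    "Caldivirga", "Vulcanisaeta_distributa", "Thermoproteus_uzoniensis",
    "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis",
)

SULFOLOBALES_TAXA = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_solfataricus_98_2",
    "Sulfolobus_islandicus_LAL14", "Sulfolobus_islandicus_M1425",
    "Sulfolobus_islandicus_M1627",
    "Sulfolobus_tokodaii", "Sulfolobus_acidocaldarius", "Sulfolobus_metallicus",
    "Metallosphaera_sedula", "Metallosphaera_cuprina", "Metallosphaera_yellowstonensis",
    "Acidianus", "Desulfurolobus",
)
SULF_SOXM = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_islandicus_LAL14",
    "Sulfolobus_acidocaldarius", "Sulfolobus_tokodaii", "Metallosphaera_sedula",
)
SULF_SOXB = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_islandicus_LAL14",
    "Sulfolobus_acidocaldarius", "Sulfolobus_tokodaii", "Metallosphaera_sedula",
    "Acidianus",
)
SULF_DOXB = ("Sulfolobus_tokodaii", "Metallosphaera_sedula", "Acidianus", "Desulfurolobus")
SULF_FOXA = ("Sulfolobus_tokodaii", "Metallosphaera_sedula")
SULF_SOR = ("Acidianus", "Desulfurolobus", "Sulfolobus_metallicus", "Sulfolobus_tokodaii")
SULF_SRE = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_islandicus_LAL14",
    "Sulfolobus_acidocaldarius", "Sulfolobus_tokodaii",
)
SULF_FCSD = ("Metallosphaera_sedula", "Sulfolobus_tokodaii", "Acidianus")
SULF_SQO = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_tokodaii", "Sulfolobus_acidocaldarius",
    "Metallosphaera_sedula", "Acidianus",
)
SULF_SSEA_1 = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_islandicus_LAL14",
    "Sulfolobus_acidocaldarius", "Metallosphaera_sedula",
)
SULF_SSEA_2 = ("Sulfolobus_tokodaii", "Metallosphaera_sedula", "Acidianus")
SULF_HPA = (
    "Metallosphaera_sedula", "Metallosphaera_cuprina", "Sulfolobus_tokodaii",
    "Sulfolobus_acidocaldarius", "Sulfolobus_solfataricus_P2",
    "Sulfolobus_islandicus_LAL14", "Sulfolobus_islandicus_M1425",
)
SULF_C3ED = (
    "Metallosphaera_sedula", "Metallosphaera_cuprina", "Sulfolobus_tokodaii",
    "Sulfolobus_acidocaldarius", "Sulfolobus_solfataricus_98_2",
    "Sulfolobus_islandicus_LAL14", "Sulfolobus_islandicus_M1425",
)
SISO_PHENOL = (
    "Sulfolobus_solfataricus_P2", "Sulfolobus_solfataricus_98_2",
    "Sulfolobus_islandicus_LAL14", "Sulfolobus_islandicus_M1425",
)

THERMOCOCCALES = ("Pyrococcus_furiosus", "Thermococcus_kodakarensis")
METHANOCOCCALES = (
    "Methanococcus_maripaludis", "Methanococcus_thermolithotrophicus",
    "Methanococcus_aeolicus", "Methanococcus_vannielii", "Methanocaldococcus_FS406",
)

# clade tuples below: (gene, clade_id, taxa, verdict)
SURVEY_CLADES: tuple[CladeRecord, ...] = tuple(
    CladeRecord(*row)
    for row in [
        # -- cytochrome oxidase, subunits I and I+III ----------------------
        ("CoxAC", "cox1_e1", FERRO_PICRO, "unresolved"),
        ("CoxA1", "cox1_e2", HALO_COXA1, "alternative_rooting"),
        ("CoxA2", "cox1_e3", HALO_COXA2, "congruent"),
        ("CoxA3", "cox1_e4", HALO_COXA3, "alternative_rooting"),
        ("CoxA3", "cox1_e5", ("Natronomonas",), "unresolved"),
        ("CoxA_cren", "cox1_c3", ("Caldivirga",), "unresolved"),
        ("CoxA_cren", "cox1_c2", PYRO_COXA, "alternative_rooting"),
        ("CoxAC_cren", "cox1_c1", PYRO_COXAC, "supported_conflict"),
        ("CoxA_cren", "cox1_c8", ("Aeropyrum",), "unresolved"),
        ("CoxAC_cren", "cox1_c9", ("Aeropyrum",), "unresolved"),
        ("SoxB", "cox1_c5", SULF_SOXB, "congruent"),
        ("DoxB", "cox1_c6", SULF_DOXB, "congruent"),
        ("FoxA", "cox1_c7", SULF_FOXA, "unresolved"),
        ("SoxM", "cox1_c4", SULF_SOXM, "supported_conflict"),
        # -- cytochrome oxidase, subunit II --------------------------------
        ("CoxB", "cox2_e1", FERRO_PICRO, "unresolved"),
        ("CoxB1", "cox2_e2", HALO_COXA1, "alternative_rooting"),
        ("CoxB2", "cox2_e3", HALO_COXA2, "congruent"),
        ("CoxB3", "cox2_e4", HALO_COXA3, "alternative_rooting"),
        ("CoxB3", "cox2_e5", ("Natronomonas",), "unresolved"),
        ("CoxB_cren", "cox2_c3", ("Caldivirga",), "unresolved"),
        ("PoxH", "cox2_c1", PYRO_COXA, "alternative_rooting"),
        ("PoxB", "cox2_c2", PYRO_COXAC, "supported_conflict"),
        ("PoxH", "cox2_c8", ("Aeropyrum",), "unresolved"),
        ("PoxB", "cox2_c9", ("Aeropyrum",), "unresolved"),
        ("SoxA", "cox2_c4", SULF_SOXB, "congruent"),
        ("SoxH", "cox2_c5", SULF_SOXM, "congruent"),
        # -- bd-type quinol oxidase ----------------------------------------
        ("QoxA_eury", "qox1_e1", ("Thermococcus_gammatolerans", "Thermococcus_AM4"), "unresolved"),
        ("QoxA_eury", "qox1_e2", HALO_QOX, "alternative_rooting"),
        ("QoxA_eury", "qox1_e3", ("Methanosarcina_acetivorans", "Methanosarcina_barkeri"), "unresolved"),
        ("QoxA_eury", "qox1_e4", ("Archaeoglobus_fulgidus",), "unresolved"),
        ("QoxA_eury", "qox1_e5", THERMOPLASMATALES, "congruent"),
        ("QoxB_eury", "qox2_e1", ("Thermococcus_gammatolerans", "Thermococcus_AM4"), "unresolved"),
        ("QoxB_eury", "qox2_e2", HALO_QOX, "alternative_rooting"),
        ("QoxB_eury", "qox2_e3", ("Methanosarcina_acetivorans", "Methanosarcina_barkeri"), "unresolved"),
        ("CydA_copy1", "qox1_c1", THERMOPROTEALES_QOX, "alternative_rooting"),
        ("CydA_copy2", "qox1_c2", THERMOPROTEALES_QOX, "alternative_rooting"),
        ("CydA_copy1", "qox1_c4", ("Hyperthermus", "Acidilobus"), "unresolved"),
        ("CydA_copy2", "qox1_c5", ("Hyperthermus", "Acidilobus"), "unresolved"),
        ("CydA_extra", "qox1_c3", ("Vulcanisaeta_distributa", "Vulcanisaeta_moutnovskia"), "unresolved"),
        # -- dissimilatory sulfite reductase -------------------------------
        ("DsrA", "dsr_1", ("Archaeoglobus_fulgidus", "Archaeoglobus_profundus"), "unresolved"),
        ("DsrA", "dsr_2", THERMOPROTEALES_DSR, "congruent"),
        ("DsrB", "dsr_3", ("Archaeoglobus_fulgidus", "Archaeoglobus_profundus"), "unresolved"),
        ("DsrB", "dsr_4", THERMOPROTEALES_DSR, "congruent"),
        # -- thiosulfate sulfurtransferase ---------------------------------
        ("SseA", "ssea_1", ("Methanohalophilus",), "unresolved"),
        ("SseA", "ssea_2", ("Methanosaeta",), "unresolved"),
        ("SseA", "ssea_3", ("Methanoculleus",), "unresolved"),
        ("SseA", "ssea_4", ("Methanothermobacter",), "unresolved"),
        ("SseA", "ssea_5", HALO_SSEA, "alternative_rooting"),
        ("SseA2", "ssea_6", HALO_SSEA, "alternative_rooting"),
        ("SseA", "ssea_c1", ("Aeropyrum",), "unresolved"),
        ("SseA", "ssea_c2", ("Caldivirga", "Pyrobaculum_aerophilum"), "unresolved"),
        ("SseA", "ssea_c3", THERMOPROTEALES_SSEA, "congruent"),
        ("SseA", "ssea_c4", ("Pyrobaculum_sp_1860",), "unresolved"),
        ("SseA", "ssea_c5", SULF_SSEA_1, "alternative_rooting"),
        ("SseA", "ssea_c6", SULF_SSEA_2, "alternative_rooting"),
        # -- sulfur oxygenase reductase / sulfur reductase / FCSD / SQO ----
        ("SOR", "sor_1", SULF_SOR, "congruent"),
        ("SOR", "sor_2", FERRO_PICRO, "unresolved"),
        ("SreC", "sre_1", SULF_SRE, "congruent"),
        ("FCSD", "fcsd_1", ("Ignicoccus",), "unresolved"),
        ("FCSD", "fcsd_2", THERMOPROTEALES_FCSD, "congruent"),
        ("FCSD", "fcsd_3", SULF_FCSD, "congruent"),
        ("SQO", "sqo_1", THERMOPLASMATALES, "congruent"),
        ("SQO", "sqo_2", SULF_SQO, "congruent"),
        # -- nitrate / nitrite / nitric and nitrous oxide reduction --------
        ("NarG", "nar_1", ("Ferroglobus",), "unresolved"),
        ("NarG", "nar_2", HALO_NARG, "congruent"),
        ("NarG", "nar_3", ("Aeropyrum",), "unresolved"),
        ("NarG", "nar_4", ("Pyrobaculum_aerophilum", "Pyrobaculum_arsenaticum", "Pyrobaculum_calidifontis"), "unresolved"),
        ("NarG", "nar_5", ("Sulfolobus_islandicus_M1425", "Sulfolobus_islandicus_M1627"), "unresolved"),
        ("NarG", "nar_6", ("Metallosphaera_yellowstonensis",), "unresolved"),
        ("NarG", "nar_7", ("Vulcanisaeta_distributa",), "unresolved"),
        ("NarH", "nar_8", ("Ferroglobus",), "unresolved"),
        ("NarH", "nar_9", HALO_NARG, "congruent"),
        ("NarH", "nar_10", ("Aeropyrum",), "unresolved"),
        ("NarH", "nar_11", ("Pyrobaculum_aerophilum", "Pyrobaculum_arsenaticum", "Pyrobaculum_calidifontis"), "unresolved"),
        ("NarH", "nar_12", ("Sulfolobus_islandicus_M1425", "Sulfolobus_islandicus_M1627"), "unresolved"),
        ("NarH", "nar_13", ("Metallosphaera_yellowstonensis",), "unresolved"),
        ("NarH", "nar_14", ("Vulcanisaeta_distributa",), "unresolved"),
        ("NirK", "nirk_1", HALO_NIRK, "congruent"),
        ("NirS", "nirs_1", ("Pyrobaculum_aerophilum", "Pyrobaculum_arsenaticum", "Pyrobaculum_calidifontis"), "congruent"),
        ("NorB", "norb_1", HALO_NORB, "congruent"),
        ("NorB", "norb_2", ("Sulfolobus_solfataricus_P2", "Sulfolobus_islandicus_LAL14", "Sulfolobus_islandicus_M1425"), "congruent"),
        ("NorB", "norb_3", ("Acidilobus",), "unresolved"),
        ("NorB", "norb_4", THERMOPROTEALES_NORB, "congruent"),
        ("NosZ", "nosz_1", HALO_NOSZ, "congruent"),
        ("NosZ", "nosz_2", ("Ferroglobus",), "unresolved"),
        ("NosZ", "nosz_3", ("Pyrobaculum_calidifontis", "Pyrobaculum_sp_1860"), "unresolved"),
        # -- nitrogen fixation ---------------------------------------------
        ("NifH", "nif_1", METHANOCOCCALES, "supported_conflict"),
        ("NifH", "nif_2", ("Methanothermobacter",), "unresolved"),
        ("NifH", "nif_3", ("Methanospirillum", "Methanosarcina_barkeri"), "supported_conflict"),
        ("NifH", "nif_4", ("Methanosarcina_barkeri",), "unresolved"),
        ("NifD", "nif_5", METHANOCOCCALES, "supported_conflict"),
        ("NifD", "nif_6", ("Methanothermobacter",), "unresolved"),
        ("NifD", "nif_7", ("Methanospirillum", "Methanosarcina_barkeri"), "supported_conflict"),
        ("NifD", "nif_8", ("Methanosarcina_barkeri",), "unresolved"),
        ("NifE", "nif_9", METHANOCOCCALES, "supported_conflict"),
        ("NifE", "nif_10", ("Methanothermobacter",), "unresolved"),
        ("NifE", "nif_11", ("Methanospirillum", "Methanosarcina_barkeri"), "supported_conflict"),
        ("NifE", "nif_12", ("Methanosarcina_barkeri",), "unresolved"),
        # -- chitin degradation --------------------------------------------
        ("ChiA", "chi_1", THERMOCOCCALES, "unresolved"),
        ("ChiA", "chi_2", HALO_CHIA, "alternative_rooting"),
        ("GlmA", "chi_3", THERMOCOCCALES, "unresolved"),
        ("GlmD", "chi_4", THERMOCOCCALES, "unresolved"),
        ("Dak", "chi_5", THERMOCOCCALES, "unresolved"),
        # -- phenolic compound degradation ---------------------------------
        ("PhOH", "phe_1", SISO_PHENOL, "congruent"),
        ("PhOH", "phe_2", ("Pyrobaculum_arsenaticum",), "unresolved"),
        ("CatDiox", "phe_3", SISO_PHENOL, "congruent"),
        ("HpaD", "phe_4", SULF_HPA, "congruent"),
        ("HpaD", "phe_5", ("Pyrobaculum_oguniense",), "unresolved"),
        ("HpaH", "phe_6", SULF_HPA, "congruent"),
        ("HpaH", "phe_7", ("Pyrobaculum_oguniense",), "unresolved"),
        ("C3ED", "phe_8", SULF_C3ED, "congruent"),
        ("C3ED", "phe_9", ("Thermoplasma_acidophilum",), "unresolved"),
        ("C3ED", "phe_10", ("Pyrobaculum_arsenaticum",), "unresolved"),
        ("C3ED", "phe_11", ("Methanobacterium_AL21", "Methanobacterium_SWAN"), "unresolved"),
        ("C3ED", "phe_12", ("Methanosphaera", "Methanoregula"), "unresolved"),
        ("C3ED", "phe_13", ("Methanosarcina_acetivorans", "Methanosarcina_barkeri"), "unresolved"),
    ]
)

# (taxon, copy_a, copy_b, gap_orfs): adjacency observed in that taxon's genome
SURVEY_LINKAGE: tuple[tuple[str, str, str, int], ...] = (
    ("Picrophilus", "CoxB", "CoxAC", 1),
    ("Ferroplasma", "CoxB", "CoxAC", 1),
    ("Haloarcula", "CoxB1", "CoxA1", 0),
    ("Haloferax", "CoxB2", "CoxA2", 0),
    ("Haloarcula", "CoxB3", "CoxA3", 0),
    ("Natronomonas", "CoxB3", "CoxA3", 0),
    ("Pyrobaculum_aerophilum", "PoxH", "CoxA_cren", 0),
    ("Aeropyrum", "PoxH", "CoxA_cren", 0),
    ("Pyrobaculum_aerophilum", "PoxB", "CoxAC_cren", 0),
    ("Aeropyrum", "PoxB", "CoxAC_cren", 0),
    ("Caldivirga", "CoxB_cren", "CoxA_cren", 0),
    ("Sulfolobus_solfataricus_P2", "SoxA", "SoxB", 0),
    ("Sulfolobus_solfataricus_P2", "SoxH", "SoxM", 0),
    ("Thermococcus_gammatolerans", "QoxB_eury", "QoxA_eury", 0),
    ("Haloferax", "QoxB_eury", "QoxA_eury", 0),
    ("Methanosarcina_acetivorans", "QoxB_eury", "QoxA_eury", 0),
    ("Pyrobaculum_aerophilum", "CydA_copy1", "CydA_copy2", 0),
    ("Hyperthermus", "CydA_copy1", "CydA_copy2", 0),
    ("Archaeoglobus_fulgidus", "DsrA", "DsrB", 0),
    ("Pyrobaculum_aerophilum", "DsrA", "DsrB", 0),
    ("Haloarcula", "SseA", "SseA2", 0),
    ("Ferroglobus", "NarG", "NarH", 0),
    ("Haloarcula", "NarG", "NarH", 0),
    ("Aeropyrum", "NarG", "NarH", 0),
    ("Pyrobaculum_aerophilum", "NarG", "NarH", 0),
    ("Sulfolobus_islandicus_M1425", "NarG", "NarH", 0),
    ("Metallosphaera_yellowstonensis", "NarG", "NarH", 0),
    ("Vulcanisaeta_distributa", "NarG", "NarH", 0),
    ("Methanococcus_maripaludis", "NifH", "NifD", 0),
    ("Methanococcus_maripaludis", "NifD", "NifE", 0),
    ("Methanothermobacter", "NifH", "NifD", 0),
    ("Methanothermobacter", "NifD", "NifE", 0),
    ("Methanospirillum", "NifH", "NifD", 0),
    ("Methanospirillum", "NifD", "NifE", 0),
    ("Methanosarcina_barkeri", "NifH", "NifD", 0),
    ("Methanosarcina_barkeri", "NifD", "NifE", 0),
    ("Pyrococcus_furiosus", "ChiA", "GlmA", 0),
    ("Pyrococcus_furiosus", "ChiA", "GlmD", 0),
    ("Pyrococcus_furiosus", "ChiA", "Dak", 0),
    ("Sulfolobus_solfataricus_P2", "PhOH", "CatDiox", 0),
    ("Sulfolobus_tokodaii", "HpaH", "HpaD", 0),
    ("Pyrobaculum_oguniense", "HpaH", "HpaD", 0),
    ("Pyrobaculum_arsenaticum", "PhOH", "C3ED", 0),
)

# duplication-ambiguity flags: DoxB and FoxA may be duplicates of SoxB
SURVEY_FLAGS: tuple[tuple[str, str, bool], ...] = (
    ("SoxB", "sulfolobales_family_b", True),  # anchor: the firm member
    ("DoxB", "sulfolobales_family_b", False),
    ("FoxA", "sulfolobales_family_b", False),
)

CATEGORIES: dict[str, tuple[str, ...]] = {
    "Cytochrome oxidase": (
        "CoxAC", "CoxA1", "CoxA2", "CoxA3", "CoxB", "CoxB1", "CoxB2", "CoxB3",
        "CoxA_cren", "CoxAC_cren", "CoxB_cren", "PoxH", "PoxB",
        "SoxM", "SoxB", "DoxB", "FoxA", "SoxA", "SoxH",
    ),
    "Quinol oxidase": ("QoxA_eury", "QoxB_eury", "CydA_copy1", "CydA_copy2", "CydA_extra"),
    "Dissimilatory sulfite reductase (DsrAB)": ("DsrA", "DsrB"),
    "Thiosulfate sulfurtransferase (SseA)": ("SseA", "SseA2"),
    "Sulfur oxygenase reductase (SOR)": ("SOR",),
    "Sulfur reductase (SreC)": ("SreC",),
    "Flavocytochrome c sulfide dehydrogenase (FCSD)": ("FCSD",),
    "Sulfide quinone oxidoreductase (SQO)": ("SQO",),
    "Nitrate reductase (NarGH)": ("NarG", "NarH"),
    "Nitrite reductase (NirK)": ("NirK",),
    "Nitrite reductase (NirS)": ("NirS",),
    "Nitric oxide reductase (NorB)": ("NorB",),
    "Nitrous oxide reductase (NosZ)": ("NosZ",),
    "Nitrogenase (NifHDE)": ("NifH", "NifD", "NifE"),
    "Chitin degradation": ("ChiA", "GlmA", "GlmD", "Dak"),
    "Oxidation of phenolic compounds": ("PhOH", "CatDiox", "HpaD", "HpaH", "C3ED"),
}

CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "Total genes using oxygen as terminal electron acceptor": (
        "Cytochrome oxidase", "Quinol oxidase",
    ),
    "Total genes using sulfur compounds as electron donors or acceptors": (
        "Dissimilatory sulfite reductase (DsrAB)",
        "Thiosulfate sulfurtransferase (SseA)",
        "Sulfur oxygenase reductase (SOR)",
        "Sulfur reductase (SreC)",
        "Flavocytochrome c sulfide dehydrogenase (FCSD)",
        "Sulfide quinone oxidoreductase (SQO)",
    ),
    "Total genes involved in nitrate reduction or nitrogen fixation": (
        "Nitrate reductase (NarGH)",
        "Nitrite reductase (NirK)",
        "Nitrite reductase (NirS)",
        "Nitric oxide reductase (NorB)",
        "Nitrous oxide reductase (NosZ)",
        "Nitrogenase (NifHDE)",
    ),
    "Total selected organic carbon degradation genes": (
        "Chitin degradation", "Oxidation of phenolic compounds",
    ),
}

_CREN_MARKERS = (
    "Pyrobaculum", "Thermoproteus", "Caldivirga", "Vulcanisaeta", "Thermofilum",
    "Aeropyrum", "Hyperthermus", "Acidilobus", "Ignicoccus", "Sulfolobus",
    "Metallosphaera", "Acidianus", "Desulfurolobus",
)


def domain_taxa() -> frozenset[str]:
    out: set[str] = set()
    for record in SURVEY_CLADES:
        out.update(record.taxa)
    return frozenset(out)


CRENARCHAEOTA_TAXA = frozenset(
    t for t in domain_taxa() if t.startswith(_CREN_MARKERS)
)
EURYARCHAEOTA_TAXA = domain_taxa() - CRENARCHAEOTA_TAXA


def survey_gains() -> dict[str, list[GainEdge]]:
    """One candidate gain edge per surveyed clade (its stem edge)."""
    gains: dict[str, list[GainEdge]] = {}
    for record in SURVEY_CLADES:
        gains.setdefault(record.gene, []).append(
            GainEdge(
                parent_taxa=frozenset(),
                child_taxa=frozenset(record.taxa),
                parent_p1=0.0,
                child_p1=1.0,
            )
        )
    return gains


def survey_assessments() -> dict[str, list[CladeAssessment]]:
    out: dict[str, list[CladeAssessment]] = {}
    for record in SURVEY_CLADES:
        out.setdefault(record.gene, []).append(
            CladeAssessment(
                gene_name=record.gene,
                clade_id=record.clade_id,
                taxa=frozenset(record.taxa),
                verdict=record.verdict,
            )
        )
    return out


def survey_linkage_table() -> LinkageTable:
    return LinkageTable(LinkageRecord(*row) for row in SURVEY_LINKAGE)


def survey_flags() -> list[DuplicationFlag]:
    return [DuplicationFlag(gene=g, family=f, anchor=a) for g, f, a in SURVEY_FLAGS]


# ---------------------------------------------------------------------------
# small dated reference tree + cytochrome oxidase presence (ASR demo)
# ---------------------------------------------------------------------------

def _clade(age: float, *children) -> Node:
    node = Node(age=age)
    for child in children:
        if isinstance(child, str):
            child = Node(label=child, age=0.0)
        node.add_child(child)
    return node


def reference_tree() -> DatedTree:
    """A small dated archaeal reference tree (ages in Ga, root 3.5)."""
    eury = _clade(
        3.3,
        _clade(0.8, "Pyrococcus_furiosus", "Thermococcus_kodakarensis"),
        _clade(
            3.1,
            _clade(2.9, "Methanothermobacter", "Methanococcus_maripaludis"),
            _clade(
                2.8,
                "Archaeoglobus_fulgidus",
                _clade(
                    2.6,
                    "Methanosarcina_acetivorans",
                    _clade(
                        2.4,
                        _clade(
                            1.8,
                            "Thermoplasma_acidophilum",
                            _clade(0.7, "Ferroplasma", "Picrophilus"),
                        ),
                        _clade(
                            1.5,
                            "Halobacterium",
                            _clade(1.0, "Haloarcula", _clade(0.6, "Haloferax", "Halorubrum")),
                        ),
                    ),
                ),
            ),
        ),
    )
    cren = _clade(
        3.2,
        "Thermofilum",
        _clade(
            3.0,
            _clade(
                2.7,
                "Caldivirga",
                _clade(
                    2.3,
                    _clade(1.4, "Vulcanisaeta_distributa", "Vulcanisaeta_moutnovskia"),
                    _clade(
                        2.0,
                        "Thermoproteus_tenax",
                        _clade(
                            1.6,
                            "Thermoproteus_uzoniensis",
                            _clade(0.9, "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis"),
                        ),
                    ),
                ),
            ),
            _clade(
                2.5,
                _clade(
                    1.9,
                    "Aeropyrum",
                    _clade(1.3, "Ignicoccus", _clade(0.9, "Hyperthermus", "Acidilobus")),
                ),
                _clade(
                    1.2,
                    "Sulfolobus_solfataricus_P2",
                    _clade(0.8, "Sulfolobus_tokodaii", "Metallosphaera_sedula"),
                ),
            ),
        ),
    )
    root = _clade(3.5, eury, cren)
    # derive branch lengths from the age field (1 Gy of time = 1 unit)
    tree = DatedTree(root)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return tree


_COX_PRESENT = (
    "Ferroplasma", "Picrophilus",
    "Halobacterium", "Haloarcula", "Haloferax", "Halorubrum",
    "Caldivirga", "Thermoproteus_uzoniensis",
    "Pyrobaculum_aerophilum", "Pyrobaculum_calidifontis",
    "Aeropyrum",
    "Sulfolobus_solfataricus_P2", "Sulfolobus_tokodaii", "Metallosphaera_sedula",
)


def cox_presence() -> PresenceMatrix:
    """Cytochrome oxidase presence over the bundled reference tree's taxa."""
    tree = reference_tree()
    present = frozenset(_COX_PRESENT)
    return PresenceMatrix.from_dict(
        {"cox": {taxon: int(taxon in present) for taxon in tree.leaf_labels()}}
    )
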