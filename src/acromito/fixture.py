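"""The packaged 31-taxon iguanian study fixture.

Hand-entered per-taxon metadata (family, accession, mtDNA and control-region
lengths), the five arrangement-character states, and the rooted mitogenomic
tree topology used for event mapping.  Control-region lengths are absent for
the four taxa whose CRs could not be fully sequenced (extensive tandem
repeats); those taxa are excluded from family CR-length means.

The tree encodes the published family/subfamily relationships: Iguanidae
sister to Acrodonta; within Agamidae, Uromastycinae then Leiolepidinae
diverge first, then Amphibolurinae, Hydrosaurinae, and sister subfamilies
Agaminae + Draconinae; within Chamaeleonidae, Brookesia then Rieppeleon
diverge first, the six hornless Chamaeleo form a clade, and Trioceros
groups with Calumma + Furcifer and then Kinyongia.  Orderings inside the
Chamaeleo clade and among the non-oplurine iguanids carry no signal for the
arrangement characters (identical states throughout) and are nested
arbitrarily.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .genome import MitogenomeRecord, GeneFeature
from .rearrangement import CharacterMatrix

__all__ = ["study_fixture", "FIG3_NEWICK", "FIG5_EVENTS", "TABLE1"]

AGAMIDAE = "Agamidae"
CHAMAELEONIDAE = "Chamaeleonidae"
IGUANIDAE = "Iguanidae"

#: taxon, family, accession, mtDNA length (bp), CR length (bp; None = unresolved)
TABLE1: List[Tuple[str, str, str, int, object]] = [
    ("Uromastyx_benti", AGAMIDAE, "AB114447", 16380, 990),
    ("Leiolepis_guttata", AGAMIDAE, "AB476400", 16552, 1167),
    ("Pogona_vitticeps", AGAMIDAE, "AB166795", 16751, 798),
    ("Chlamydosaurus_kingii", AGAMIDAE, "EF090422", 16761, 812),
    ("Hydrosaurus_amboinensis", AGAMIDAE, "AB475096", 16129, 823),
    ("Calotes_versicolor", AGAMIDAE, "AB183287", 16670, 1504),
    ("Acanthosaura_armata", AGAMIDAE, "AB266452", 16544, 1463),
    ("Pseudotrapelus_sinaitus", AGAMIDAE, "AB262447", 16560, 1456),
    ("Xenagama_taylori", AGAMIDAE, "DQ008215", 16220, 1174),
    ("Calumma_parsonii", CHAMAELEONIDAE, "AB474915", 17497, 2182),
    ("Trioceros_melleri", CHAMAELEONIDAE, "AB474916", 16832, 1521),
    ("Chamaeleo_calcaricarens", CHAMAELEONIDAE, "EF222195", 17451, 2189),
    ("Chamaeleo_chamaeleon", CHAMAELEONIDAE, "EF222201", 17415, 2155),
    ("Chamaeleo_calyptratus", CHAMAELEONIDAE, "EF222192", 17433, 2178),
    ("Chamaeleo_zeylanicus", CHAMAELEONIDAE, "EF222191", 18923, 3665),
    ("Chamaeleo_monachus", CHAMAELEONIDAE, "EF222190", 18900, 3672),
    ("Chamaeleo_dilepis", CHAMAELEONIDAE, "EF222189", 17875, 2618),
    ("Furcifer_oustaleti", CHAMAELEONIDAE, "AB185326", 18021, 2785),
    ("Kinyongia_fischeri", CHAMAELEONIDAE, "AB474917", 17400, None),
    ("Rieppeleon_kerstenii", CHAMAELEONIDAE, "AB474918", 17982, None),
    ("Brookesia_decaryi", CHAMAELEONIDAE, "AB474914", 17324, 2094),
    ("Anolis_cybotes", IGUANIDAE, "AB218960", 17853, None),
    ("Basiliscus_vittatus", IGUANIDAE, "AB218883", 16948, 1562),
    ("Gambelia_wislizenii", IGUANIDAE, "AB218884", 17563, 2181),
    ("Iguana_iguana", IGUANIDAE, "AJ278511", 16633, 1191),
    ("Oplurus_grandidieri", IGUANIDAE, "AB218720", 17122, 1758),
    ("Chalarodon_madagascariensis", IGUANIDAE, "AB266748", 16851, 1493),
    ("Polychrus_marmoratus", IGUANIDAE, "AB266749", 17743, 2371),
    ("Leiocephalus_personatus", IGUANIDAE, "AB266739", 16681, 1316),
    ("Plica_plica", IGUANIDAE, "AB218961", 17643, None),
    ("Sceloporus_occidentalis", IGUANIDAE, "AB079242", 17072, 1689),
]

_INVERTED_P = {"Calotes_versicolor", "Acanthosaura_armata"}
_TRANSLOCATED_P_AGAMINES = {"Pseudotrapelus_sinaitus", "Xenagama_taylori"}
_DUPLICATE_CR = {"Pogona_vitticeps", "Chlamydosaurus_kingii"}
_OL_ABSENT = {"Uromastyx_benti", "Hydrosaurus_amboinensis",
              "Pogona_vitticeps", "Chlamydosaurus_kingii"}
_CGG = {"Acanthosaura_armata"}


def _states_for(taxon: str, family: str) -> Dict[str, str]:
    acrodont = family in (AGAMIDAE, CHAMAELEONIDAE)
    if family == CHAMAELEONIDAE or taxon in _TRANSLOCATED_P_AGAMINES:
        c2 = "translocated_3prime_CR"
    elif taxon in _INVERTED_P:
        c2 = "inverted"
    else:
        c2 = "typical"
    return {
        "C1": "QIM" if acrodont else "IQM",
        "C2": c2,
        "C3": "duplicate_ND5_ND6" if taxon in _DUPLICATE_CR else "single",
        "C4": "absent" if taxon in _OL_ABSENT else "present",
        "C5": "CGG" if taxon in _CGG else "TGG",
    }


FIG3_NEWICK = (
    "(((Oplurus_grandidieri,Chalarodon_madagascariensis)Oplurinae,"
    "(Leiocephalus_personatus,(Iguana_iguana,(Basiliscus_vittatus,"
    "(Sceloporus_occidentalis,(Gambelia_wislizenii,(Anolis_cybotes,"
    "(Polychrus_marmoratus,Plica_plica))))))))Iguanidae,"
    "((Uromastyx_benti,(Leiolepis_guttata,((Pogona_vitticeps,"
    "Chlamydosaurus_kingii)Amphibolurinae,(Hydrosaurus_amboinensis,"
    "((Pseudotrapelus_sinaitus,Xenagama_taylori)Agaminae,"
    "(Calotes_versicolor,Acanthosaura_armata)Draconinae)"
    "AgaminaeDraconinae))))Agamidae,"
    "(Brookesia_decaryi,(Rieppeleon_kerstenii,((Chamaeleo_calcaricarens,"
    "(Chamaeleo_chamaeleon,(Chamaeleo_calyptratus,(Chamaeleo_zeylanicus,"
    "(Chamaeleo_monachus,Chamaeleo_dilepis)))))Chamaeleo,"
    "(Kinyongia_fischeri,(Trioceros_melleri,(Calumma_parsonii,"
    "Furcifer_oustaleti))))))Chamaeleonidae)Acrodonta)Iguania;"
)

#: the event set mapped on the tree by the parsimony analysis: one
#: IQM->QIM change on the Acrodonta stem; the tRNA-Pro inversion on the
#: Draconinae stem; independent tRNA-Pro translocations on the Agaminae and
#: Chamaeleonidae stems; the CR duplication on the Amphibolurinae stem;
#: three independent OL losses; one anticodon change.
FIG5_EVENTS = [
    ("C1", "Acrodonta", "QIM"),
    ("C2", "Draconinae", "inverted"),
    ("C2", "Agaminae", "translocated_3prime_CR"),
    ("C2", "Chamaeleonidae", "translocated_3prime_CR"),
    ("C3", "Amphibolurinae", "duplicate_ND5_ND6"),
    ("C4", "Uromastyx_benti", "absent"),
    ("C4", "Amphibolurinae", "absent"),
    ("C4", "Hydrosaurus_amboinensis", "absent"),
    ("C5", "Acanthosaura_armata", "CGG"),
]

# nominal feature spans (bp) used to lay out fixture records; the exact
# values are irrelevant to every analysis (orders, not coordinates, are
# compared), they only keep the records geometrically plausible
_NOMINAL_SPAN = {
    "12S": 950, "16S": 1600,
    "ND1": 970, "ND2": 1040, "ND3": 350, "ND4": 1380, "ND4L": 295,
    "ND5": 1810, "ND6": 520, "COI": 1550, "COII": 690, "COIII": 785,
    "ATP6": 680, "ATP8": 165, "CYTB": 1140,
    "OL": 35, "CR": 1200,
}


def _features_from_order(order, cr_length) -> list:
    feats = []
    pos = 1
    from .genome import base_symbol
    for name, orient in order.elements:
        base = base_symbol(name)
        span = _NOMINAL_SPAN.get(base, 70)      # tRNAs default to 70 bp
        if base == "CR" and cr_length:
            span = cr_length
        feats.append(GeneFeature(name, pos, pos + span - 1,
                                 "H" if orient == "+" else "L"))
        pos += span
    return feats


def study_fixture():
    """The packaged study fixture.

    Returns ``(records, matrix, newick)``: 31 annotated
    :class:`MitogenomeRecord` objects carrying the per-taxon metadata and
    the gene order implied by each taxon's arrangement states, the
    hand-entered :class:`CharacterMatrix`, and the rooted tree topology as
    a Newick string with labelled internal nodes.
    """
    from .simulate import order_from_states

    records = []
    states = {}
    for taxon, family, accession, mt_len, cr_len in TABLE1:
        st = _states_for(taxon, family)
        states[taxon] = st
        order = order_from_states(st)
        records.append(MitogenomeRecord(
            taxon=taxon,
            family=family,
            features=_features_from_order(order, cr_len),
            genome_length=mt_len,
            cr_length=cr_len,
            extras={"accession": accession,
                    "ol_status": st["C4"],
                    "anticodon": st["C5"]},
        ))
    matrix = CharacterMatrix(taxa=[t for t, *_ in TABLE1], states=states)
    return records, matrix, FIG3_NEWICK
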