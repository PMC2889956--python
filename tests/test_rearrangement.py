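"""Arrangement-character coding and signed-order comparison."""

import itertools
import random

import pytest

from acromito.genome import GeneOrder, canonical_vertebrate_order
from acromito.rearrangement import (
    CHARACTERS,
    CharacterMatrix,
    breakpoint_distance,
    encode_characters,
    order_diff,
)
from acromito.simulate import order_from_states

from conftest import random_signed_order


def _oracle_adjacencies(order):
    """Independent oracle: enumerate circular oriented adjacencies directly."""
    signed = [(n, 1 if o == "+" else -1) for n, o in order.elements]
    out = set()
    for i in range(len(signed)):
        a, b = signed[i], signed[(i + 1) % len(signed)]
        out.add(min((a, b), ((b[0], -b[1]), (a[0], -a[1]))))
    return out


class TestEncodeCharacters:
    def test_canonical_gives_ancestral_states(self):
        states = encode_characters(canonical_vertebrate_order(), "present", "TGG")
        assert states == {cid: c.ancestral_state
                          for cid, c in CHARACTERS.items()}

    def test_draconine_pattern(self):
        # QIM swap + inverted tRNA-Pro + lost OL, the Calotes/Acanthosaura form
        order = order_from_states({"C1": "QIM", "C2": "inverted"})
        states = encode_characters(order, "absent", "TGG")
        assert states == {"C1": "QIM", "C2": "inverted", "C3": "single",
                          "C4": "absent", "C5": "TGG"}

    def test_translocation_and_duplicate_cr(self):
        order = order_from_states({"C2": "translocated_3prime_CR",
                                   "C3": "duplicate_ND5_ND6"})
        states = encode_characters(order, "present", "TGG")
        assert states["C2"] == "translocated_3prime_CR"
        assert states["C3"] == "duplicate_ND5_ND6"

    def test_amphibolurine_duplicate_cr_keeps_typical_p(self):
        # the duplicate between ND5/ND6 must not masquerade as a translocation
        order = order_from_states({"C3": "duplicate_ND5_ND6"})
        assert encode_characters(order, "present", "TGG")["C2"] == "typical"

    def test_closure_over_all_state_vectors(self):
        """encode_characters inverts order_from_states on every state combo."""
        for c1, c2, c3, c4, c5 in itertools.product(
                CHARACTERS["C1"].states, CHARACTERS["C2"].states,
                CHARACTERS["C3"].states, CHARACTERS["C4"].states,
                CHARACTERS["C5"].states):
            states = {"C1": c1, "C2": c2, "C3": c3, "C4": c4, "C5": c5}
            order = order_from_states(states)
            assert encode_characters(order, c4, c5) == states

    def test_unknowns_become_missing(self):
        states = encode_characters(canonical_vertebrate_order(), "unknown", None)
        assert states["C4"] == "?" and states["C5"] == "?"

    def test_missing_p_is_an_error(self):
        elems = [e for e in canonical_vertebrate_order().elements
                 if e[0] != "P"]
        with pytest.raises(ValueError, match="P"):
            encode_characters(GeneOrder(elements=tuple(elems), anchor="F"))

    def test_wrong_anchor_rejected(self):
        order = canonical_vertebrate_order().reanchor("CYTB")
        with pytest.raises(ValueError, match="anchor"):
            encode_characters(order)

    def test_unexpected_anticodon_rejected(self):
        with pytest.raises(ValueError, match="anticodon"):
            encode_characters(canonical_vertebrate_order(), "present", "GGG")


class TestOrderDiff:
    def test_identity(self):
        d = order_diff(canonical_vertebrate_order(), canonical_vertebrate_order())
        assert d.identical

    def test_qim_variant_moves_q(self):
        d = order_diff(order_from_states({"C1": "QIM"}),
                       canonical_vertebrate_order())
        assert [m[0] for m in d.moved] == ["Q"]
        assert d.inverted == [] and d.gained == [] and d.lost == []

    def test_inversion_only(self):
        d = order_diff(order_from_states({"C2": "inverted"}),
                       canonical_vertebrate_order())
        assert d.inverted == ["P"] and d.moved == []

    def test_gain_and_loss_on_duplication(self):
        d = order_diff(order_from_states({"C3": "duplicate_ND5_ND6"}),
                       canonical_vertebrate_order())
        assert sorted(d.gained) == ["CR-1", "CR-2"] and d.lost == ["CR"]

    def test_planted_moves_counted(self):
        """k random single-element relocations leave exactly k symbols off
        the LCS (low-density regime: moved elements stay far apart)."""
        rng = random.Random(7)
        for _ in range(20):
            elems = list(canonical_vertebrate_order().elements)
            k = rng.randint(1, 3)
            moved = set()
            while True:
                positions = sorted(rng.sample(range(2, 36), 2 * k))
                if all(b - a >= 3 for a, b in zip(positions, positions[1:])):
                    break
            for j in range(k):
                src, dst = positions[2 * j], positions[2 * j + 1]
                e = elems.pop(src)
                elems.insert(dst, e)
                moved.add(e[0])
            order = GeneOrder(elements=tuple(elems), anchor="F")
            d = order_diff(order, canonical_vertebrate_order())
            assert {m[0] for m in d.moved} == moved


class TestBreakpointDistance:
    def test_identity_is_zero(self):
        order = canonical_vertebrate_order()
        assert breakpoint_distance(order, order) == 0

    def test_qim_variant_matches_adjacency_oracle(self):
        a = canonical_vertebrate_order()
        b = order_from_states({"C1": "QIM"})
        expected = len(_oracle_adjacencies(a) - _oracle_adjacencies(b))
        assert breakpoint_distance(a, b) == expected == 3

    def test_symmetry_and_oracle_on_random_permutations(self):
        rng = random.Random(11)
        a = canonical_vertebrate_order()
        for _ in range(100):
            b = random_signed_order(rng)
            d_ab = breakpoint_distance(a, b)
            assert d_ab == breakpoint_distance(b, a)
            assert d_ab == len(_oracle_adjacencies(a) - _oracle_adjacencies(b))

    def test_symbol_mismatch_rejected(self):
        elems = [e for e in canonical_vertebrate_order().elements
                 if e[0] != "OL"]
        with pytest.raises(ValueError):
            breakpoint_distance(canonical_vertebrate_order(),
                                GeneOrder(elements=tuple(elems), anchor="F"))


class TestCharacterMatrix:
    def test_tsv_round_trip(self, fixture_matrix):
        back = CharacterMatrix.from_tsv(fixture_matrix.to_tsv())
        assert back.taxa == fixture_matrix.taxa
        assert back.states == fixture_matrix.states

    def test_nexus_round_trip(self, fixture_matrix):
        back = CharacterMatrix.from_nexus(fixture_matrix.to_nexus())
        assert back.taxa == fixture_matrix.taxa
        assert back.states == fixture_matrix.states

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            CharacterMatrix(taxa=["t"], states={"t": {"C1": "XYZ"}})

    def test_missing_marker_allowed(self):
        m = CharacterMatrix(taxa=["t"], states={"t": {"C1": "?"}})
        assert m.column("C1")["t"] == "?"


class TestFixturePattern:
    """The coded 31-taxon matrix reproduces the published pattern."""

    def test_qim_splits_acrodonts_from_iguanids(self, fixture_records,
                                                fixture_matrix):
        fam = {r.taxon: r.family for r in fixture_records}
        for taxon in fixture_matrix.taxa:
            expect = "IQM" if fam[taxon] == "Iguanidae" else "QIM"
            assert fixture_matrix.states[taxon]["C1"] == expect

    def test_state_counts(self, fixture_matrix):
        col = fixture_matrix.column
        counts = {
            "inverted": sum(s == "inverted" for s in col("C2").values()),
            "translocated": sum(s == "translocated_3prime_CR"
                                for s in col("C2").values()),
            "duplicate": sum(s == "duplicate_ND5_ND6"
                             for s in col("C3").values()),
            "ol_absent": sum(s == "absent" for s in col("C4").values()),
            "cgg": sum(s == "CGG" for s in col("C5").values()),
        }
        assert counts == {"inverted": 2, "translocated": 14, "duplicate": 2,
                          "ol_absent": 4, "cgg": 1}
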