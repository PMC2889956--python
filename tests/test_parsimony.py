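"""Sankoff/Fitch reconstruction, MPR enumeration and event mapping."""

import random

import numpy as np
import pytest

from acromito.parsimony import (
    annotated_newick,
    constrained_cost,
    count_mprs,
    count_state_origins,
    enumerate_mprs,
    fitch_count,
    map_events,
    sankoff_min_changes,
)
from acromito.rearrangement import CHARACTERS
from acromito.simulate import SimulationParams, random_rooted_tree, \
    simulate_arrangements

from conftest import exhaustive_parsimony


class TestSankoffBasics:
    def test_constant_character_costs_nothing(self):
        tips = {f"t{i}": "a" for i in range(1, 6)}
        nwk = "((t1,t2),(t3,(t4,t5)));"
        assert sankoff_min_changes(nwk, tips, states=["a", "b"]) == 0

    def test_two_tip_split_forces_one_change(self):
        assert sankoff_min_changes("(t1,t2);", {"t1": "a", "t2": "b"}) == 1

    def test_missing_tips_are_unconstrained(self):
        nwk = "((t1,t2),(t3,t4));"
        tips = {"t1": "a", "t2": "?", "t3": "b", "t4": "?"}
        assert sankoff_min_changes(nwk, tips, states=["a", "b"]) == 1

    def test_custom_cost_matrix(self):
        # making a->b five times costlier shifts the minimum accordingly
        cost = np.array([[0, 5], [1, 0]])
        got = sankoff_min_changes("(t1,(t2,t3));",
                                  {"t1": "a", "t2": "b", "t3": "b"},
                                  cost_matrix=cost, states=["a", "b"])
        assert got == 1  # single b->... no: one a<-b change at cost 1

    def test_unknown_tip_rejected_unless_pruned(self, fixture_matrix,
                                                fixture_tree):
        tips = dict(fixture_matrix.column("C1"))
        tips.pop("Iguana_iguana")
        with pytest.raises(ValueError, match="without states"):
            sankoff_min_changes(fixture_tree, tips)
        assert sankoff_min_changes(fixture_tree, tips, prune_missing=True) == 1

    def test_polytomies_supported(self):
        nwk = "((t1,t2,t3),(t4,t5,t6));"
        tips = {"t1": "a", "t2": "a", "t3": "b",
                "t4": "b", "t5": "b", "t6": "b"}
        states = ["a", "b"]
        dp = sankoff_min_changes(nwk, tips, states=states)
        ex, _, _ = exhaustive_parsimony(nwk, tips, states)
        assert dp == ex


class TestOracleEquivalence:
    def test_dp_equals_exhaustive_and_fitch_on_random_trees(self):
        """Sankoff DP, Fitch and brute-force enumeration agree (small n)."""
        rng = random.Random(42)
        all_states = ["a", "b", "c", "d"]
        for _ in range(150):
            n = rng.randint(4, 9)
            nwk = random_rooted_tree(n, rng)
            states = all_states[:rng.randint(2, 4)]
            tips = {f"t{i + 1}": rng.choice(states + ["?"])
                    for i in range(n)}
            if all(s == "?" for s in tips.values()):
                tips["t1"] = states[0]
            dp = sankoff_min_changes(nwk, tips, states=states)
            ex, _, _ = exhaustive_parsimony(nwk, tips, states)
            assert dp == ex
            assert fitch_count(nwk, tips) == ex


class TestMprEnumeration:
    def test_count_matches_enumeration(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(4, 8)
            nwk = random_rooted_tree(n, rng)
            states = ["a", "b", "c"][:rng.randint(2, 3)]
            tips = {f"t{i + 1}": rng.choice(states) for i in range(n)}
            mprs = list(enumerate_mprs(nwk, tips, states=states,
                                       polarize_root=False))
            assert len(mprs) == count_mprs(nwk, tips, states=states,
                                           polarize_root=False)
            assert len(set(tuple(sorted(m.items())) for m in mprs)) == len(mprs)

    def test_every_mpr_achieves_the_minimum(self):
        rng = random.Random(9)
        nwk = random_rooted_tree(7, rng)
        tips = {f"t{i + 1}": rng.choice("ab") for i in range(7)}
        best = sankoff_min_changes(nwk, tips, states=["a", "b"])
        from acromito.parsimony import read_tree, _mpr_events
        t = read_tree(nwk)
        for mpr in enumerate_mprs(nwk, tips, states=["a", "b"],
                                  polarize_root=False):
            assert len(_mpr_events(t, mpr, ["a", "b"])) == best


class TestMapEvents:
    def test_constant_character_has_no_events(self):
        nwk = "((t1,t2),t3);"
        tips = {"C1": {"t1": "IQM", "t2": "IQM", "t3": "IQM"}}
        emap = map_events(nwk, tips)
        assert emap.events["C1"] == [] and emap.min_changes["C1"] == 0

    def test_event_count_equals_min_changes(self):
        for seed in range(25):
            _, matrix, man = simulate_arrangements(
                SimulationParams(seed=seed, tree=9, events_per_character=2))
            emap = map_events(man.newick, matrix)
            for cid in emap.min_changes:
                assert len(emap.events[cid]) == emap.min_changes[cid]

    def test_acctran_deltran_same_counts_different_placements(self):
        for seed in range(25):
            _, matrix, man = simulate_arrangements(
                SimulationParams(seed=seed, tree=10, events_per_character=2))
            acc = map_events(man.newick, matrix, resolution="ACCTRAN")
            delt = map_events(man.newick, matrix, resolution="DELTRAN")
            assert acc.min_changes == delt.min_changes
            for cid in acc.min_changes:
                assert len(acc.events[cid]) == len(delt.events[cid])

    def test_planted_single_events_recovered_exactly(self):
        """One planted change per character: the reconstruction must place
        every event on exactly the planted branch, unambiguously."""
        for seed in range(60):
            _, matrix, man = simulate_arrangements(
                SimulationParams(seed=seed, tree=9))
            emap = map_events(man.newick, matrix)
            planted = sorted((e["character"], e["branch"], e["from"], e["to"])
                             for e in man.events)
            found = sorted((cid, e.branch, e.from_state, e.to_state)
                           for cid, evs in emap.events.items() for e in evs)
            assert planted == found
            assert not any(e.ambiguous
                           for evs in emap.events.values() for e in evs)

    def test_fixture_c1_single_origin_on_acrodont_stem(self, fixture_matrix,
                                                       fixture_tree):
        emap = map_events(fixture_tree, fixture_matrix)
        assert emap.min_changes["C1"] == 1 and emap.n_mprs["C1"] == 1
        (event,) = emap.events["C1"]
        assert (event.branch, event.from_state, event.to_state) == \
               ("Acrodonta", "IQM", "QIM")
        assert not event.ambiguous

    def test_fixture_c2_two_independent_translocations(self, fixture_matrix,
                                                       fixture_tree):
        emap = map_events(fixture_tree, fixture_matrix)
        assert emap.min_changes["C2"] == 3
        gains = [e for e in emap.events["C2"]
                 if e.to_state == "translocated_3prime_CR"]
        assert sorted(e.branch for e in gains) == ["Agaminae", "Chamaeleonidae"]
        lo, hi = count_state_origins(
            fixture_tree, fixture_matrix.column("C2"),
            "translocated_3prime_CR",
            states=list(CHARACTERS["C2"].states), ancestral_state="typical")
        assert (lo, hi) == (2, 2)

    def test_bad_resolution_rejected(self, fixture_matrix, fixture_tree):
        with pytest.raises(ValueError):
            map_events(fixture_tree, fixture_matrix, resolution="MAXTRAN")


class TestCountStateOrigins:
    def test_constant_character_never_gains(self):
        tips = {f"t{i}": "a" for i in range(1, 5)}
        assert count_state_origins("((t1,t2),(t3,t4));", tips, "b",
                                   states=["a", "b"],
                                   ancestral_state="a") == (0, 0)

    def test_single_derived_tip_forced(self):
        tips = {"t1": "b", "t2": "a", "t3": "a"}
        assert count_state_origins("(t1,(t2,t3));", tips, "b",
                                   states=["a", "b"],
                                   ancestral_state="a") == (1, 1)

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = random.Random(17)
        for _ in range(60):
            n = rng.randint(4, 8)
            nwk = random_rooted_tree(n, rng)
            tips = {f"t{i + 1}": rng.choice("ab") for i in range(n)}
            if len(set(tips.values())) == 1:
                continue
            got = count_state_origins(nwk, tips, "b", states=["a", "b"],
                                      ancestral_state="a")
            _, lo, hi = exhaustive_parsimony(nwk, tips, ["a", "b"],
                                             root_state="a",
                                             derived_state="b")
            assert got == (lo, hi)

    def test_unknown_derived_state_rejected(self):
        with pytest.raises(ValueError):
            count_state_origins("(t1,t2);", {"t1": "a", "t2": "b"}, "z",
                                states=["a", "b"])


class TestConstrainedCost:
    def test_no_constraints_equals_sankoff(self, fixture_matrix, fixture_tree):
        for cid in CHARACTERS:
            tips = fixture_matrix.column(cid)
            assert constrained_cost(fixture_tree, tips, {}) == \
                   sankoff_min_changes(fixture_tree, tips)

    def test_single_origin_hypothesis_costs_more(self, fixture_matrix,
                                                 fixture_tree):
        """Pinning the agamid+chamaeleonid ancestor to the translocated
        state forces extra reversals: the single-origin scenario is
        strictly less parsimonious than two independent translocations."""
        tips = fixture_matrix.column("C2")
        states = list(CHARACTERS["C2"].states)
        free = constrained_cost(fixture_tree, tips, {}, states=states)
        pinned = constrained_cost(
            fixture_tree, tips,
            {"Acrodonta": "translocated_3prime_CR"}, states=states)
        assert pinned > free

    def test_constraint_matching_an_mpr_is_free(self, fixture_matrix,
                                                fixture_tree):
        tips = fixture_matrix.column("C1")
        assert constrained_cost(fixture_tree, tips,
                                {"Acrodonta": "QIM", "Iguanidae": "IQM"}) == 1

    def test_unknown_label_rejected(self, fixture_matrix, fixture_tree):
        with pytest.raises(ValueError, match="NotAClade"):
            constrained_cost(fixture_tree, fixture_matrix.column("C1"),
                             {"NotAClade": "QIM"})


class TestAnnotatedNewick:
    def test_events_appear_as_comments(self, fixture_matrix, fixture_tree):
        emap = map_events(fixture_tree, fixture_matrix)
        text = annotated_newick(fixture_tree, emap)
        assert "C1:IQM->QIM" in text
        assert "Acrodonta" in text
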