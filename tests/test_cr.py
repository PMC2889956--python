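"""Control-region annotation: motifs, tandem repeats, AT arrays, domains."""

import random

import pytest

from acromito.cr import (
    CRConfig,
    MotifDef,
    classify_at_arrays,
    cr_profile,
    detect_tandem_repeats,
    find_motifs,
    partition_domains,
)
from acromito.simulate import SimulationParams, simulate_cr

from conftest import hamming


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFindMotifs:
    def test_planted_exact_pattern_found_once(self):
        rng = random.Random(0)
        pattern = "TACATTAATGTATAACGT"
        seq = _random_seq(rng, 300) + pattern + _random_seq(rng, 300)
        hits = find_motifs(seq, [MotifDef("ETAS1", pattern, 2)])
        assert [(h.motif, h.start, h.mismatches) for h in hits] == \
               [("ETAS1", 301, 0)]

    def test_no_hits_in_unrelated_sequence(self):
        hits = find_motifs("G" * 200, [MotifDef("BoxD", "ATTTAAT", 1)])
        assert hits == []

    def test_mismatch_boundary(self):
        """A plant with exactly max mismatches is found; one more is not.
        Verified against a direct Hamming computation."""
        rng = random.Random(3)
        pattern = "ACGTACGTACGTACGTACGT"   # 20 nt, no degeneracy
        for extra in (0, 1):
            mm = 4 + extra
            mutated = list(pattern)
            for i in rng.sample(range(len(pattern)), mm):
                mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
            mutated = "".join(mutated)
            assert hamming(pattern, mutated) == mm
            seq = "G" * 50 + mutated + "G" * 50
            hits = find_motifs(seq, [MotifDef("BoxC", pattern, 4)])
            if extra == 0:
                assert len(hits) == 1 and hits[0].mismatches == 4
            else:
                assert hits == []

    def test_overlapping_hits_reduced_to_best(self):
        # two overlapping windows match; the exact one must win
        seq = "C" * 20 + "AAAAAAAAAA" + "C" * 20
        hits = find_motifs(seq, [MotifDef("ETAS2", "AAAAAAAAAA", 2)])
        assert len(hits) == 1
        assert hits[0].start == 21 and hits[0].mismatches == 0

    def test_iupac_degeneracy(self):
        hits = find_motifs("CCCARYCCC".replace("R", "A").replace("Y", "T"),
                           [MotifDef("CSB1", "CCCARYCCC", 1)])
        assert len(hits) == 1 and hits[0].mismatches == 0

    def test_non_iupac_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifDef("BoxF", "ACGTX", 1)


class TestTandemRepeats:
    def test_perfect_dinucleotide_repeat(self):
        arrays = detect_tandem_repeats("ATATATATAT", min_period=2)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.unit, a.copies, a.purity) == ("AT", 5.0, 1.0)
        assert (a.start, a.end) == (1, 10)

    def test_planted_long_unit_recovered(self):
        """64-bp unit x 8 copies with 2% noise inside random flanks:
        period exact, copies within one."""
        for seed in range(20):
            rng = random.Random(seed)
            unit = _random_seq(rng, 64)
            array = list(unit * 8)
            for i in range(len(array)):
                if rng.random() < 0.02:
                    array[i] = rng.choice("ACGT")
            seq = _random_seq(rng, 400) + "".join(array) + _random_seq(rng, 400)
            arrays = detect_tandem_repeats(seq, min_period=10, max_period=100,
                                           min_copies=3, min_identity=0.85)
            assert any(a.period == 64 and abs(a.copies - 8) <= 1
                       for a in arrays), (seed, arrays)

    def test_null_rate_on_random_sequence(self):
        """Random i.i.d. sequence rarely yields long-period arrays."""
        empty = 0
        for seed in range(200):
            rng = random.Random(10_000 + seed)
            seq = _random_seq(rng, 2000)
            arrays = detect_tandem_repeats(seq, min_period=10, max_period=200,
                                           min_copies=3, min_identity=0.9)
            empty += not arrays
        assert empty >= 190      # >= 95% of replicates

    def test_smaller_period_suppresses_multiples(self):
        arrays = detect_tandem_repeats("ACG" * 12, min_period=2, max_period=12,
                                       min_copies=3, min_identity=0.9)
        periods = sorted(a.period for a in arrays)
        assert periods == [3]


class TestATArrays:
    def test_perfect_block_repeat(self):
        arrays = classify_at_arrays("AAATTAAATTAAATT", min_len=10, min_copies=2)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.kind == "AT_block"
        assert a.profile == [(3, 2)] * 3 and a.copies == 3
        assert (a.start, a.end) == (1, 15)

    def test_perfect_dinucleotide(self):
        arrays = classify_at_arrays("ATATATAT", min_len=8, min_copies=3)
        assert len(arrays) == 1
        assert arrays[0].kind == "AT_dinucleotide" and arrays[0].copies == 4

    def test_short_regions_discarded(self):
        assert classify_at_arrays("ATATAT", min_len=8, min_copies=3) == []

    def test_dinucleotide_beats_block_on_overlap(self):
        seq = "G" * 5 + "AT" * 12 + "G" * 5 + "AATT" * 6 + "G" * 5
        arrays = classify_at_arrays(seq, min_len=10, min_copies=3)
        kinds = sorted(a.kind for a in arrays)
        assert kinds == ["AT_block", "AT_dinucleotide"]

    def test_no_same_kind_overlap(self):
        rng = random.Random(4)
        for _ in range(20):
            seq = _random_seq(rng, 500) + "AT" * 15 + _random_seq(rng, 100)
            arrays = classify_at_arrays(seq, min_len=10, min_copies=3)
            by_kind = {}
            for a in arrays:
                by_kind.setdefault(a.kind, []).append((a.start, a.end))
            for spans in by_kind.values():
                spans.sort()
                assert all(s2 > e1 for (_, e1), (s2, _) in
                           zip(spans, spans[1:]))


class TestPartitionDomains:
    def _hits(self, seq):
        return find_motifs(seq, CRConfig().motifs)

    def test_planted_layout_recovered(self):
        seq, manifest = simulate_cr(SimulationParams(seed=8))
        hits = find_motifs(seq, CRConfig().motifs)
        part = partition_domains(seq, hits)
        assert [list(part.domain1), list(part.domain2), list(part.domain3)] \
            == [manifest.domains["domain1"], manifest.domains["domain2"],
                manifest.domains["domain3"]]
        assert not part.low_confidence

    def test_no_hits_falls_back_flagged(self):
        part = partition_domains("G" * 1000, [])
        assert part.low_confidence
        assert part.domain1[0] == 1 and part.domain3[1] == 1000
        assert part.domain1[1] < part.domain2[1] < part.domain3[1]

    def test_out_of_order_anchors(self):
        from acromito.cr import MotifHit
        hits = [MotifHit("BoxD", 10, 27, 0), MotifHit("ETAS1", 100, 117, 0)]
        with pytest.raises(ValueError):
            partition_domains("G" * 300, hits, on_disorder="error")
        part = partition_domains("G" * 300, hits, on_disorder="flag")
        assert part.low_confidence

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            partition_domains("", [])


class TestCRProfile:
    def test_chamaeleonid_style_context(self):
        """Block arrays 5' of tRNA-Pro, dinucleotide arrays 3' of it."""
        seq, man = simulate_cr(SimulationParams(seed=21))
        ann = cr_profile({"sequence": seq, "trnp_interval": man.trnp_interval})
        ctx = {(r.kind, lbl) for r, lbl in zip(ann.repeat_arrays,
                                              ann.context_labels)
               if r.kind.startswith("AT")}
        assert ("AT_block", "5prime") in ctx
        assert ("AT_dinucleotide", "3prime") in ctx
        assert len({k for k, _ in ctx}) == 2   # the two AT-rich classes

    def test_brookesia_style_exception(self):
        seq, man = simulate_cr(SimulationParams(seed=22, cr_style="brookesia"))
        ann = cr_profile({"sequence": seq, "trnp_interval": man.trnp_interval})
        ctx = [(r.kind, lbl) for r, lbl in zip(ann.repeat_arrays,
                                               ann.context_labels)
               if r.kind == "AT_dinucleotide"]
        assert ("AT_dinucleotide", "5prime") in ctx
        assert ("AT_dinucleotide", "3prime") in ctx

    def test_plain_cr_has_no_at_arrays(self):
        seq, man = simulate_cr(SimulationParams(
            seed=23, cr_style="plain", include_trnp=False,
            include_tandem=False))
        ann = cr_profile(seq)
        assert ann.arrays_of_kind("AT_block") == []
        assert ann.arrays_of_kind("AT_dinucleotide") == []
        assert ann.domains is not None
        assert [lbl for r, lbl in zip(ann.repeat_arrays, ann.context_labels)
                if r.kind.startswith("AT")] == []

    def test_intervals_inside_sequence(self):
        for seed in range(10):
            seq, man = simulate_cr(SimulationParams(seed=seed))
            ann = cr_profile({"sequence": seq,
                              "trnp_interval": man.trnp_interval})
            n = len(seq)
            for h in ann.motif_hits:
                assert 1 <= h.start <= h.end <= n
            for r in ann.repeat_arrays:
                assert 1 <= r.start <= r.end <= n
            d1, d2, d3 = ann.domains
            assert d1[0] == 1 and d3[1] == n
            assert d1[1] < d2[0] and d2[1] < d3[0]

    def test_threshold_monotonicity(self):
        """Raising identity/length thresholds never grows the reported
        arrays: covered sequence shrinks (a stricter threshold may split an
        array, so coverage, not count, is the monotone quantity)."""
        def coverage(arrays):
            pos = set()
            for a in arrays:
                pos.update(range(a.start, a.end + 1))
            return pos

        for seed in (30, 31, 32):
            seq, _ = simulate_cr(SimulationParams(seed=seed))
            loose = detect_tandem_repeats(seq, 10, 150, 3, 0.80)
            tight = detect_tandem_repeats(seq, 10, 150, 3, 0.95)
            assert len(coverage(tight)) <= len(coverage(loose))
            loose_at = classify_at_arrays(seq, min_len=10, min_copies=3)
            tight_at = classify_at_arrays(seq, min_len=30, min_copies=3)
            assert coverage(tight_at) <= coverage(loose_at)

    def test_bed_and_json_outputs(self):
        seq, man = simulate_cr(SimulationParams(seed=31))
        ann = cr_profile({"sequence": seq, "trnp_interval": man.trnp_interval})
        bed = ann.to_bed_tsv()
        assert bed.startswith("feature\tstart\tend")
        import json
        d = json.loads(ann.to_json())
        assert d["length"] == len(seq)


class TestCRConfig:
    def test_yaml_round_trip(self):
        cfg = CRConfig(tandem_min_copies=4, at_min_len=25)
        back = CRConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_default_mismatch_budget_is_a_fifth(self):
        m = MotifDef("ETAS1", "A" * 15)
        assert m.max_mismatches == 3
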