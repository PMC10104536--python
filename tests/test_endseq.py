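"""Junction caller: constructed reads, oracle agreement, P2 filter,
tail calling and species classification."""

import numpy as np
import pytest

from oracles import oracle_resolve

from preribo.endseq import (
    JunctionParams,
    Species,
    Status,
    call_tail,
    classify_species,
    filter_p2,
    process_library,
    resolve_junction,
)
from preribo.simulate import EndseqSimConfig, sim_endseq


def _read(ref, three_end, tail, five_len=70, three_len=50, five_start=None):
    """Assemble a circularized read from reference slices."""
    s = ref.sequence
    p2 = five_start if five_start is not None else ref.sites["P2"]
    return s[three_end - three_len + 1 : three_end + 1] + tail + s[p2 : p2 + five_len]


class TestResolveJunction:
    def test_mature_read_from_reference_slices(self, ref):
        d, p2 = ref.sites["D"], ref.sites["P2"]
        call = resolve_junction("r", _read(ref, d, ""), ref)
        assert call.status is Status.RESOLVED
        assert (call.five_prime_pos, call.three_prime_pos, call.tail_seq) == (p2, d, "")

    def test_pre18s_end_ten_nt_into_its1(self, ref):
        d = ref.sites["D"]
        call = resolve_junction("r", _read(ref, d + 10, ""), ref)
        assert call.status is Status.RESOLVED
        assert ref.offset_from_d(call.three_prime_pos) == 10
        assert call.tail_seq == ""

    def test_nontemplated_tail_at_d(self, ref):
        d = ref.sites["D"]
        call = resolve_junction("r", _read(ref, d, "AAA"), ref)
        assert call.status is Status.RESOLVED
        assert call.three_prime_pos == d
        assert call.tail_seq == "AAA"
        # junction index = 3' arm + tail
        assert call.junction_index == 50 + 3

    def test_against_oracle_on_constructed_reads(self, small_ref):
        d = small_ref.sites["D"]
        for three_end, tail in [(d, ""), (d + 9, "AA"), (d + 60, ""), (d - 20, "T")]:
            seq = _read(small_ref, three_end, tail, five_len=60, three_len=45)
            expected = oracle_resolve(seq, small_ref)
            call = resolve_junction("r", seq, small_ref)
            assert expected is not None
            assert call.status is Status.RESOLVED
            assert (call.five_prime_pos, call.three_prime_pos, call.tail_seq) == expected

    def test_non_acgtn_characters_rejected(self, ref):
        call = resolve_junction("r", "ACGTX" * 20, ref)
        assert call.status is Status.REJECTED
        assert "non-ACGTN" in call.reject_reason

    def test_short_read_flagged(self, ref):
        call = resolve_junction("r", "ACGT" * 5, ref)
        assert call.status is Status.TOO_SHORT

    def test_unmappable_read_has_no_junction(self, ref):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        assert resolve_junction("r", seq, ref).status is Status.NO_JUNCTION

    def test_sequencing_error_in_arm_is_bridged(self, ref):
        d = ref.sites["D"]
        seq = _read(ref, d, "")
        mutated = seq[:25] + ("A" if seq[25] != "A" else "C") + seq[26:]
        call = resolve_junction("r", mutated, ref)
        assert call.status is Status.RESOLVED
        assert call.three_prime_pos == d
        assert call.mismatches_3p == 1


class TestP2Filter:
    def test_exact_p2_kept(self, ref):
        call = resolve_junction("r", _read(ref, ref.sites["D"], ""), ref)
        assert filter_p2(call, ref, 0).status is Status.RESOLVED

    def test_ets_containing_molecule_excluded(self, ref):
        seq = _read(ref, ref.sites["D"], "", five_start=ref.sites["P2"] - 30)
        call = resolve_junction("r", seq, ref)
        assert call.status is Status.RESOLVED
        assert filter_p2(call, ref, 0).status is Status.NON_P2

    def test_tolerance_boundary(self, ref):
        # pick a 3' end whose base differs from ref[P2], so the 5' arm
        # cannot extend one base leftward and absorb the junction
        d, p2 = ref.sites["D"], ref.sites["P2"]
        offset = next(
            o for o in range(15, 40) if ref.sequence[d + o] != ref.sequence[p2]
        )
        seq = _read(ref, d + offset, "", five_start=p2 + 1)
        call = resolve_junction("r", seq, ref)
        assert call.five_prime_pos == ref.sites["P2"] + 1
        assert filter_p2(call, ref, 1).status is Status.RESOLVED


class TestTailAndSpecies:
    def test_tail_base_matching_reference_is_templated(self, ref):
        # append the next reference base followed by a non-matching base:
        # maximal templated extension absorbs the first, tails the second
        d = ref.sites["D"]
        nxt = ref.sequence[d + 1]
        other = "A" if ref.sequence[d + 2] != "A" else "T"
        call = resolve_junction("r", _read(ref, d, nxt + other), ref)
        three, tail = call_tail(call, ref)
        assert three == d + 1
        assert tail == other

    def test_tail_composition_counts_each_base(self, ref):
        # order the four tail bases so neither junction-flanking base can
        # be absorbed as templated (first != ref[D+1], last != ref[P2-1])
        d, p2 = ref.sites["D"], ref.sites["P2"]
        tail = "ATCG" if ref.sequence[p2 - 1] != "G" else "ATGC"
        assert tail[0] != ref.sequence[d + 1]
        call = resolve_junction("r", _read(ref, d, tail), ref)
        assert call.tail_seq == tail
        assert sorted(call.tail_seq) == ["A", "C", "G", "T"]

    @pytest.mark.parametrize(
        "offset,expected",
        [
            (0, Species.MATURE_18S),
            (9, Species.PRE18S_A1),
            (13, Species.PRE18S_A1),
            (14, Species.PRE18S_OTHER),
            (-15, Species.UPSTREAM_OF_D),
        ],
    )
    def test_species_by_offset(self, ref, offset, expected):
        call = resolve_junction("r", _read(ref, ref.sites["D"] + offset, ""), ref)
        assert classify_species(call, ref) is expected

    def test_a2_species(self, ref):
        call = resolve_junction("r", _read(ref, ref.sites["A2"], ""), ref)
        assert classify_species(call, ref) is Species.PRE18S_A2


class TestLibraryProperties:
    def test_status_conservation(self, ref):
        config = EndseqSimConfig(n_reads=300, error_rate=0.01)
        records, _ = sim_endseq(ref, config, 5)
        records.append(("bad", "ACGTQ" * 30))
        records.append(("short", "ACGTACGT"))
        result = process_library(records, ref)
        assert sum(result.counts.values()) == len(records)

    def test_error_free_reads_recover_truth_exactly(self, ref):
        config = EndseqSimConfig(n_reads=1500, error_rate=0.0)
        records, truth = sim_endseq(ref, config, 9)
        result = process_library(records, ref)
        truth_map = {
            r.read_id: (r.true_five_prime, r.true_three_prime, r.true_tail)
            for r in truth.itertuples(index=False)
        }
        resolved = [c for c in result.calls if c.status is Status.RESOLVED]
        assert len(resolved) == len(records)
        for c in resolved:
            assert (c.five_prime_pos, c.three_prime_pos, c.tail_seq) == truth_map[c.read_id]

    def test_low_error_rate_agreement_above_99_percent(self, ref):
        config = EndseqSimConfig(n_reads=3000, error_rate=0.001)
        records, truth = sim_endseq(ref, config, 13)
        result = process_library(records, ref)
        truth_map = {
            r.read_id: (r.true_five_prime, r.true_three_prime, r.true_tail)
            for r in truth.itertuples(index=False)
        }
        resolved = [c for c in result.calls if c.status is Status.RESOLVED]
        agree = sum(
            (c.five_prime_pos, c.three_prime_pos, c.tail_seq) == truth_map[c.read_id]
            for c in resolved
        )
        assert agree / len(resolved) >= 0.99

    def test_byte_identical_reruns(self, ref):
        from preribo.endseq import calls_to_table

        config = EndseqSimConfig(n_reads=400, error_rate=0.001)
        records, _ = sim_endseq(ref, config, 21)
        t1 = calls_to_table(process_library(records, ref).calls, ref)
        t2 = calls_to_table(process_library(records, ref).calls, ref)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
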