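"""Breakpoint decomposition, canonical normalization, and read merging."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormko.breakcall import (
    BreakpointReport,
    call_breakpoint,
    call_from_reads,
    enumerate_decompositions,
    normalize_report,
    revcomp,
)
from wormko.errors import AssemblyError, NoDeletionFoundError
from wormko.seqmodel import DeletionAllele

from _oracle import brute_decompositions, canonical_choice, zero_insert_placements
from conftest import bare_amplicon

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class TestEnumerate:
    def test_unique_clean_decomposition(self):
        ds = enumerate_decompositions("AAAACGTTTT", "AAAATTTT", min_anchor=0)
        zero = [d for d in ds if not d.insert]
        assert [(d.left, d.right) for d in zero] == [(4, 6)]

    def test_microhomology_yields_four_placements(self):
        ds = enumerate_decompositions("AAAGCTGCTTT", "AAAGCTTT", min_anchor=0)
        zero = sorted((d.left, d.right) for d in ds if not d.insert)
        assert zero == [(3, 6), (4, 7), (5, 8), (6, 9)]

    def test_unrelated_product_raises(self):
        with pytest.raises(NoDeletionFoundError):
            enumerate_decompositions("A" * 20 + "T" * 20, "GGGG")

    def test_sorted_canonically_and_matches_oracle(self, rng):
        amp = random_seq(rng, 30)
        prod = amp[:11] + amp[20:]
        ds = enumerate_decompositions(amp, prod, min_anchor=0)
        expected = sorted(
            brute_decompositions(amp, prod),
            key=lambda d: (len(d[2]), -(d[0] + len(amp) - d[1]), -d[0]),
        )
        assert [(d.left, d.right, d.insert) for d in ds] == expected


class TestCallBreakpoint:
    def test_clean_call(self):
        rep = call_breakpoint(bare_amplicon("AAAACGTTTT"), "AAAATTTT", min_anchor=0)
        a = rep.allele
        assert (a.left, a.right, a.break_class, a.ambiguity_width) == (4, 6, "clean", 1)

    def test_ambiguous_rightmost_left_breakpoint(self):
        rep = call_breakpoint(bare_amplicon("AAAGCTGCTTT"), "AAAGCTTT", min_anchor=0)
        a = rep.allele
        assert (a.left, a.right) == (6, 9)
        assert a.break_class == "ambiguous"
        assert a.ambiguity_width == 4
        assert (rep.flank_left, rep.flank_right) == ("AAAGCT", "TT")
        assert len(rep.all_placements) == a.ambiguity_width

    def test_insertion_minimal_insert_maximal_flanks(self):
        rep = call_breakpoint(
            bare_amplicon("AAAACCCCGGGGTTTT"), "AAAATATTTT", min_anchor=0
        )
        a = rep.allele
        assert (a.left, a.right, a.insert, a.break_class) == (4, 12, "TA", "insertion")

    def test_product_reconstruction_invariant(self, rng):
        amp = bare_amplicon(random_seq(rng, 60))
        prod = amp.seq[:20] + "TT" + amp.seq[45:]
        rep = call_breakpoint(amp, prod, min_anchor=0)
        assert rep.product == prod

    def test_anchor_requirement_enforced(self, rng):
        amp = bare_amplicon(random_seq(rng, 100))
        prod = amp.seq[:6] + amp.seq[60:]  # only 6 bp of left anchor
        with pytest.raises(NoDeletionFoundError):
            call_breakpoint(amp, prod, min_anchor=10)

    @given(
        seed=st.integers(0, 10_000),
        amp_len=st.integers(14, 34),
        ins_len=st.integers(0, 3),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_agrees_with_brute_force_oracle(self, seed, amp_len, ins_len):
        """Planted products: the direct construction equals the sorted oracle."""
        rng = np.random.default_rng(seed)
        amp_seq = random_seq(rng, amp_len)
        left = int(rng.integers(0, amp_len - ins_len - 1))
        right = int(rng.integers(left + ins_len + 1, amp_len + 1))
        insert = random_seq(rng, ins_len)
        prod = amp_seq[:left] + insert + amp_seq[right:]
        if not prod or len(prod) >= amp_len:
            return
        oracle = brute_decompositions(amp_seq, prod)
        want = canonical_choice(oracle, amp_len)
        rep = call_breakpoint(bare_amplicon(amp_seq), prod, min_anchor=0)
        a = rep.allele
        assert (a.left, a.right, a.insert) == want
        # ambiguity width matches the count of zero-insert placements
        zero = zero_insert_placements(oracle)
        if zero:
            assert a.insert == ""
            assert a.ambiguity_width == len(zero)
            assert sorted(rep.all_placements) == zero

    @given(seed=st.integers(0, 5000), h=st.integers(1, 6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_ambiguity_width_is_microhomology_plus_one(self, seed, h):
        """Engineered h-bp microhomology at the break gives width h+1."""
        rng = np.random.default_rng(seed)
        core = random_seq(rng, 40)
        left, right = 15, 25
        seq = list(core)
        for j in range(h):
            seq[right + j] = seq[left + j]
        if seq[right + h] == seq[left + h]:
            seq[right + h] = "A" if seq[left + h] != "A" else "C"
        if seq[right - 1] == seq[left - 1]:
            seq[right - 1] = "A" if seq[left - 1] != "A" else "C"
        amp_seq = "".join(seq)
        prod = amp_seq[:left] + amp_seq[right:]
        rep = call_breakpoint(bare_amplicon(amp_seq), prod, min_anchor=0)
        assert rep.allele.ambiguity_width == h + 1
        assert rep.allele.left == left + h  # rightmost placement

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_canonical_insertions_are_flank_maximal(self, seed):
        rng = np.random.default_rng(seed)
        amp_seq = random_seq(rng, 40)
        prod = amp_seq[:12] + random_seq(rng, 4) + amp_seq[30:]
        if len(prod) >= len(amp_seq):
            return
        rep = call_breakpoint(bare_amplicon(amp_seq), prod, min_anchor=0)
        a = rep.allele
        if a.break_class == "insertion":
            assert a.insert[0] != amp_seq[a.left]
            assert a.insert[-1] != amp_seq[a.right - 1]


class TestNormalize:
    def test_idempotent_on_canonical(self):
        rep = call_breakpoint(bare_amplicon("AAAGCTGCTTT"), "AAAGCTTT", min_anchor=0)
        again = normalize_report(rep)
        assert again.allele == rep.allele
        assert normalize_report(again).allele == again.allele

    def test_leftmost_placement_normalizes_to_rightmost(self):
        amp = bare_amplicon("AAAGCTGCTTT")
        allele = DeletionAllele(
            allele_id="raw", amplicon_id="amp", left=3, right=6, insert="",
            break_class="ambiguous", ambiguity_width=4,
        )
        raw = BreakpointReport(
            allele=allele, amplicon=amp, flank_left=amp.seq[:3],
            flank_right=amp.seq[6:],
            all_placements=((3, 6), (4, 7), (5, 8), (6, 9)),
        )
        fixed = normalize_report(raw)
        assert (fixed.allele.left, fixed.allele.right) == (6, 9)
        assert fixed.product == raw.product

    def test_flank_extending_insert_is_shortened(self):
        # amplicon AAAACCGGTTTT, deletion [4, 8) with insert starting with
        # the retained base C: a non-canonical report places the break at
        # L=4 with insert "CA"; canonical advances L and shortens to "A".
        amp = bare_amplicon("AAAACCGGTTTT")
        prod = amp.seq[:4] + "CA" + amp.seq[8:]
        rep = call_breakpoint(amp, prod, min_anchor=0)
        assert rep.allele.insert == "A"
        assert rep.allele.left == 5


class TestCallFromReads:
    def _case(self, rng):
        amp_seq = random_seq(rng, 200)
        prod = amp_seq[:80] + amp_seq[140:]
        return bare_amplicon(amp_seq), prod

    def test_lossless_split_equals_direct_call(self, rng):
        amp, prod = self._case(rng)
        direct = call_breakpoint(amp, prod)
        left_read = prod[:90]
        right_read = revcomp(prod[40:])
        viaread = call_from_reads(amp, left_read, right_read)
        assert viaread.allele == direct.allele

    def test_identity_merge_full_reads(self, rng):
        amp, prod = self._case(rng)
        direct = call_breakpoint(amp, prod)
        viaread = call_from_reads(amp, prod, revcomp(prod))
        assert viaread.allele == direct.allele

    def test_right_read_accepted_on_reference_strand(self, rng):
        amp, prod = self._case(rng)
        direct = call_breakpoint(amp, prod)
        viaread = call_from_reads(amp, prod[:90], prod[40:])
        assert viaread.allele == direct.allele

    def test_wild_type_reads_raise_no_deletion(self, rng):
        amp, _ = self._case(rng)
        with pytest.raises(NoDeletionFoundError):
            call_from_reads(amp, amp.seq, revcomp(amp.seq))

    def test_non_overlapping_reads_raise_assembly_error(self, rng):
        amp, prod = self._case(rng)
        with pytest.raises(AssemblyError):
            call_from_reads(amp, prod[:30], revcomp(prod[100:]))

    def test_overlap_conflict_resolved_and_flagged(self, rng):
        amp, prod = self._case(rng)
        left_read = prod[:90]
        # one substitution error deep inside the left read's overlap
        errpos = 85
        base = "A" if prod[errpos] != "A" else "C"
        broken = left_read[:errpos] + base + left_read[errpos + 1 :]
        rep = call_from_reads(
            amp, broken, revcomp(prod[40:]), max_mismatch_rate=0.05
        )
        assert rep.merge_conflicts == 1
        assert rep.allele == call_breakpoint(amp, prod).allele
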