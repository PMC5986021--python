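"""Tests for register enumeration, slippage and the cycle simulation.

The register enumerator is cross-checked against an independent brute-force
oracle that walks every antiparallel alignment of the forward tail on the
template strand with an explicit complement table — it shares no geometry
code with the implementation.
"""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protatether as pt
from protatether.library_sim import (
    IncompatiblePrimersError,
    MinOverlap,
    _product_linker,
)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def oracle_registers(tail: str, template_block: str, min_nt: int):
    """Every extensible ungapped duplex of ``tail`` (5'->3') on the template
    block (5'->3' template strand), as a set of (overlap, product_linker).

    A duplex is a diagonal i + j = c on which tail[i] pairs with block[j]
    (Watson-Crick, antiparallel).  It is extensible when the tail's
    3'-terminal base is paired; polymerase then copies the template 5' of the
    paired region, so the product linker is tail + revcomp(block[:j_min]).
    """
    nT, nR = len(tail), len(template_block)
    out = set()
    for c in range(nT - 1, nT + nR - 1):
        i_lo = max(0, c - (nR - 1))
        positions = range(i_lo, nT)
        if not all(_COMP[tail[i]] == template_block[c - i] for i in positions):
            continue
        overlap = nT - i_lo
        if overlap < min_nt:
            continue
        j_min = c - (nT - 1)
        suffix = "".join(_COMP[b] for b in reversed(template_block[:j_min]))
        out.add((overlap, tail + suffix))
    return out


def ggs_pair(f, r):
    return pt.design_library_primers(pt.MOTIFS["GGS"], f, r)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "fwd_tail, block",
        [
            ("GGCGGCAGC" * 2, "GCTGCCGCC" * 4),
            ("GGCGGCAGCGACGGCGGC", "GTCGCTGCCGCC" * 8),
            ("AAACGCAAA", "GCGTTT" * 6),
            ("AAGAAGAAG", "CTTCTTCTT" * 4),
            ("GGCGGCGGC", "GCCGCCGCC" * 4),
        ],
    )
    @pytest.mark.parametrize("min_nt", [1, 6, 9])
    def test_catalog_tails(self, fwd_tail, block, min_nt):
        rule = MinOverlap(mode="nt", min_nt=min_nt)
        got = {
            (reg.overlap_nt, _product_linker(fwd_tail, block, reg))
            for reg in pt.enumerate_registers(fwd_tail, block, rule)
        }
        assert got == oracle_registers(fwd_tail, block, min_nt)

    @settings(derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=15),
        st.text(alphabet="ACGT", min_size=1, max_size=25),
        st.integers(min_value=1, max_value=6),
    )
    def test_random_sequences(self, tail, block, min_nt):
        rule = MinOverlap(mode="nt", min_nt=min_nt)
        got = {
            (reg.overlap_nt, _product_linker(tail, block, reg))
            for reg in pt.enumerate_registers(tail, block, rule)
        }
        assert got == oracle_registers(tail, block, min_nt)


class TestRegisters:
    def test_ggs_2x4_register_family(self):
        fwd, rev = ggs_pair(2, 4)
        regs = pt.enumerate_registers(fwd.tail, rev.tail, MinOverlap(mode="units"), 9)
        linkers = {len(_product_linker(fwd.tail, rev.tail, r)) // 9 for r in regs}
        assert linkers == {2, 3, 4, 5}

    def test_min_two_units_trims_overhang_register(self):
        fwd, rev = ggs_pair(2, 4)
        rule = MinOverlap(mode="units", min_units=2)
        regs = pt.enumerate_registers(fwd.tail, rev.tail, rule, 9)
        linkers = {len(_product_linker(fwd.tail, rev.tail, r)) // 9 for r in regs}
        assert linkers == {2, 3, 4}

    def test_tm_rule_matches_two_unit_rule_for_ggs(self):
        # the 55 degC floor rejects the 9-nt overlap (Tm 21.3) and keeps 18 nt
        fwd, rev = ggs_pair(2, 4)
        regs = pt.enumerate_registers(fwd.tail, rev.tail, MinOverlap(), 9)
        assert {r.overlap_nt for r in regs} == {18}

    def test_innermost_register_is_first_and_gives_shortest_product(self):
        fwd, rev = ggs_pair(2, 4)
        regs = pt.enumerate_registers(fwd.tail, rev.tail, MinOverlap(mode="units"), 9)
        first = regs[0]
        assert (first.overlap_nt, first.offset_nt) == (18, 18)
        amp = pt.extend_register(fwd, rev, first)
        assert amp.repeat_count == 2
        assert len(amp.seq) == 52
        assert amp.linker_peptide == "GGSGGS"

    def test_outermost_full_register_reproduces_rev_units(self):
        fwd, rev = ggs_pair(2, 4)
        regs = pt.enumerate_registers(fwd.tail, rev.tail, MinOverlap(mode="units"), 9)
        flush = [r for r in regs if r.shift == 0]
        assert len(flush) == 1
        amp = pt.extend_register(fwd, rev, flush[0])
        assert amp.repeat_count == 4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            pt.enumerate_registers("", "GGC")


class TestMinOverlap:
    def test_parse(self):
        assert MinOverlap.parse("tm:62").anneal_temp_C == 62.0
        assert MinOverlap.parse("nt:6") == MinOverlap(mode="nt", min_nt=6)
        assert MinOverlap.parse("units:2") == MinOverlap(mode="units", min_units=2)
        with pytest.raises(ValueError):
            MinOverlap.parse("bp:6")

    def test_tm_mode_floor_below_8nt(self):
        assert not MinOverlap(anneal_temp_C=0.0).accepts("GGCGGCA", 9)

    def test_units_mode_needs_unit(self):
        with pytest.raises(ValueError):
            MinOverlap(mode="units").accepts("GGCGGCAGC", None)


class TestSlippage:
    def _amp(self, n):
        fwd, rev = ggs_pair(2, 4)
        motif = pt.MOTIFS["GGS"]
        linker = motif.repeat(n)
        return pt.Amplicon(
            seq=fwd.arm + linker + pt.revcomp(rev.arm),
            linker=linker, fwd_arm=fwd.arm, rev_arm_sense=pt.revcomp(rev.arm),
            motif=motif, born_cycle=1,
        )

    def test_contraction(self):
        out = pt.apply_slippage(self._amp(2), pt.MOTIFS["GGS"], "contraction_only")
        assert [a.repeat_count for a in out] == [1]
        assert out[0].slip_events == 1

    def test_single_unit_cannot_contract(self):
        assert pt.apply_slippage(self._amp(1), pt.MOTIFS["GGS"], "contraction_only") == []

    def test_both_modes(self):
        out = pt.apply_slippage(self._amp(8), pt.MOTIFS["GGS"], "both")
        assert {a.repeat_count for a in out} == {7, 9}

    def test_event_budget(self):
        slipped = pt.apply_slippage(self._amp(3), pt.MOTIFS["GGS"], "contraction_only")[0]
        assert pt.apply_slippage(slipped, pt.MOTIFS["GGS"], "contraction_only", max_events=1) == []

    def test_non_array_linker_untouched(self):
        amp = self._amp(2)
        amp = type(amp)(
            seq=amp.seq, linker="GGCGGCAGCGAC", fwd_arm=amp.fwd_arm,
            rev_arm_sense=amp.rev_arm_sense, motif=amp.motif, born_cycle=1,
        )
        assert pt.apply_slippage(amp, pt.MOTIFS["GGS"], "both") == []


class TestSimulateDefaults:
    def test_ggs_2x4_reachable_set(self):
        fwd, rev = ggs_pair(2, 4)
        pred = pt.simulate_cycles(fwd, rev)
        assert pred.reachable_int_counts() == {1, 2, 3, 4}
        assert pred.min_linker_aa == 3
        assert pred.max_linker_aa == 12
        peptides = {e.linker_peptide for e in pred.entries}
        assert peptides == {"GGS" * n for n in (1, 2, 3, 4)}

    def test_no_slippage_drops_single_unit(self):
        fwd, rev = ggs_pair(2, 4)
        pred = pt.simulate_cycles(fwd, rev, pt.SimConfig(slippage="off"))
        assert pred.reachable_int_counts() == {2, 3, 4}

    def test_band_table(self):
        fwd, rev = ggs_pair(2, 4)
        bands = pt.band_table(pt.simulate_cycles(fwd, rev))
        assert list(bands["amplicon_nt"]) == [70, 61, 52, 43]
        assert bands["modal"].sum() == 1

    def test_frame_conservation(self):
        fwd, rev = ggs_pair(2, 4)
        for entry in pt.simulate_cycles(fwd, rev).entries:
            assert entry.linker_nt % 3 == 0
            assert "*" not in entry.linker_peptide

    def test_weights_normalised(self):
        fwd, rev = ggs_pair(2, 4)
        pred = pt.simulate_cycles(fwd, rev)
        assert sum(e.weight for e in pred.entries) == pytest.approx(1.0)

    def test_determinism_byte_identical(self):
        fwd, rev = ggs_pair(2, 4)
        a = pt.simulate_cycles(fwd, rev).to_json()
        b = pt.simulate_cycles(fwd, rev).to_json()
        assert a == b

    def test_stochastic_seeded(self):
        fwd, rev = ggs_pair(2, 4)
        cfg = pt.SimConfig(stochastic=True, seed=11)
        a = pt.simulate_cycles(fwd, rev, cfg)
        b = pt.simulate_cycles(fwd, rev, cfg)
        assert [e.weight for e in a.entries] == [e.weight for e in b.entries]
        assert sum(e.weight for e in a.entries) == pytest.approx(1.0)


class TestTemplateOverrun:
    def test_ggsd_reaches_nine_and_ten_units(self):
        # half-unit 3'-overhang pairing plus primer-on-product re-annealing
        # push past the 8 units encoded on the reverse primer
        motif = pt.MOTIFS["GGSD"]
        fwd = pt.library_primer_from_tail(
            "GGSD_fwd", pt.UPSTREAM_JUNCTION_ARM, "GGCGGCAGCGACGGCGGC", "forward", motif
        )
        _, rev = pt.design_library_primers(motif, 1, 8)
        cfg = pt.SimConfig(min_overlap=MinOverlap(mode="nt", min_nt=6), cycles=3, slippage="off")
        pred = pt.simulate_cycles(fwd, rev, cfg)
        assert {9, 10} <= pred.reachable_int_counts()
        by_count = {e.repeat_count: e.first_reachable_cycle for e in pred.entries}
        assert by_count[Fraction(9)] == 1
        assert by_count[Fraction(10)] == 2

    def test_max_length_grows_with_cycles_under_permissive_overlap(self):
        fwd, rev = ggs_pair(2, 4)
        cfg1 = pt.SimConfig(min_overlap=MinOverlap(mode="units"), cycles=1, slippage="off")
        cfg3 = pt.SimConfig(min_overlap=MinOverlap(mode="units"), cycles=3, slippage="off")
        m1 = pt.simulate_cycles(fwd, rev, cfg1).max_linker_aa
        m3 = pt.simulate_cycles(fwd, rev, cfg3).max_linker_aa
        assert m3 > m1

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=5))
    def test_cycle1_reachable_interval(self, f, r):
        # one cycle, single-unit overlap floor: products span exactly
        # [f, f + r - 1] units (full-tail registers down to the one-unit
        # 3'-overhang register)
        fwd, rev = ggs_pair(f, r)
        cfg = pt.SimConfig(min_overlap=MinOverlap(mode="units"), cycles=1, slippage="off")
        pred = pt.simulate_cycles(fwd, rev, cfg)
        assert pred.reachable_int_counts() == set(range(f, f + r))


class TestSimulateErrors:
    def test_mixed_motifs_rejected(self):
        fwd, _ = pt.design_library_primers(pt.MOTIFS["GGS"], 2, 2)
        _, rev = pt.design_library_primers(pt.MOTIFS["polyK"], 2, 12)
        with pytest.raises(IncompatiblePrimersError):
            pt.simulate_cycles(fwd, rev)

    def test_non_complementary_tails_rejected(self):
        fwd = pt.PrimerSpec("f", pt.UPSTREAM_JUNCTION_ARM, "AAGAAGAAG", "forward")
        rev = pt.PrimerSpec("r", pt.DOWNSTREAM_JUNCTION_ARM, "AAGAAGAAG", "reverse")
        with pytest.raises(IncompatiblePrimersError):
            pt.simulate_cycles(fwd, rev)

    def test_tailless_primer_rejected(self):
        fwd, rev = ggs_pair(2, 4)
        bare = pt.PrimerSpec("bare", pt.UPSTREAM_JUNCTION_ARM, "", "forward")
        with pytest.raises(IncompatiblePrimersError):
            pt.simulate_cycles(bare, rev)

    def test_bad_config_values(self):
        with pytest.raises(ValueError):
            pt.SimConfig(cycles=0)
        with pytest.raises(ValueError):
            pt.SimConfig(slippage="sometimes")
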