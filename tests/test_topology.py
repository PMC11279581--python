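"""Disulfide chain topology: lasso parameters, single-bond calls, matchings."""

import math

import pytest

from cyclopep import (
    BondKind,
    DomainError,
    IntrachainBond,
    Linkage,
    NotDisulfideCyclic,
    PairingScheme,
    PeptideRecord,
    ResidueChain,
    StructureClass,
    Synthesis,
    classify_matching,
    classify_peptide_topology,
    classify_single_dsb,
    count_matchings,
    crossing_count,
    enumerate_matchings,
    lasso_params,
    loop_size,
)
from cyclopep.topology import BondConflictError, ladder_matching, string_matching


def brute_crossings(pairs):
    """Independent O(k^2) crossing oracle written from the definition."""
    n = 0
    ps = [tuple(sorted(p)) for p in pairs]
    for i in range(len(ps)):
        for j in range(len(ps)):
            a1, b1 = ps[i]
            a2, b2 = ps[j]
            if a1 < a2 < b1 < b2:
                n += 1
    return n


class TestLassoParams:
    @pytest.mark.parametrize(
        "L,n1,n2,s,p",
        [
            (20, 13, 19, 0.75, 1 / 12),
            (18, 2, 17, 4 / 18, 1.0),
            (10, 1, 10, 0.2, None),
        ],
    )
    def test_hand_evaluated_examples(self, L, n1, n2, s, p):
        params = lasso_params(L, n1, n2)
        assert params.s == pytest.approx(s)
        if p is None:
            assert params.p is None
        else:
            assert params.p == pytest.approx(p)

    @pytest.mark.parametrize("L,n1,n2", [(10, 5, 5), (10, 7, 3), (10, 0, 5), (10, 3, 11)])
    def test_domain_errors(self, L, n1, n2):
        with pytest.raises(DomainError):
            lasso_params(L, n1, n2)


class TestSingleBondCall:
    @pytest.mark.parametrize(
        "L,n1,n2,expected",
        [
            (25, 18, 24, StructureClass.C_LL),   # s=0.80, p=1/17
            (18, 2, 17, StructureClass.HL),      # s~0.222
            (20, 1, 8, StructureClass.N_LL),     # n1=1 clause, C-tail 12 > 1
            (20, 10, 12, StructureClass.AMBIGUOUS),  # s=0.95, p=8/9
        ],
    )
    def test_rule_examples(self, L, n1, n2, expected):
        assert classify_single_dsb(L, n1, n2).value is expected

    def test_tail_tie_breaks_to_c_terminal_lasso(self):
        # L - n2 = n1 = 1 with s >= 0.5: documented tie-break to C-LL
        assert classify_single_dsb(6, 1, 5).value is StructureClass.C_LL

    def test_hairpin_takes_priority_over_n1_clause(self):
        # n1 = 1 but the loop spans nearly the whole chain: s < 0.5 wins
        assert classify_single_dsb(20, 1, 18).value is StructureClass.HL

    def test_threshold_overrides(self):
        # widen the p window so the balanced-tail case becomes a lasso
        call = classify_single_dsb(20, 10, 12, p_low=1.0)
        assert call.value in (StructureClass.C_LL, StructureClass.N_LL)


class TestLoopSize:
    @pytest.mark.parametrize("n1,n2,size", [(1, 7, 7), (3, 12, 10), (4, 5, 2)])
    def test_inclusive_loop(self, n1, n2, size):
        assert loop_size(n1, n2) == size

    def test_spacing_to_loop_mapping(self):
        # i residues strictly between the cysteines close a loop of i + 2
        for spacing in (5, 8):
            assert loop_size(1, spacing + 2) == spacing + 2

    def test_rejects_unordered(self):
        with pytest.raises(DomainError):
            loop_size(5, 5)


class TestMatchings:
    @pytest.mark.parametrize("k", range(1, 6))
    def test_enumeration_matches_closed_form(self, k):
        ms = enumerate_matchings(k)
        assert len(ms) == count_matchings(k) == (
            math.factorial(2 * k) // (2**k * math.factorial(k))
        )
        assert len(set(ms)) == len(ms)
        assert ms == sorted(ms)

    def test_small_counts(self):
        assert count_matchings(1) == 1
        assert count_matchings(2) == 3
        assert count_matchings(4) == 105
        assert enumerate_matchings(2) == [
            ((1, 2), (3, 4)), ((1, 3), (2, 4)), ((1, 4), (2, 3)),
        ]

    @pytest.mark.parametrize("k", [0, 7])
    def test_enumeration_guard(self, k):
        with pytest.raises(DomainError):
            enumerate_matchings(k)

    @pytest.mark.parametrize(
        "pairs,expected",
        [([(1, 4), (2, 3)], 0), ([(1, 3), (2, 4)], 1), ([(1, 4), (2, 5), (3, 6)], 3)],
    )
    def test_crossing_examples(self, pairs, expected):
        assert crossing_count(pairs) == expected == brute_crossings(pairs)

    @pytest.mark.parametrize("k", range(1, 6))
    def test_noncrossing_count_is_catalan(self, k):
        catalan = math.comb(2 * k, k) // (k + 1)
        noncrossing = [m for m in enumerate_matchings(k) if crossing_count(m) == 0]
        assert len(noncrossing) == catalan

    @pytest.mark.parametrize("k", range(2, 6))
    def test_exactly_one_ladder_and_one_string(self, k):
        calls = [classify_matching(m).value for m in enumerate_matchings(k)]
        assert calls.count(PairingScheme.LD) == 1
        assert calls.count(PairingScheme.SR) == 1
        catalan = math.comb(2 * k, k) // (k + 1)
        assert calls.count(PairingScheme.MIXED) == max(catalan - 2, 0)

    @pytest.mark.parametrize("k", range(1, 6))
    def test_crossed_iff_any_crossing(self, k):
        for m in enumerate_matchings(k):
            call = classify_matching(m)
            assert (call.value is PairingScheme.CR) == (brute_crossings(m) > 0)
            assert call.crossing_count == brute_crossings(m)

    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(1, 4), (2, 3)], PairingScheme.LD),
            ([(1, 2), (3, 4)], PairingScheme.SR),
            ([(1, 3), (2, 4)], PairingScheme.CR),
            ([(1, 6), (2, 3), (4, 5)], PairingScheme.MIXED),
        ],
    )
    def test_scheme_examples(self, pairs, expected):
        assert classify_matching(pairs).value is expected

    def test_pure_schemes_are_well_formed(self):
        assert ladder_matching(3) == ((1, 6), (2, 5), (3, 4))
        assert string_matching(3) == ((1, 2), (3, 4), (5, 6))


def _dsb_record(L, pairs, seq_char="A"):
    tokens = [seq_char] * L
    for p1, p2 in pairs:
        tokens[p1 - 1] = tokens[p2 - 1] = "C"
    return PeptideRecord(
        chain=ResidueChain(id="t", tokens=tuple(tokens)),
        synthesis=Synthesis.RIBOSOMAL,
        bonds=tuple(
            IntrachainBond(BondKind.DSB, Linkage.SSB, p1, p2) for p1, p2 in pairs
        ),
    )


class TestPeptideTopology:
    def test_single_bond_record(self):
        call = classify_peptide_topology(_dsb_record(25, [(18, 24)]))
        assert call.label == "C-LL" and call.k == 1
        assert call.s == pytest.approx(0.80)
        assert call.loop_sizes == (7,)

    def test_nested_bonds_are_ladder(self):
        call = classify_peptide_topology(_dsb_record(18, [(6, 15), (8, 13)]))
        assert call.label == "LD" and call.k == 2 and call.crossing_count == 0

    def test_ordinals_ignore_free_cysteines(self):
        rec = _dsb_record(18, [(6, 15), (8, 13)], seq_char="C")  # all-Cys chain
        assert classify_peptide_topology(rec).label == "LD"

    def test_no_disulfide_signal(self):
        rec = PeptideRecord(
            chain=ResidueChain.from_sequence("t", "ACDEFGHIK"),
            synthesis=Synthesis.RIBOSOMAL,
        )
        with pytest.raises(NotDisulfideCyclic):
            classify_peptide_topology(rec)

    def test_shared_position_conflict(self):
        with pytest.raises(BondConflictError):
            classify_peptide_topology(_dsb_record(18, [(6, 15), (6, 13)]))

    def test_strict_three_class_folds_mixed_into_sr(self):
        rec = _dsb_record(22, [(1, 22), (5, 9), (13, 17)])
        assert classify_peptide_topology(rec).label == "MIXED"
        assert classify_peptide_topology(rec, strict_three_class=True).label == "SR"
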