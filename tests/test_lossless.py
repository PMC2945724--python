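"""Lossless certification: cost automata, budget automata, DP vs oracle."""

import itertools
import math

import numpy as np
import pytest

from colorseed.lossless import (
    CostScheme,
    build_cost_automaton,
    build_error_combo_automaton,
    build_snp_error_automaton,
    brute_force_lossless,
    check_lossless,
    check_lossless_combo,
    check_lossless_cost,
    check_lossless_snp_err,
    event_combination_cost,
    min_cost_dp,
    mismatch_count_automaton,
)
from colorseed.seeds import PositionedSeed, SeedFamily, SpacedSeed, family_hits

from conftest import random_positioned_family


def snp_err_predicate(string: str, k: int, h: int) -> bool:
    """Independent membership test: can the mismatches be covered by at
    most k adjacent pairs plus h singletons?  Tries every per-run pairing
    count explicitly."""
    runs = [len(r) for r in string.split("1") if r]
    choices = [range(r // 2 + 1) for r in runs]
    for pairing in itertools.product(*choices):
        pairs = sum(pairing)
        singles = sum(r - 2 * p for r, p in zip(runs, pairing))
        if pairs <= k and singles <= h:
            return True
    return not runs


class TestCostAutomaton:
    @pytest.mark.parametrize(
        "string,cost",
        [
            ("111111", 0),
            ("110011", 3),  # one SNP: 2 + 1
            ("110111", 2),  # one reading error
            ("1I11", 4),  # one indel, no mismatch
            ("1I011", 4),  # indel plus its free color change
            ("10I011", 6),  # mismatch(2) + indel(4) + free mismatch(0)
            ("000111", 4),  # run of three mismatches: 2 + 1 + 1
            ("011011", 4),  # two isolated mismatches, each the full 2
        ],
    )
    def test_context_costs(self, string, cost):
        aut = build_cost_automaton(CostScheme())
        assert aut.path_cost(string) == cost

    def test_post_indel_discount_chains_to_adjacency(self):
        # I then two mismatches: free + adjacent-discounted
        aut = build_cost_automaton(CostScheme())
        assert aut.path_cost("I00") == 4 + 0 + 1


class TestSnpErrorAutomaton:
    @pytest.mark.parametrize("k,h", [(0, 0), (1, 0), (0, 2), (1, 2), (2, 1)])
    def test_language_matches_predicate(self, k, h):
        aut = build_snp_error_automaton(k, h)
        for m in (1, 4, 7, 9):
            for bits in itertools.product("10", repeat=m):
                s = "".join(bits)
                assert aut.accepts(s) == snp_err_predicate(s, k, h), (k, h, s)

    def test_zero_budget_accepts_only_all_match(self):
        aut = build_snp_error_automaton(0, 0)
        assert aut.accepts("1111")
        assert not aut.accepts("1101")

    def test_one_snp_examples(self):
        aut = build_snp_error_automaton(1, 0)
        assert aut.accepts("0011")  # adjacent pair
        assert aut.accepts("1001")  # adjacent pair at 1,2
        assert not aut.accepts("0101")  # two isolated mismatches
        assert not aut.accepts("0110")  # isolated at both ends


class TestComboAutomaton:
    def test_indel_with_optional_free_mismatch(self):
        aut = build_error_combo_automaton(1, 0, 0)
        assert aut.accepts("1I11")
        assert aut.accepts("1I011")  # the indel's own color change is free
        assert not aut.accepts("1I0011")  # second mismatch is a real error
        assert not aut.accepts("10I11")  # mismatch before the indel counts
        assert not aut.accepts("1I1I1")  # two indels

    def test_reduces_to_snp_error_automaton_without_indels(self):
        a = build_error_combo_automaton(0, 1, 2)
        b = build_snp_error_automaton(1, 2)
        for bits in itertools.product("10", repeat=8):
            s = "".join(bits)
            assert a.accepts(s) == b.accepts(s)


class TestMinCostDP:
    def test_contiguous_seed_one_mismatch_witness(self):
        fam = SeedFamily((PositionedSeed(SpacedSeed("###"), (0, 1, 2)),), 5)
        verdict = check_lossless(fam, mismatch_count_automaton(), threshold=1)
        assert not verdict.lossless
        assert verdict.min_missed_cost == 1
        assert verdict.witness == "11011"  # the unique missed 1-mismatch string

    def test_zero_budget_always_lossless_with_feasible_placement(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng)
            verdict = check_lossless(fam, mismatch_count_automaton(), threshold=0)
            assert verdict.lossless

    def test_full_span_seed_fails_single_mismatch(self):
        m = 6
        fam = SeedFamily((PositionedSeed(SpacedSeed("#" * m), (0,)),), m)
        verdict = check_lossless(fam, mismatch_count_automaton(), threshold=1)
        assert not verdict.lossless
        assert verdict.min_missed_cost == 1

    def test_needs_costs(self):
        from colorseed.automata import seed_to_dfa

        with pytest.raises(ValueError):
            min_cost_dp(seed_to_dfa(SpacedSeed("##")), 4, 0)


class TestVerdictProperties:
    def test_threshold_monotone(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng, n_members=2, m_range=(10, 16))
            verdicts = [
                check_lossless(fam, mismatch_count_automaton(), threshold=t)
                for t in range(4)
            ]
            # lossless at t implies lossless at every smaller threshold
            for lo, hi in zip(verdicts, verdicts[1:]):
                assert not (hi.lossless and not lo.lossless)

    def test_position_monotone(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng, m_range=(8, 14))
            mem = fam.members[0]
            m = fam.read_length
            unused = sorted(
                set(range(m - mem.seed.span + 1)) - set(mem.positions)
            )
            if not unused:
                continue
            bigger = SeedFamily(
                (PositionedSeed(mem.seed, mem.positions + (unused[-1],)),), m
            )
            for k in (1, 2):
                small = check_lossless_snp_err(fam, k, 0).lossless
                if small:
                    assert check_lossless_snp_err(bigger, k, 0).lossless

    def test_stability_under_longer_reads(self, rng):
        """A positioned family lossless at m stays lossless at m+1..m+4."""
        found = 0
        for _ in range(30):
            fam = random_positioned_family(
                rng, n_members=2, w_range=(2, 4), max_gaps=1,
                m_range=(6, 10), n_pos_range=(2, 4),
            )
            base = check_lossless_snp_err(fam, 1, 0)
            if not base.lossless:
                continue
            found += 1
            for extra in range(1, 5):
                assert check_lossless_snp_err(
                    fam, 1, 0, m=fam.read_length + extra
                ).lossless
        assert found > 0

    def test_nonconsecutive_snps_cover_consecutive_snps(self, rng):
        """Lossless for k nonconsecutive SNPs implies every alignment
        with k consecutive SNPs (a run of k+1 mismatches) is hit."""
        k = 2
        # seed '##' at all positions, m=10: any in-class string (<= 4
        # mismatches) keeps two adjacent matches somewhere
        certified = [
            SeedFamily((PositionedSeed(SpacedSeed("##"), tuple(range(9))),), 10)
        ]
        for _ in range(40):
            fam = random_positioned_family(
                rng, n_members=2, w_range=(2, 3), max_gaps=1,
                m_range=(6, 9), n_pos_range=(2, 4),
            )
            if check_lossless_snp_err(fam, k, 0).lossless:
                certified.append(fam)
        assert check_lossless_snp_err(certified[0], k, 0).lossless
        for fam in certified:
            m = fam.read_length
            for start in range(m - k):
                s = "1" * start + "0" * (k + 1) + "1" * (m - start - k - 1)
                assert family_hits(fam, s)


class TestDPAgainstOracle:
    def test_random_families_snp_err_budgets(self, rng):
        for _ in range(40):
            fam = random_positioned_family(
                rng, n_members=int(rng.integers(1, 3)),
                w_range=(3, 6), max_gaps=3, m_range=(8, 16), n_pos_range=(1, 5),
            )
            k = int(rng.integers(0, 2))
            h = int(rng.integers(0, 3))
            constraint = build_snp_error_automaton(k, h)
            dp = check_lossless_snp_err(fam, k, h)
            bf = brute_force_lossless(
                fam, constraint, fam.read_length, 2 * k + h
            )
            assert dp.lossless == bf.lossless
            assert dp.min_missed_cost == bf.min_missed_cost
            if not dp.lossless:
                # the DP witness really is a missed in-class alignment
                assert constraint.accepts(dp.witness)
                assert not family_hits(fam, dp.witness)

    def test_random_families_with_indels(self, rng):
        for _ in range(12):
            fam = random_positioned_family(
                rng, n_members=2, w_range=(2, 4), max_gaps=2,
                m_range=(6, 10), n_pos_range=(2, 4),
            )
            combo = (1, int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            constraint = build_error_combo_automaton(*combo)
            budget = 2 * combo[0] + 2 * combo[1] + combo[2]
            dp = check_lossless_combo(fam, *combo)
            bf = brute_force_lossless(fam, constraint, fam.read_length, budget)
            assert dp.lossless == bf.lossless
            assert dp.min_missed_cost == bf.min_missed_cost

    def test_guard_rejects_huge_enumerations(self):
        fam = SeedFamily((PositionedSeed(SpacedSeed("####"), (0,)),), 20)
        with pytest.raises(ValueError, match="guard"):
            brute_force_lossless(
                fam, build_cost_automaton(CostScheme()), 20, 40, guard=10
            )


def test_four_error_combination_costs():
    """The four certified combinations all fit within total cost 7, with
    the maximum attained: indel+SNP = 4+3, SNP+2 errors = 3+2+2."""
    scheme = CostScheme()
    combos = {
        (1, 1, 0): 7,  # 1 indel + 1 SNP
        (1, 0, 1): 6,  # 1 indel + 1 reading error
        (0, 2, 0): 6,  # 2 SNPs
        (0, 1, 2): 7,  # 1 SNP + 2 reading errors
    }
    costs = {
        combo: event_combination_cost(scheme, *combo) for combo in combos
    }
    assert costs == combos
    assert max(costs.values()) == scheme.threshold == 7
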