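"""Seed automata, position chains, products, and the indel extension."""

import itertools

import numpy as np
import pytest

from colorseed.automata import (
    AlignmentDFA,
    family_to_dfa,
    indel_extend,
    make_absorbing,
    minimize_dfa,
    position_chain,
    positioned_seed_dfa,
    product,
    seed_occurrence_dfa,
    seed_to_dfa,
)
from colorseed.seeds import PositionedSeed, SeedFamily, SpacedSeed, family_hits, seed_hits

from conftest import random_positioned_family


def binary_strings(n):
    return ("".join(bits) for bits in itertools.product("10", repeat=n))


def contains_hit(seed, string):
    return any(
        seed_hits(seed, string, off) for off in range(len(string) - seed.span + 1)
    )


class TestSeedDFA:
    def test_contiguous_seed_language(self):
        dfa = seed_to_dfa(SpacedSeed("###"))
        assert dfa.n_states <= 4
        assert dfa.accepts("111")
        assert dfa.accepts("0111")
        assert not dfa.accepts("110")
        assert not dfa.accepts("110110")
        assert dfa.accepts("0101110")

    def test_gapped_seed_language(self):
        dfa = seed_to_dfa(SpacedSeed("#-#"))
        for s in binary_strings(3):
            assert dfa.accepts(s) == (s[0] == "1" and s[2] == "1")

    def test_finals_absorbing(self):
        assert seed_to_dfa(SpacedSeed("##-#")).finals_absorbing()

    @pytest.mark.parametrize(
        "pattern", ["####-##-####", "#-########-#", "####-#-------#-####"]
    )
    def test_language_matches_brute_force_scan(self, pattern, rng):
        seed = SpacedSeed(pattern)
        dfa = seed_to_dfa(seed)
        for _ in range(200):
            n = int(rng.integers(seed.span, seed.span + 8))
            s = "".join(rng.choice(list("10"), n))
            assert dfa.accepts(s) == contains_hit(seed, s)

    def test_state_bound_sweep(self, rng):
        """Minimal seed DFA never exceeds (w+1) * 2^(s-w) states."""
        for _ in range(40):
            w = int(rng.integers(2, 11))
            g = int(rng.integers(0, 7))
            s = w + g
            pat = ["#"] * s
            if g:
                for i in rng.choice(s - 2, g, replace=False) + 1:
                    pat[i] = "-"
            seed = SpacedSeed("".join(pat))
            dfa = seed_to_dfa(seed)
            assert dfa.n_states <= (w + 1) * 2 ** (s - w)

    def test_printed_seed_meets_bound(self):
        dfa = seed_to_dfa(SpacedSeed("####-##-####"))
        assert dfa.n_states <= 44  # (10 + 1) * 2^2


class TestPositionChain:
    def test_final_rule(self):
        chain = position_chain(4, 2, {0})
        assert list(np.nonzero(chain.finals)[0]) == [2]
        chain = position_chain(4, 2, {0, 1, 2})
        assert list(np.nonzero(chain.finals)[0]) == [2, 3, 4]

    def test_span_exceeding_read_rejected(self):
        with pytest.raises(ValueError):
            position_chain(4, 5, {0})

    def test_empty_positions_warn(self):
        with pytest.warns(UserWarning):
            position_chain(4, 2, set())


class TestProduct:
    def test_position_restriction(self):
        dfa = positioned_seed_dfa(SpacedSeed("##"), {1}, 3)
        assert dfa.accepts("011")
        assert dfa.accepts("111")
        assert not dfa.accepts("110")

    def test_alphabet_mismatch_rejected(self):
        two = seed_to_dfa(SpacedSeed("##"))
        three = indel_extend(two)
        with pytest.raises(ValueError, match="lphabet"):
            product(two, three)

    @pytest.mark.parametrize("pattern,m", [("##-#", 8), ("#-#", 7), ("###", 6)])
    def test_full_position_chain_is_vacuous(self, pattern, m):
        """Restricting to every valid position accepts exactly the
        strings of length <= m containing a hit."""
        seed = SpacedSeed(pattern)
        dfa = positioned_seed_dfa(seed, range(m - seed.span + 1), m)
        plain = seed_to_dfa(seed)
        for n in range(m + 1):
            for s in binary_strings(n):
                assert dfa.accepts(s) == plain.accepts(s)

    def test_economical_position_product_bound(self, rng):
        """Reachable size of the position-restricted automaton stays
        within (w+1) * 2^(s-w) * |P| + m."""
        for _ in range(40):
            fam = random_positioned_family(
                rng, w_range=(3, 9), max_gaps=5, m_range=(10, 34), n_pos_range=(1, 8)
            )
            mem = fam.members[0]
            w, s = mem.seed.weight, mem.seed.span
            dfa = family_to_dfa(fam)
            bound = (w + 1) * 2 ** (s - w) * len(mem.positions) + fam.read_length
            assert dfa.n_states <= bound


class TestFamilyDFA:
    def test_single_member_equals_seed_chain_product(self, rng):
        for _ in range(15):
            fam = random_positioned_family(rng, m_range=(6, 10))
            mem = fam.members[0]
            via_product = positioned_seed_dfa(
                mem.seed, mem.positions, fam.read_length
            )
            via_threads = family_to_dfa(fam)
            for s in binary_strings(fam.read_length):
                assert via_threads.accepts(s) == via_product.accepts(s)

    def test_two_member_union(self):
        a = PositionedSeed(SpacedSeed("##"), (0,))
        b = PositionedSeed(SpacedSeed("##"), (3,))
        fam = SeedFamily((a, b), 5)
        dfa = family_to_dfa(fam)
        only_a = family_to_dfa(SeedFamily((a,), 5))
        only_b = family_to_dfa(SeedFamily((b,), 5))
        for s in binary_strings(5):
            assert dfa.accepts(s) == (only_a.accepts(s) or only_b.accepts(s))

    def test_matches_direct_scan_on_random_strings(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng, n_members=2, m_range=(8, 14))
            dfa = family_to_dfa(fam)
            for _ in range(100):
                s = "".join(rng.choice(list("10"), fam.read_length))
                assert dfa.accepts(s) == family_hits(fam, s)

    def test_finals_absorbing_structurally(self, rng, lossless_family):
        assert family_to_dfa(lossless_family).finals_absorbing()
        for _ in range(5):
            fam = random_positioned_family(rng)
            assert family_to_dfa(fam).finals_absorbing()


class TestIndelExtension:
    def test_indel_resets_partial_matches(self):
        fam = SeedFamily(
            (PositionedSeed(SpacedSeed("##"), (0, 1, 2)),), 4
        )
        dfa = indel_extend(family_to_dfa(fam))
        assert dfa.accepts("1I11")  # window on read positions 1,2
        assert not dfa.accepts("1I1")
        assert not dfa.accepts("0I10")

    def test_conservative_on_indel_free_strings(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng, m_range=(6, 12))
            base = family_to_dfa(fam)
            ext = indel_extend(base)
            for s in binary_strings(min(fam.read_length, 10)):
                assert ext.accepts(s) == base.accepts(s)

    def test_agrees_with_read_coordinate_scan(self, rng):
        for _ in range(10):
            fam = random_positioned_family(rng, n_members=2, m_range=(6, 12))
            dfa = indel_extend(family_to_dfa(fam))
            for _ in range(150):
                s = "".join(
                    rng.choice(list("10I"), fam.read_length, p=[0.6, 0.25, 0.15])
                )
                assert dfa.accepts(s) == family_hits(fam, s)

    def test_requires_binary_automaton(self):
        three = indel_extend(seed_to_dfa(SpacedSeed("##")))
        with pytest.raises(ValueError):
            indel_extend(three)


class TestDumpLoad:
    def test_round_trip(self, tmp_path):
        dfa = positioned_seed_dfa(SpacedSeed("#-##"), {0, 2}, 8)
        path = tmp_path / "aut.txt"
        dfa.dump(path)
        back = AlignmentDFA.load(path)
        assert back.initial == dfa.initial
        for s in binary_strings(8):
            assert back.accepts(s) == dfa.accepts(s)

    def test_costs_preserved(self, tmp_path):
        from colorseed.lossless import CostScheme, build_cost_automaton

        dfa = build_cost_automaton(CostScheme())
        path = tmp_path / "cost.txt"
        dfa.dump(path)
        back = AlignmentDFA.load(path)
        assert np.array_equal(back.cost, dfa.cost)
        assert np.array_equal(back.delta, dfa.delta)


def test_minimize_preserves_language(rng):
    seed = SpacedSeed("##--#-#")
    raw = seed_to_dfa(seed, minimized=False)
    mini = minimize_dfa(raw)
    assert mini.n_states <= raw.n_states
    for s in binary_strings(9):
        assert mini.accepts(s) == raw.accepts(s)
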