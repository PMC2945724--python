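"""Lossless certification of seed families.

A family is *lossless* for a class of alignments when it hits every
alignment in the class.  The class is described by a constraint automaton
— either an error-budget automaton (at most k SNPs and h isolated
reading errors) or a cost automaton (total event cost at most a
threshold, with the scheme: match 0, color mismatch 2, second adjacent
mismatch 1 so that one SNP totals 3, indel 4, post-indel mismatch 0).

Certification intersects the family automaton with the constraint and
runs a per-state minimal-cost dynamic program: the family is lossless iff
after m steps every state that the family does not accept but the
constraint does requires a cost above the threshold.  A cheapest missed
alignment (witness) is reconstructed from backpointers on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .automata import (
    INDEL,
    MATCH,
    MISMATCH,
    SYMBOL_CHARS,
    AlignmentDFA,
    family_to_dfa,
    indel_extend,
    product,
)
from .seeds import SeedFamily, family_hits

__all__ = [
    "CostScheme",
    "LosslessVerdict",
    "build_cost_automaton",
    "build_snp_error_automaton",
    "build_error_combo_automaton",
    "mismatch_count_automaton",
    "min_cost_dp",
    "check_lossless",
    "check_lossless_cost",
    "check_lossless_snp_err",
    "check_lossless_combo",
    "brute_force_lossless",
    "event_combination_cost",
]

_INF = np.iinfo(np.int64).max // 4


@dataclass(frozen=True)
class CostScheme:
    """Per-event alignment costs with context rules.

    An isolated SNP (two adjacent color mismatches) totals
    ``mismatch_cost + snp_adjacent_cost`` = 3 by default; a mismatch
    directly after an indel is the indel's own color artifact and is
    free.
    """

    match_cost: int = 0
    mismatch_cost: int = 2
    snp_adjacent_cost: int = 1
    indel_cost: int = 4
    post_indel_mismatch_cost: int = 0
    threshold: int = 7

    def __post_init__(self) -> None:
        for name in (
            "match_cost",
            "mismatch_cost",
            "snp_adjacent_cost",
            "indel_cost",
            "post_indel_mismatch_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative integer")


def event_combination_cost(
    scheme: CostScheme, indels: int = 0, snps: int = 0, errors: int = 0
) -> int:
    """Total cost of a combination of isolated events under the scheme."""
    snp_cost = scheme.mismatch_cost + scheme.snp_adjacent_cost
    return (
        indels * scheme.indel_cost + snps * snp_cost + errors * scheme.mismatch_cost
    )


@dataclass(frozen=True)
class LosslessVerdict:
    lossless: bool
    min_missed_cost: float  # math.inf when every in-class alignment is hit
    witness: str | None
    threshold: int

    def __post_init__(self) -> None:
        if self.lossless != (self.min_missed_cost > self.threshold):
            raise ValueError("inconsistent verdict")


# ---------------------------------------------------------------------------
# constraint automata
# ---------------------------------------------------------------------------

def build_cost_automaton(scheme: CostScheme) -> AlignmentDFA:
    """Three context states (after-match, after-mismatch, after-indel)
    carrying the per-transition costs of the scheme.  Every state is
    accepting: membership in the class is a matter of total cost, which
    the dynamic program tracks against the threshold.

    A string never begins with the "second mismatch of a SNP": the start
    context is after-match, so a leading mismatch costs the full
    ``mismatch_cost``.  A post-indel (free) mismatch moves to the
    after-mismatch context, keeping the adjacent-mismatch discount
    available for a following mismatch.
    """
    AM, AX, AI = 0, 1, 2  # after-match, after-mismatch, after-indel
    delta = np.zeros((3, 3), dtype=np.int64)
    cost = np.zeros((3, 3), dtype=np.int64)
    for src in (AM, AX, AI):
        delta[src, MATCH] = AM
        cost[src, MATCH] = scheme.match_cost
        delta[src, MISMATCH] = AX
        delta[src, INDEL] = AI
        cost[src, INDEL] = scheme.indel_cost
    cost[AM, MISMATCH] = scheme.mismatch_cost
    cost[AX, MISMATCH] = scheme.snp_adjacent_cost
    cost[AI, MISMATCH] = scheme.post_indel_mismatch_cost
    finals = np.ones(3, dtype=bool)
    return AlignmentDFA(delta, AM, finals, cost=cost,
                        labels=["after_match", "after_mismatch", "after_indel"])


def build_snp_error_automaton(k: int, h: int) -> AlignmentDFA:
    """Binary-alphabet automaton accepting the alignments with at most
    ``k`` SNPs (adjacent mismatch pairs) and ``h`` isolated reading
    errors.

    Equivalently: at most ``2k + h`` mismatches of which all but at most
    ``h`` can be grouped into disjoint adjacent pairs.  The state tracks
    the capped mismatch count R, the capped number of completable pairs
    P, and whether the current mismatch run has a dangling unpaired
    mismatch; acceptance is ``R - 2 * min(P, k) <= h``.  Transition costs
    count mismatches, so the certification DP reports the number of
    mismatches of a cheapest missed in-class alignment.
    """
    if k < 0 or h < 0:
        raise ValueError("budgets must be non-negative")
    r_cap = 2 * k + h + 1
    index: dict[tuple[int, int, int], int] = {}
    order: list[tuple[int, int, int]] = []

    def intern(key):
        if key not in index:
            index[key] = len(order)
            order.append(key)
        return index[key]

    initial = intern((0, 0, 0))
    frontier = [(0, 0, 0)]
    trans: list[tuple[int, int, int]] = []
    while frontier:
        key = frontier.pop()
        r, p, d = key
        for a, nxt in (
            (MATCH, (r, p, 0)),
            (MISMATCH, (min(r + 1, r_cap), min(p + 1, k) if d else p, 0 if d else 1)),
        ):
            if nxt not in index:
                intern(nxt)
                frontier.append(nxt)
            trans.append((index[key], a, index[nxt]))
    n = len(order)
    delta = np.zeros((n, 2), dtype=np.int64)
    for u, a, v in trans:
        delta[u, a] = v
    cost = np.zeros((n, 2), dtype=np.int64)
    cost[:, MISMATCH] = 1
    finals = np.array([r - 2 * min(p, k) <= h for r, p, d in order], dtype=bool)
    return AlignmentDFA(delta, initial, finals, cost=cost, labels=order)


def build_error_combo_automaton(n_indels: int, n_snps: int, n_errors: int) -> AlignmentDFA:
    """Automaton for a bounded combination of events: at most ``n_indels``
    color indels (each optionally followed by one free color mismatch),
    ``n_snps`` SNPs, and ``n_errors`` isolated reading errors.

    Two-symbol when ``n_indels`` is 0, three-symbol otherwise.  Costs
    count error symbols (mismatches and indels), so a cheapest missed
    alignment minimizes its number of corrupted colors.
    """
    if min(n_indels, n_snps, n_errors) < 0:
        raise ValueError("budgets must be non-negative")
    k_sym = 3 if n_indels > 0 else 2
    r_cap = 2 * n_snps + n_errors + 1
    i_cap = n_indels + 1
    # state: (indels used, mismatches R, pairs P, dangling, post-indel flag)
    index: dict[tuple, int] = {}
    order: list[tuple] = []

    def intern(key):
        if key not in index:
            index[key] = len(order)
            order.append(key)
        return index[key]

    initial = intern((0, 0, 0, 0, 0))
    frontier = [(0, 0, 0, 0, 0)]
    trans = []
    while frontier:
        key = frontier.pop()
        u, r, p, d, post = key
        succ = [(MATCH, (u, r, p, 0, 0))]
        if post:
            # mismatch right after an indel: the indel's own color change
            succ.append((MISMATCH, (u, r, p, 0, 0)))
        else:
            succ.append(
                (MISMATCH,
                 (u, min(r + 1, r_cap), min(p + 1, n_snps) if d else p, 0 if d else 1, 0))
            )
        if k_sym == 3:
            succ.append((INDEL, (min(u + 1, i_cap), r, p, 0, 1)))
        for a, nxt in succ:
            if nxt not in index:
                intern(nxt)
                frontier.append(nxt)
            trans.append((index[key], a, index[nxt]))
    n = len(order)
    delta = np.zeros((n, k_sym), dtype=np.int64)
    for u_, a, v in trans:
        delta[u_, a] = v
    cost = np.zeros((n, k_sym), dtype=np.int64)
    cost[:, MISMATCH] = 1
    if k_sym == 3:
        cost[:, INDEL] = 1
    finals = np.array(
        [
            u <= n_indels and r - 2 * min(p, n_snps) <= n_errors
            for u, r, p, d, post in order
        ],
        dtype=bool,
    )
    return AlignmentDFA(delta, initial, finals, cost=cost, labels=order)


def mismatch_count_automaton() -> AlignmentDFA:
    """One-state binary automaton whose cost counts mismatches — the
    constraint for the plain k-mismatch lossless framework."""
    delta = np.zeros((1, 2), dtype=np.int64)
    cost = np.zeros((1, 2), dtype=np.int64)
    cost[0, MISMATCH] = 1
    return AlignmentDFA(delta, 0, np.ones(1, dtype=bool), cost=cost)


# ---------------------------------------------------------------------------
# the certification dynamic program
# ---------------------------------------------------------------------------

def min_cost_dp(
    dfa: AlignmentDFA,
    m: int,
    threshold: int,
    miss_mask: np.ndarray | None = None,
    want_witness: bool = True,
) -> LosslessVerdict:
    """Per-state minimal-cost dynamic program over ``m`` steps.

    ``D_i[q]`` is the minimal total transition cost of reaching state
    ``q`` with ``i`` symbols.  The family is lossless iff every state in
    ``miss_mask`` (default: the non-final states) costs more than
    ``threshold`` at step ``m``.  Two rolling rows are used; backpointers
    for witness reconstruction are kept only on demand and break ties
    toward the lexicographically smallest string (match < mismatch <
    indel).
    """
    if dfa.cost is None:
        raise ValueError("min_cost_dp needs per-transition costs")
    n, k = dfa.delta.shape
    if miss_mask is None:
        miss_mask = ~dfa.finals
    D = np.full(n, _INF, dtype=np.int64)
    D[dfa.initial] = 0
    par_state = np.zeros((m, n), dtype=np.int64) if want_witness else None
    par_sym = np.full((m, n), -1, dtype=np.int8) if want_witness else None
    state_ids = np.arange(n)
    for t in range(m):
        D2 = np.full(n, _INF, dtype=np.int64)
        for a in range(k):  # ascending symbol order = lexicographic ties
            cand = D + dfa.cost[:, a]
            targets = dfa.delta[:, a]
            # per-target minimum with a deterministic argmin
            order = np.lexsort((state_ids, cand, targets))
            tgt_sorted = targets[order]
            first = np.ones(n, dtype=bool)
            first[1:] = tgt_sorted[1:] != tgt_sorted[:-1]
            sel = order[first]
            tgt = targets[sel]
            better = cand[sel] < D2[tgt]
            upd_t = tgt[better]
            D2[upd_t] = cand[sel][better]
            if want_witness:
                par_state[t, upd_t] = sel[better]
                par_sym[t, upd_t] = a
        D = D2
    missed = miss_mask & (D < _INF)
    if not missed.any():
        return LosslessVerdict(True, math.inf, None, threshold)
    min_cost = int(D[missed].min())
    lossless = min_cost > threshold
    witness = None
    if not lossless and want_witness:
        q = int(state_ids[missed][np.argmin(D[missed])])
        chars = []
        for t in range(m - 1, -1, -1):
            a = int(par_sym[t, q])
            chars.append(SYMBOL_CHARS[a])
            q = int(par_state[t, q])
        witness = "".join(reversed(chars))
    return LosslessVerdict(lossless, float(min_cost), witness, threshold)


def check_lossless(
    family: SeedFamily,
    constraint: AlignmentDFA,
    threshold: int,
    m: int | None = None,
    want_witness: bool = True,
) -> LosslessVerdict:
    """Certify a family against a constraint automaton.

    Intersects the family automaton with the constraint (extending the
    family to the indel alphabet when the constraint uses it) and runs
    :func:`min_cost_dp`.  A length-m string counts as missed iff the
    constraint accepts it within the cost threshold and no family member
    hits it.
    """
    if m is None:
        m = family.read_length
    elif m < family.read_length:
        raise ValueError(
            "certification horizon must be at least the family read length"
        )
    fam = family_to_dfa(
        family if m == family.read_length
        else SeedFamily(family.members, m)
    )
    if constraint.n_symbols == 3:
        fam = indel_extend(fam)
    prod = product(fam, constraint, final_rule="and")
    fam_final, cons_final = prod.component_finals
    miss_mask = (~fam_final) & cons_final
    return min_cost_dp(prod, m, threshold, miss_mask, want_witness)


def check_lossless_cost(
    family: SeedFamily,
    scheme: CostScheme | None = None,
    m: int | None = None,
    want_witness: bool = True,
) -> LosslessVerdict:
    """Lossless under a total-cost budget with context rules."""
    scheme = scheme or CostScheme()
    return check_lossless(
        family, build_cost_automaton(scheme), scheme.threshold, m, want_witness
    )


def check_lossless_snp_err(
    family: SeedFamily,
    k: int,
    h: int,
    m: int | None = None,
    want_witness: bool = True,
) -> LosslessVerdict:
    """Lossless for at most k SNPs plus h isolated reading errors."""
    return check_lossless(
        family, build_snp_error_automaton(k, h), 2 * k + h, m, want_witness
    )


def check_lossless_combo(
    family: SeedFamily,
    n_indels: int,
    n_snps: int,
    n_errors: int,
    m: int | None = None,
    want_witness: bool = True,
) -> LosslessVerdict:
    """Lossless for a bounded event combination (indels, SNPs, errors)."""
    budget = 2 * n_indels + 2 * n_snps + n_errors  # max corrupted colors
    return check_lossless(
        family,
        build_error_combo_automaton(n_indels, n_snps, n_errors),
        budget,
        m,
        want_witness,
    )


def brute_force_lossless(
    family: SeedFamily,
    constraint: AlignmentDFA,
    m: int,
    threshold: int,
    guard: int = 10**6,
) -> LosslessVerdict:
    """Enumeration oracle: depth-first generation of every in-budget
    string accepted by the constraint, each tested with the direct hit
    scan.  Exact but exponential; guarded by a candidate-count limit."""
    k = constraint.n_symbols
    cost = constraint.cost
    if cost is None:
        cost = np.zeros((constraint.n_states, k), dtype=np.int64)
    best_cost = math.inf
    best_witness = None
    candidates = 0
    chars: list[str] = []

    def dfs(depth: int, state: int, acc: int):
        nonlocal best_cost, best_witness, candidates
        if depth == m:
            if not constraint.finals[state]:
                return
            candidates += 1
            if candidates > guard:
                raise ValueError(f"enumeration guard of {guard} candidates exceeded")
            s = "".join(chars)
            if not family_hits(family, s) and acc < best_cost:
                best_cost = acc
                best_witness = s
            return
        for a in range(k):
            c = acc + int(cost[state, a])
            if c > threshold:
                continue
            chars.append(SYMBOL_CHARS[a])
            dfs(depth + 1, int(constraint.delta[state, a]), c)
            chars.pop()

    dfs(0, constraint.initial, 0)
    lossless = best_cost > threshold
    return LosslessVerdict(lossless, best_cost, best_witness, threshold)
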