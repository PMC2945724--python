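"""Deterministic automata over the alignment alphabet.

Alignment strings describe a read-to-reference alignment one color per
symbol: ``1`` (match), ``0`` (mismatch), and in the 3-symbol mode ``I``
(color indel).  Seeds, position restrictions, and error budgets are all
compiled to automata over this alphabet so that sensitivity computation
and lossless certification reduce to dynamic programming over states.
"""

from __future__ import annotations

import warnings
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np

from .seeds import SeedFamily, SpacedSeed

__all__ = [
    "MATCH",
    "MISMATCH",
    "INDEL",
    "SYMBOL_CHARS",
    "AlignmentDFA",
    "seed_to_dfa",
    "seed_occurrence_dfa",
    "position_chain",
    "product",
    "make_absorbing",
    "positioned_seed_dfa",
    "family_to_dfa",
    "indel_extend",
    "minimize_dfa",
]

# Symbol indices.  The order MATCH < MISMATCH < INDEL is also the
# lexicographic tie-break order used for witness reconstruction.
MATCH, MISMATCH, INDEL = 0, 1, 2
SYMBOL_CHARS = "10I"
CHAR_TO_SYMBOL = {c: i for i, c in enumerate(SYMBOL_CHARS)}


@dataclass
class AlignmentDFA:
    """A total DFA over the 2- or 3-symbol alignment alphabet.

    ``delta[state, symbol]`` is the destination state; ``finals`` marks
    accepting states.  ``cost`` optionally attaches a non-negative integer
    to each transition.  ``restart`` optionally maps each state to the
    state representing the same position-progress with all partial seed
    matches forgotten; it is what makes the indel extension well defined.
    ``component_finals`` is set on product automata and records which
    states are final in each factor.
    """

    delta: np.ndarray
    initial: int
    finals: np.ndarray
    cost: np.ndarray | None = None
    restart: np.ndarray | None = None
    labels: list | None = None
    component_finals: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.finals = np.asarray(self.finals, dtype=bool)
        if self.cost is not None:
            self.cost = np.asarray(self.cost, dtype=np.int64)
        if self.restart is not None:
            self.restart = np.asarray(self.restart, dtype=np.int64)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.delta.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.delta.shape[1]

    def validate(self) -> None:
        n, k = self.delta.shape
        if k not in (2, 3):
            raise ValueError(f"alphabet must have 2 or 3 symbols, got {k}")
        if not (0 <= self.initial < n):
            raise ValueError("initial state out of range")
        if self.delta.min() < 0 or self.delta.max() >= n:
            raise ValueError("transition function not total over the state set")
        if self.finals.shape != (n,):
            raise ValueError("finals mask has wrong shape")
        if self.cost is not None:
            if self.cost.shape != (n, k):
                raise ValueError("cost array has wrong shape")
            if self.cost.min() < 0:
                raise ValueError("transition costs must be non-negative")

    def finals_absorbing(self) -> bool:
        """True iff every final state self-loops on every symbol."""
        idx = np.nonzero(self.finals)[0]
        return bool(np.all(self.delta[idx] == idx[:, None]))

    def accepts(self, string: str) -> bool:
        q = self.initial
        for ch in string:
            a = CHAR_TO_SYMBOL[ch]
            if a >= self.n_symbols:
                raise ValueError(f"symbol {ch!r} outside this automaton's alphabet")
            q = self.delta[q, a]
        return bool(self.finals[q])

    def path_cost(self, string: str) -> int:
        if self.cost is None:
            raise ValueError("automaton carries no costs")
        q, total = self.initial, 0
        for ch in string:
            a = CHAR_TO_SYMBOL[ch]
            total += int(self.cost[q, a])
            q = self.delta[q, a]
        return total

    # -- plain-text dump/load ------------------------------------------------

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"; alignment automaton, {self.n_symbols} symbols\n")
            fh.write(f"@ {self.initial}\n")
            fh.write("* " + " ".join(map(str, np.nonzero(self.finals)[0])) + "\n")
            for u in range(self.n_states):
                for a in range(self.n_symbols):
                    line = f"{u} {SYMBOL_CHARS[a]} {self.delta[u, a]}"
                    if self.cost is not None:
                        line += f" {self.cost[u, a]}"
                    fh.write(line + "\n")

    @classmethod
    def load(cls, path) -> "AlignmentDFA":
        initial = None
        finals_list: list[int] = []
        trans: list[tuple[int, int, int, int | None]] = []
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(";"):
                    continue
                parts = line.split()
                if parts[0] == "@":
                    initial = int(parts[1])
                elif parts[0] == "*":
                    finals_list = [int(x) for x in parts[1:]]
                else:
                    u, sym, v = int(parts[0]), parts[1], int(parts[2])
                    c = int(parts[3]) if len(parts) > 3 else None
                    trans.append((u, CHAR_TO_SYMBOL[sym], v, c))
        if initial is None or not trans:
            raise ValueError(f"malformed automaton file {path}")
        n = 1 + max(max(u, v) for u, _, v, _ in trans)
        k = 1 + max(a for _, a, _, _ in trans)
        delta = np.zeros((n, k), dtype=np.int64)
        has_cost = any(c is not None for *_, c in trans)
        cost = np.zeros((n, k), dtype=np.int64) if has_cost else None
        for u, a, v, c in trans:
            delta[u, a] = v
            if has_cost:
                cost[u, a] = c or 0
        finals = np.zeros(n, dtype=bool)
        finals[finals_list] = True
        return cls(delta, initial, finals, cost)


# ---------------------------------------------------------------------------
# generic BFS construction over hashable state keys
# ---------------------------------------------------------------------------

def _build_from_keys(
    initial_key: Hashable,
    n_symbols: int,
    step: Callable[[Hashable, int], Hashable],
    is_final: Callable[[Hashable], bool],
    extra_keys: Iterable[Hashable] = (),
    restart_key: Callable[[Hashable], Hashable] | None = None,
    cost_fn: Callable[[Hashable, int], int] | None = None,
) -> tuple[AlignmentDFA, dict]:
    index: dict[Hashable, int] = {}
    order: list[Hashable] = []

    def intern(key: Hashable) -> int:
        if key not in index:
            index[key] = len(order)
            order.append(key)
        return index[key]

    intern(initial_key)
    for k in extra_keys:
        intern(k)
    queue = deque(range(len(order)))
    delta_rows: list[list[int]] = []
    while queue:
        i = queue.popleft()
        while len(delta_rows) <= i:
            delta_rows.append([0] * n_symbols)
        key = order[i]
        for a in range(n_symbols):
            before = len(order)
            j = intern(step(key, a))
            if len(order) > before:
                queue.append(j)
            delta_rows[i][a] = j
    n = len(order)
    while len(delta_rows) < n:  # pragma: no cover - keys interned late
        delta_rows.append([0] * n_symbols)
    delta = np.array(delta_rows, dtype=np.int64)
    finals = np.array([is_final(k) for k in order], dtype=bool)
    restart = None
    if restart_key is not None:
        restart = np.array([index[restart_key(k)] for k in order], dtype=np.int64)
    cost = None
    if cost_fn is not None:
        cost = np.array(
            [[cost_fn(k, a) for a in range(n_symbols)] for k in order],
            dtype=np.int64,
        )
    dfa = AlignmentDFA(delta, 0, finals, cost=cost, restart=restart, labels=order)
    return dfa, index


# ---------------------------------------------------------------------------
# seed automata
# ---------------------------------------------------------------------------

_HIT = "HIT"


def seed_to_dfa(seed: SpacedSeed, minimized: bool = True) -> AlignmentDFA:
    """DFA accepting exactly the binary strings containing a seed hit.

    Built by subset construction over viable seed-prefix lengths and then
    minimized; the minimal automaton never exceeds the compact-construction
    bound of ``(w + 1) * 2^(s - w)`` states.  Final (hit) states are
    absorbing.
    """
    pat, s = seed.pattern, seed.span

    def step(key, a):
        if key == _HIT:
            return _HIT
        nxt = {0}
        for j in key:
            if pat[j] == "-" or a == MATCH:
                if j + 1 == s:
                    return _HIT
                nxt.add(j + 1)
        return frozenset(nxt)

    dfa, _ = _build_from_keys(
        frozenset([0]), 2, step, lambda k: k == _HIT
    )
    if minimized:
        dfa = minimize_dfa(dfa)
    dfa.restart = np.full(dfa.n_states, dfa.initial, dtype=np.int64)
    dfa.restart[np.nonzero(dfa.finals)[0]] = np.nonzero(dfa.finals)[0]
    return dfa


def seed_occurrence_dfa(seed: SpacedSeed, minimized: bool = True) -> AlignmentDFA:
    """DFA whose final states mark that a seed occurrence *ends at the
    current symbol* (non-absorbing).  This is the factor needed to combine
    a seed with a position chain: the product's finals then identify hits
    ending at allowed offsets."""
    pat, s = seed.pattern, seed.span

    def step(key, a):
        nxt = {0}
        for j in key:
            if j < s and (pat[j] == "-" or a == MATCH):
                nxt.add(j + 1)
        return frozenset(nxt)

    dfa, _ = _build_from_keys(frozenset([0]), 2, step, lambda k: s in k)
    if minimized:
        dfa = minimize_dfa(dfa)
    dfa.restart = np.full(dfa.n_states, dfa.initial, dtype=np.int64)
    return dfa


def minimize_dfa(dfa: AlignmentDFA) -> AlignmentDFA:
    """Language-preserving minimization by Moore partition refinement."""
    delta, finals = dfa.delta, dfa.finals
    n, k = delta.shape
    cls = finals.astype(np.int64)
    n_cls = len(np.unique(cls))
    while True:
        sig = np.column_stack([cls] + [cls[delta[:, a]] for a in range(k)])
        _, new_cls = np.unique(sig, axis=0, return_inverse=True)
        new_n = len(np.unique(new_cls))
        if new_n == n_cls:
            cls = new_cls
            break
        cls, n_cls = new_cls, new_n
    # representative per class
    reps = np.zeros(n_cls, dtype=np.int64)
    seen = np.zeros(n_cls, dtype=bool)
    for u in range(n):
        c = cls[u]
        if not seen[c]:
            reps[c] = u
            seen[c] = True
    new_delta = cls[delta[reps]]
    new_finals = finals[reps]
    restart = None
    if dfa.restart is not None:
        restart = cls[dfa.restart[reps]]
    return AlignmentDFA(new_delta, int(cls[dfa.initial]), new_finals, restart=restart)


# ---------------------------------------------------------------------------
# position chains and products
# ---------------------------------------------------------------------------

def position_chain(m: int, span: int, positions: Sequence[int]) -> AlignmentDFA:
    """Linear chain of ``m + 1`` states counting consumed symbols; state
    ``q_i`` is final iff ``i - span`` is an allowed start position."""
    pos = sorted(set(int(p) for p in positions))
    for p in pos:
        if p < 0 or p + span > m:
            raise ValueError(
                f"position {p} invalid for span {span} and read length {m}"
            )
    if not pos:
        warnings.warn("empty position set: the chain has no final state")
    pos_set = set(pos)
    delta = np.zeros((m + 1, 2), dtype=np.int64)
    for i in range(m):
        delta[i] = i + 1
    delta[m] = m
    finals = np.array([(i - span) in pos_set for i in range(m + 1)], dtype=bool)
    restart = np.arange(m + 1, dtype=np.int64)  # chains carry no match memory
    return AlignmentDFA(delta, 0, finals, restart=restart)


def product(a: AlignmentDFA, b: AlignmentDFA, final_rule: str = "and") -> AlignmentDFA:
    """Synchronous product over reachable pair states.

    ``final_rule`` is ``"and"`` or ``"or"``.  Costs, when present on
    either factor, add.  Restart maps compose componentwise when both
    factors carry one (the restart closure is included in the BFS).
    """
    if a.n_symbols != b.n_symbols:
        raise ValueError(
            f"alphabet mismatch: {a.n_symbols} vs {b.n_symbols} symbols"
        )
    if final_rule not in ("and", "or"):
        raise ValueError(f"final_rule must be 'and' or 'or', got {final_rule!r}")
    k = a.n_symbols
    have_restart = a.restart is not None and b.restart is not None
    have_cost = a.cost is not None or b.cost is not None

    def step(key, sym):
        u, v = key
        return (int(a.delta[u, sym]), int(b.delta[v, sym]))

    def is_final(key):
        u, v = key
        if final_rule == "and":
            return bool(a.finals[u] and b.finals[v])
        return bool(a.finals[u] or b.finals[v])

    def restart_key(key):
        u, v = key
        return (int(a.restart[u]), int(b.restart[v]))

    def cost_fn(key, sym):
        u, v = key
        c = 0
        if a.cost is not None:
            c += int(a.cost[u, sym])
        if b.cost is not None:
            c += int(b.cost[v, sym])
        return c

    initial = (a.initial, b.initial)
    extra: list = []
    if have_restart:
        # close over restart targets so indel extension stays total
        seen = {initial}
        frontier = [initial]
        while frontier:
            key = frontier.pop()
            r = restart_key(key)
            if r not in seen:
                seen.add(r)
                frontier.append(r)
            for sym in range(k):
                nk = step(key, sym)
                if nk not in seen:
                    seen.add(nk)
                    frontier.append(nk)
        extra = sorted(seen - {initial})
    dfa, index = _build_from_keys(
        initial,
        k,
        step,
        is_final,
        extra_keys=extra,
        restart_key=restart_key if have_restart else None,
        cost_fn=cost_fn if have_cost else None,
    )
    order = dfa.labels
    dfa.component_finals = (
        np.array([a.finals[u] for u, _ in order], dtype=bool),
        np.array([b.finals[v] for _, v in order], dtype=bool),
    )
    return dfa


def make_absorbing(dfa: AlignmentDFA) -> AlignmentDFA:
    """Copy of ``dfa`` in which final states self-loop on every symbol."""
    delta = dfa.delta.copy()
    idx = np.nonzero(dfa.finals)[0]
    delta[idx] = idx[:, None]
    cost = dfa.cost.copy() if dfa.cost is not None else None
    if cost is not None:
        cost[idx] = 0
    restart = dfa.restart.copy() if dfa.restart is not None else None
    if restart is not None:
        restart[idx] = idx
    return AlignmentDFA(
        delta,
        dfa.initial,
        dfa.finals.copy(),
        cost=cost,
        restart=restart,
        labels=dfa.labels,
        component_finals=dfa.component_finals,
    )


def positioned_seed_dfa(seed: SpacedSeed, positions: Sequence[int], m: int) -> AlignmentDFA:
    """Absorbing DFA for one position-restricted seed: accepts strings of
    length <= m in which a seed occurrence starts at an allowed position."""
    occ = seed_occurrence_dfa(seed)
    chain = position_chain(m, seed.span, positions)
    return make_absorbing(product(occ, chain, "and"))


def family_to_dfa(family: SeedFamily) -> AlignmentDFA:
    """Absorbing DFA for a whole family (OR over members and positions).

    Built directly as a placement-thread automaton: a state records the
    number of consumed symbols and the set of placements that are still
    viable; completing any placement jumps to the absorbing hit state.
    Backbone states with an empty thread set are always materialized so
    the automaton carries a total restart map (needed for indel support).
    """
    m = family.read_length
    placements: list[tuple[int, str, int]] = []
    for mem in family.members:
        for p in mem.positions:
            placements.append((p, mem.seed.pattern, mem.seed.span))
    starts_at: dict[int, list[int]] = defaultdict(list)
    for pid, (p, _, _) in enumerate(placements):
        starts_at[p].append(pid)

    def step(key, a):
        if key == _HIT:
            return _HIT
        i, S = key
        if i >= m:
            return (m, frozenset())
        surviving = []
        for pid in list(S) + starts_at.get(i, []):
            p, pat, s = placements[pid]
            j = i - p
            if pat[j] == "#" and a != MATCH:
                continue
            if j == s - 1:
                return _HIT
            surviving.append(pid)
        return (i + 1, frozenset(surviving))

    def restart_key(key):
        if key == _HIT:
            return _HIT
        return (key[0], frozenset())

    backbone = [(i, frozenset()) for i in range(m + 1)]
    dfa, _ = _build_from_keys(
        (0, frozenset()),
        2,
        step,
        lambda k: k == _HIT,
        extra_keys=backbone[1:],
        restart_key=restart_key,
    )
    return dfa


def indel_extend(dfa: AlignmentDFA) -> AlignmentDFA:
    """Extend a 2-symbol automaton to the 3-symbol alphabet.

    An indel behaves as a hard reset of all partial seed matches: no seed
    window may span it.  From a non-final state the indel transition goes
    to the state's restart image (empty match memory); the read-position
    counter of a position restriction does *not* advance, because an
    indel column carries no read color — allowed positions index the
    colors of the read, not alignment columns.  Final states remain
    absorbing.  On indel-free strings the extension agrees with the
    original automaton.
    """
    if dfa.n_symbols != 2:
        raise ValueError("indel_extend expects a 2-symbol automaton")
    restart = dfa.restart
    if restart is None:
        # no position bookkeeping: restarting means returning to the start
        restart = np.full(dfa.n_states, dfa.initial, dtype=np.int64)
        restart[dfa.finals] = np.nonzero(dfa.finals)[0]
    n = dfa.n_states
    delta = np.zeros((n, 3), dtype=np.int64)
    delta[:, :2] = dfa.delta
    indel_dst = restart.copy()
    idx_final = np.nonzero(dfa.finals)[0]
    indel_dst[idx_final] = idx_final
    delta[:, INDEL] = indel_dst
    cost = None
    if dfa.cost is not None:
        cost = np.zeros((n, 3), dtype=np.int64)
        cost[:, :2] = dfa.cost
    return AlignmentDFA(
        delta,
        dfa.initial,
        dfa.finals.copy(),
        cost=cost,
        restart=restart.copy(),
        labels=dfa.labels,
        component_finals=dfa.component_finals,
    )
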