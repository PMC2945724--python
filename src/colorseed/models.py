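"""Probabilistic transducers generating color-alignment symbol sequences.

An alignment model is a finite-state probability transducer (a
generalization of an HMM): each transition carries a transition
probability and an emission distribution over the alignment symbols
match / mismatch / indel.  Two sources of differences between a read and
the reference are modeled separately and composed:

* the SNP/indel model (genuine genomic differences): three states
  Match, SNP, Indel.  A SNP appears in color space as two adjacent color
  mismatches; a run of consecutive SNPs emits a match/mismatch mixture
  (0.25/0.75); a color indel is preceded by a color mismatch in 3/4 of
  cases and every transition out of the Indel state emits one indel
  color.

* the reading-error model: submodels indexed by the set of error-prone
  phases on a cycle of 5 read positions.  Transitions at a marked phase
  ("red" transitions) emit a mismatch with probability ``p_err``; with
  probability ``p_s`` per step the model switches one level up, marking
  the current phase.  The baseline error probability that rises along
  the read is layered on top via a position profile (max rule).

The two are combined by a dominance product: indel > mismatch > match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .automata import CHAR_TO_SYMBOL, INDEL, MATCH, MISMATCH, SYMBOL_CHARS
from .params import ModelParams

__all__ = [
    "ProbTransducer",
    "Transition",
    "PositionProfile",
    "linear_profile",
    "build_snp_indel_model",
    "build_reading_error_model",
    "apply_position_profile",
    "product_models",
    "alignment_probability",
    "batch_probabilities",
    "total_probability",
    "build_bernoulli_model",
    "lift_to_indel",
    "default_model",
]

_ATOL = 1e-12


@dataclass(frozen=True)
class Transition:
    src: int
    dst: int
    prob: float
    #: emission distribution: shape (n_symbols,) or (horizon, n_symbols)
    emission: np.ndarray


@dataclass
class ProbTransducer:
    n_states: int
    init: np.ndarray
    transitions: list[Transition]
    n_symbols: int
    horizon: int | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        if self.init.shape != (self.n_states,):
            raise ValueError("initial distribution has wrong shape")
        if abs(self.init.sum() - 1.0) > atol:
            raise ValueError("initial distribution must sum to 1")
        out = np.zeros(self.n_states)
        for tr in self.transitions:
            out[tr.src] += tr.prob
            em = np.asarray(tr.emission, dtype=float)
            if em.ndim == 1:
                if em.shape != (self.n_symbols,):
                    raise ValueError("emission row has wrong width")
                sums = np.array([em.sum()])
            else:
                if self.horizon is None or em.shape != (self.horizon, self.n_symbols):
                    raise ValueError("step-indexed emission has wrong shape")
                sums = em.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValueError(
                    f"emission of transition {tr.src}->{tr.dst} does not sum to 1"
                )
        reachable_src = {tr.src for tr in self.transitions}
        for q in range(self.n_states):
            if q in reachable_src and abs(out[q] - 1.0) > atol:
                raise ValueError(f"outgoing probabilities of state {q} sum to {out[q]}")

    @property
    def emits_indels(self) -> bool:
        if self.n_symbols < 3:
            return False
        return any(
            tr.prob > 0 and np.any(np.asarray(tr.emission)[..., INDEL] > 0)
            for tr in self.transitions
        )

    def emission_at(self, tr: Transition, step: int) -> np.ndarray:
        em = np.asarray(tr.emission)
        return em if em.ndim == 1 else em[step]

    def symbol_matrices(self, step: int) -> np.ndarray:
        """``W[a, u, v]``: probability of moving u -> v while emitting a
        at the given 0-based step."""
        W = np.zeros((self.n_symbols, self.n_states, self.n_states))
        for tr in self.transitions:
            e = self.emission_at(tr, step)
            W[:, tr.src, tr.dst] += tr.prob * e
        return W

    @property
    def step_dependent(self) -> bool:
        return any(np.asarray(tr.emission).ndim == 2 for tr in self.transitions)

    def sample(self, rng: np.random.Generator, m: int) -> str:
        """Draw one alignment string of length ``m``."""
        if self.horizon is not None and m > self.horizon:
            raise ValueError(f"cannot sample beyond horizon {self.horizon}")
        by_src: dict[int, list[Transition]] = {}
        for tr in self.transitions:
            by_src.setdefault(tr.src, []).append(tr)
        state = int(rng.choice(self.n_states, p=self.init))
        out = []
        for t in range(m):
            trs = by_src[state]
            probs = np.array([tr.prob for tr in trs])
            tr = trs[int(rng.choice(len(trs), p=probs / probs.sum()))]
            e = self.emission_at(tr, t)
            out.append(SYMBOL_CHARS[int(rng.choice(self.n_symbols, p=e))])
            state = tr.dst
        return "".join(out)


# ---------------------------------------------------------------------------
# position profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionProfile:
    """Non-decreasing per-position baseline mismatch probability."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("profile values must lie in [0, 1]")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("profile must be non-decreasing")

    def __len__(self) -> int:
        return len(self.values)


def linear_profile(m: int, start: float = 0.01, end: float = 0.1) -> PositionProfile:
    if m == 1:
        return PositionProfile((start,))
    ramp = start + (end - start) * np.arange(m) / (m - 1)
    return PositionProfile(tuple(ramp))


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def build_snp_indel_model(p_snp: float, p_indel: float) -> ProbTransducer:
    """Three-state Match/SNP/Indel transducer over the 3-symbol alphabet."""
    if p_snp < 0 or p_indel < 0 or p_snp + p_indel > 1:
        raise ValueError("need p_snp, p_indel >= 0 and p_snp + p_indel <= 1")
    M, S, I = 0, 1, 2
    p_m = 1.0 - p_snp - p_indel
    pure_match = np.array([1.0, 0.0, 0.0])
    pure_mis = np.array([0.0, 1.0, 0.0])
    mix = np.array([0.25, 0.75, 0.0])  # match/mismatch mixture
    pure_indel = np.array([0.0, 0.0, 1.0])

    def emission(src: int, dst: int) -> np.ndarray:
        if src == I:
            return pure_indel  # leaving (or looping on) Indel: one indel color
        if dst == I:
            return mix  # entering Indel: preceding color mismatch in 3/4 cases
        if src == S and dst == S:
            return mix  # consecutive SNPs: matches may occur inside the run
        if src == S or dst == S:
            return pure_mis  # entering/leaving SNP: the two adjacent mismatches
        return pure_match

    transitions = []
    for src in (M, S, I):
        for dst, p in ((M, p_m), (S, p_snp), (I, p_indel)):
            if p > 0:
                transitions.append(Transition(src, dst, p, emission(src, dst)))
    init = np.array([1.0, 0.0, 0.0])
    return ProbTransducer(3, init, transitions, n_symbols=3, labels=["M", "SNP", "I"])


def build_reading_error_model(
    p_err: float,
    p_s: float,
    initial_marked: Iterable[int] = (),
) -> ProbTransducer:
    """Period-5 reading-error transducer.

    States are (marked-phase subset, current phase); one submodel per
    arrangement of error-prone phases on the 5-cycle.  Marked ("red")
    transitions emit a mismatch with probability ``p_err``; with
    probability ``p_s`` the model marks the current phase and moves up a
    level.  Baseline position-dependent errors are added separately via
    :func:`apply_position_profile`.
    """
    if not 0 <= p_err <= 1 or not 0 <= p_s <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    n = 32 * 5

    def idx(mask: int, phase: int) -> int:
        return mask * 5 + phase

    red = np.array([1.0 - p_err, p_err])
    black = np.array([1.0, 0.0])
    transitions = []
    for mask in range(32):
        for phase in range(5):
            src = idx(mask, phase)
            nxt = (phase + 1) % 5
            marked = bool(mask & (1 << phase))
            if marked or p_s == 0:
                transitions.append(
                    Transition(src, idx(mask, nxt), 1.0, red if marked else black)
                )
            else:
                transitions.append(
                    Transition(src, idx(mask, nxt), 1.0 - p_s, black)
                )
                # switching marks the current phase; the switch transition
                # is itself red
                transitions.append(
                    Transition(src, idx(mask | (1 << phase), nxt), p_s, red)
                )
    init_mask = 0
    for phi in initial_marked:
        if not 0 <= phi <= 4:
            raise ValueError("phases must lie in 0..4")
        init_mask |= 1 << phi
    init = np.zeros(n)
    init[idx(init_mask, 0)] = 1.0
    labels = [(mask, phase) for mask in range(32) for phase in range(5)]
    return ProbTransducer(n, init, transitions, n_symbols=2, labels=labels)


def apply_position_profile(
    model: ProbTransducer,
    profile: PositionProfile,
    combine: str = "max",
) -> ProbTransducer:
    """Layer a rising baseline mismatch probability onto a model.

    Equivalent to multiplying by a linear (m+1)-state position automaton
    whose i-th transition emits a mismatch with the profile value: at
    step ``i`` the mismatch emission of each transition becomes the
    maximum of its own rate and ``profile[i]`` (scaled by the transition's
    non-indel mass), with the match probability adjusted so the emission
    still sums to 1.  Indel emissions are untouched.  The result is
    horizon-dependent with horizon ``len(profile)``.
    """
    if combine != "max":
        raise ValueError("only the 'max' combination rule is defined")
    m = len(profile)
    if model.horizon is not None and model.horizon != m:
        raise ValueError(
            f"profile length {m} does not match model horizon {model.horizon}"
        )
    prof = np.asarray(profile.values)
    transitions = []
    for tr in model.transitions:
        em = np.asarray(tr.emission, dtype=float)
        base = np.broadcast_to(em, (m, model.n_symbols)).copy()
        if model.n_symbols == 3:
            row_mass = base[:, MATCH] + base[:, MISMATCH]
        else:
            row_mass = np.ones(m)
        new_mis = np.minimum(np.maximum(base[:, MISMATCH], prof * row_mass), row_mass)
        base[:, MISMATCH] = new_mis
        base[:, MATCH] = row_mass - new_mis
        transitions.append(Transition(tr.src, tr.dst, tr.prob, base))
    return ProbTransducer(
        model.n_states,
        model.init.copy(),
        transitions,
        n_symbols=model.n_symbols,
        horizon=m,
        labels=model.labels,
    )


def lift_to_indel(model: ProbTransducer) -> ProbTransducer:
    """View a 2-symbol model over the 3-symbol alphabet (indel mass 0)."""
    if model.n_symbols == 3:
        return model
    transitions = []
    for tr in model.transitions:
        em = np.asarray(tr.emission, dtype=float)
        pad = ((0, 0), (0, 1)) if em.ndim == 2 else ((0, 1),)
        transitions.append(Transition(tr.src, tr.dst, tr.prob, np.pad(em, pad)))
    return ProbTransducer(
        model.n_states,
        model.init.copy(),
        transitions,
        n_symbols=3,
        horizon=model.horizon,
        labels=model.labels,
    )


def _dominance_combine(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Combine emissions under the dominance rule indel > mismatch > match.

    With symbol indices MATCH=0 < MISMATCH=1 < INDEL=2 the dominant
    symbol of a pair is simply the larger index.
    """
    e1 = np.atleast_2d(e1)
    e2 = np.atleast_2d(e2)
    steps, k = max(e1.shape[0], e2.shape[0]), max(e1.shape[1], e2.shape[1])
    a = np.zeros((steps, k))
    b = np.zeros((steps, k))
    a[:, : e1.shape[1]] = e1
    b[:, : e2.shape[1]] = e2
    out = np.zeros((steps, k))
    outer = a[:, :, None] * b[:, None, :]
    for alpha in range(k):
        for beta in range(k):
            out[:, max(alpha, beta)] += outer[:, alpha, beta]
    return out[0] if steps == 1 else out


def product_models(a: ProbTransducer, b: ProbTransducer) -> ProbTransducer:
    """Dominance product of two alignment models.

    Pair states, multiplied transition probabilities; for emitted symbol
    pairs the dominant symbol (indel > mismatch > match) receives the
    product probability, and probabilities landing on the same symbol add
    up (which :func:`_dominance_combine` performs in one pass).
    """
    if a.horizon is not None and b.horizon is not None and a.horizon != b.horizon:
        raise ValueError(f"horizon mismatch: {a.horizon} vs {b.horizon}")
    horizon = a.horizon if a.horizon is not None else b.horizon
    n_symbols = max(a.n_symbols, b.n_symbols)
    a_out: dict[int, list[Transition]] = {}
    for tr in a.transitions:
        if tr.prob > 0:
            a_out.setdefault(tr.src, []).append(tr)
    b_out: dict[int, list[Transition]] = {}
    for tr in b.transitions:
        if tr.prob > 0:
            b_out.setdefault(tr.src, []).append(tr)

    index: dict[tuple[int, int], int] = {}
    order: list[tuple[int, int]] = []

    def intern(key):
        if key not in index:
            index[key] = len(order)
            order.append(key)
        return index[key]

    frontier = []
    for u in range(a.n_states):
        for v in range(b.n_states):
            if a.init[u] > 0 and b.init[v] > 0:
                intern((u, v))
                frontier.append((u, v))
    transitions: list[Transition] = []
    seen_pairs = set(order)
    while frontier:
        u, v = frontier.pop()
        for ta in a_out.get(u, []):
            for tb in b_out.get(v, []):
                dst = (ta.dst, tb.dst)
                if dst not in seen_pairs:
                    seen_pairs.add(dst)
                    intern(dst)
                    frontier.append(dst)
                transitions.append(
                    (index[(u, v)], index[dst], ta.prob * tb.prob,
                     _dominance_combine(ta.emission, tb.emission))
                )
    n = len(order)
    init = np.zeros(n)
    for (u, v), i in index.items():
        init[i] = a.init[u] * b.init[v]
    trans = [Transition(s, d, p, e) for s, d, p, e in transitions]
    la = a.labels or list(range(a.n_states))
    lb = b.labels or list(range(b.n_states))
    labels = [(la[u], lb[v]) for u, v in order]
    return ProbTransducer(n, init, trans, n_symbols=n_symbols, horizon=horizon,
                          labels=labels)


def build_bernoulli_model(
    p_match: float, n_symbols: int = 2, p_indel: float = 0.0
) -> ProbTransducer:
    """Single-state i.i.d. model (background/selectivity companion)."""
    if n_symbols == 2:
        em = np.array([p_match, 1.0 - p_match])
    else:
        em = np.array(
            [p_match * (1 - p_indel), (1 - p_match) * (1 - p_indel), p_indel]
        )
    return ProbTransducer(
        1, np.array([1.0]), [Transition(0, 0, 1.0, em)], n_symbols=n_symbols
    )


def default_model(params: ModelParams | None = None, m: int = 34) -> ProbTransducer:
    """The full read-alignment model: SNP/indel x (reading errors with the
    rising baseline profile), combined by the dominance product."""
    params = params or ModelParams()
    re_model = build_reading_error_model(params.p_err_periodic, params.p_switch)
    re_model = apply_position_profile(
        re_model, linear_profile(m, params.p_err_start, params.p_err_end)
    )
    snp_model = build_snp_indel_model(params.p_snp, params.p_indel)
    return product_models(snp_model, re_model)


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------

def alignment_probability(model: ProbTransducer, alignment: str) -> float:
    """Forward probability of one symbol string under the model."""
    if model.horizon is not None and len(alignment) > model.horizon:
        raise ValueError("alignment longer than the model horizon")
    f = model.init.copy()
    for t, ch in enumerate(alignment):
        a = CHAR_TO_SYMBOL[ch]
        if a >= model.n_symbols:
            return 0.0
        f2 = np.zeros_like(f)
        for tr in model.transitions:
            e = model.emission_at(tr, t)
            if e[a]:
                f2[tr.dst] += f[tr.src] * tr.prob * e[a]
        f = f2
    return float(f.sum())


def batch_probabilities(model: ProbTransducer, symbols: np.ndarray) -> np.ndarray:
    """Forward probabilities for many symbol strings at once.

    ``symbols`` is an integer array of shape (n_strings, m).
    """
    symbols = np.asarray(symbols)
    n_str, m = symbols.shape
    if model.horizon is not None and m > model.horizon:
        raise ValueError("strings longer than the model horizon")
    F = np.tile(model.init, (n_str, 1))
    for t in range(m):
        F2 = np.zeros_like(F)
        col = symbols[:, t]
        for tr in model.transitions:
            e = model.emission_at(tr, t)
            w = tr.prob * e[col]
            F2[:, tr.dst] += F[:, tr.src] * w
        F = F2
    return F.sum(axis=1)


def enumerate_strings(m: int, n_symbols: int) -> np.ndarray:
    """All symbol strings of length m as an integer matrix."""
    grids = np.meshgrid(*([np.arange(n_symbols)] * m), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def total_probability(model: ProbTransducer, m: int, chunk: int = 8192) -> float:
    """Exhaustively enumerate all length-m strings and sum their forward
    probabilities — an independent check that the model is a proper
    distribution (must equal 1)."""
    strings = enumerate_strings(m, model.n_symbols)
    total = 0.0
    for lo in range(0, strings.shape[0], chunk):
        total += float(batch_probabilities(model, strings[lo : lo + chunk]).sum())
    return total
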