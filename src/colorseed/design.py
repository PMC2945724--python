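"""Seed search: sampling, scoring, and local optimization.

The search explores the space of (pattern, position-set) candidates by
uniform sampling, scores candidates either by sensitivity (lossy mode)
or by certified losslessness plus selectivity (lossless mode), and
hill-climbs the best candidates with elementary moves: shifting one gap
by one slot, or swapping one allowed position for an unused one.  Runs
are fully reproducible from the problem's RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .automata import family_to_dfa
from .lossless import (
    CostScheme,
    LosslessVerdict,
    check_lossless_cost,
    check_lossless_snp_err,
)
from .models import ProbTransducer
from .seeds import PositionedSeed, SeedFamily, SpacedSeed
from .sensitivity import background_hit_probability, family_sensitivity

__all__ = ["DesignProblem", "DesignRecord", "sample_candidate", "local_optimize", "design_seeds"]


@dataclass
class DesignProblem:
    mode: str  # "lossy" or "lossless"
    weight: int
    max_span: int
    read_length: int
    positions_per_seed: int
    family_size: int = 1
    model: ProbTransducer | None = None  # lossy objective
    snp_budget: int = 0
    err_budget: int = 0
    cost_scheme: CostScheme | None = None  # alternative lossless budget
    n_samples: int = 100
    top_k: int = 5
    opt_steps: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("lossy", "lossless"):
            raise ValueError(f"mode must be 'lossy' or 'lossless', got {self.mode!r}")
        if self.weight < 1 or self.weight > self.max_span:
            raise ValueError("need 1 <= weight <= max_span")
        if self.positions_per_seed < 1 or self.family_size < 1:
            raise ValueError("positions_per_seed and family_size must be >= 1")
        if self.mode == "lossy" and self.model is None:
            raise ValueError("lossy mode needs an alignment model")
        if self.weight > self.read_length:
            raise ValueError("weight exceeds read length")
        if self.positions_per_seed > self.read_length - self.weight + 1:
            raise ValueError(
                f"{self.positions_per_seed} placements cannot fit a read of "
                f"length {self.read_length} at weight {self.weight}"
            )


@dataclass(frozen=True)
class DesignRecord:
    family: SeedFamily
    score: float
    selectivity: float
    lossless: bool | None


def _sample_member(problem: DesignProblem, rng: np.random.Generator) -> PositionedSeed:
    w, m, n = problem.weight, problem.read_length, problem.positions_per_seed
    # a span leaving fewer than n valid starts is infeasible for this member
    span_cap = min(problem.max_span, m - n + 1)
    if w >= 2 and span_cap > w:
        span = int(rng.integers(w, span_cap + 1))
    else:
        span = w
    pattern = np.full(span, "#")
    gaps = span - w
    if gaps:
        interior = rng.choice(span - 2, size=gaps, replace=False) + 1
        pattern[interior] = "-"
    seed = SpacedSeed("".join(pattern))
    starts = rng.choice(m - span + 1, size=n, replace=False)
    return PositionedSeed(seed, tuple(int(p) for p in np.sort(starts)))


def sample_candidate(problem: DesignProblem, rng: np.random.Generator) -> SeedFamily:
    """Uniformly sample one candidate family (gap layouts among interior
    slots; position subsets of the configured size)."""
    members = tuple(_sample_member(problem, rng) for _ in range(problem.family_size))
    return SeedFamily(members, problem.read_length)


def _neighbors_move(
    family: SeedFamily, rng: np.random.Generator
) -> SeedFamily | None:
    """One random elementary move; None when the drawn move is a no-op."""
    m = family.read_length
    mi = int(rng.integers(len(family.members)))
    mem = family.members[mi]
    pattern = list(mem.seed.pattern)
    span = len(pattern)
    if rng.random() < 0.5 and "-" in pattern:
        gap_positions = [i for i, ch in enumerate(pattern) if ch == "-"]
        g = gap_positions[int(rng.integers(len(gap_positions)))]
        direction = -1 if rng.random() < 0.5 else 1
        t = g + direction
        if not (1 <= t <= span - 2) or pattern[t] != "#":
            return None
        pattern[g], pattern[t] = "#", "-"
        new_mem = PositionedSeed(SpacedSeed("".join(pattern)), mem.positions)
    else:
        valid = set(range(m - span + 1))
        unused = sorted(valid - set(mem.positions))
        if not unused:
            return None
        drop = mem.positions[int(rng.integers(len(mem.positions)))]
        add = unused[int(rng.integers(len(unused)))]
        new_pos = tuple(sorted((set(mem.positions) - {drop}) | {add}))
        new_mem = PositionedSeed(mem.seed, new_pos)
    members = list(family.members)
    members[mi] = new_mem
    return SeedFamily(tuple(members), m)


def local_optimize(
    family: SeedFamily,
    objective: Callable[[SeedFamily], float],
    rng: np.random.Generator,
    steps: int = 40,
) -> SeedFamily:
    """Strict hill climbing over elementary moves; returns the best
    family seen, so the output objective is never below the input's."""
    best = current = family
    best_score = cur_score = objective(family)
    for _ in range(steps):
        proposal = _neighbors_move(current, rng)
        if proposal is None:
            continue
        score = objective(proposal)
        if score > cur_score:
            current, cur_score = proposal, score
            if score > best_score:
                best, best_score = proposal, score
    return best


def _family_key(family: SeedFamily) -> tuple:
    return tuple(
        (mem.seed.pattern, mem.positions) for mem in family.members
    )


def design_seeds(problem: DesignProblem) -> list[DesignRecord]:
    """Sample-score-optimize pipeline.

    Lossy mode ranks by sensitivity (ties: higher selectivity, then
    lexicographic pattern order).  Lossless mode discards candidates that
    fail certification before ranking by selectivity.
    """
    rng = np.random.default_rng(problem.rng_seed)
    m = problem.read_length

    def selectivity(family: SeedFamily) -> float:
        return 1.0 - background_hit_probability(family_to_dfa(family), m)

    def is_lossless(family: SeedFamily) -> bool:
        if problem.cost_scheme is not None:
            return check_lossless_cost(
                family, problem.cost_scheme, want_witness=False
            ).lossless
        return check_lossless_snp_err(
            family, problem.snp_budget, problem.err_budget, want_witness=False
        ).lossless

    if problem.mode == "lossy":
        def objective(family: SeedFamily) -> float:
            return family_sensitivity(family, problem.model).value
    else:
        def objective(family: SeedFamily) -> float:
            return selectivity(family) if is_lossless(family) else -1.0

    scored: list[tuple[float, SeedFamily]] = []
    for _ in range(problem.n_samples):
        family = sample_candidate(problem, rng)
        scored.append((objective(family), family))
    scored.sort(key=lambda t: (-t[0], _family_key(t[1])))
    top = scored[: problem.top_k]
    optimized = [
        local_optimize(family, objective, rng, problem.opt_steps)
        for _, family in top
    ]
    records = []
    for family in optimized:
        score = objective(family)
        sel = selectivity(family)
        loss = is_lossless(family) if problem.mode == "lossless" else None
        if problem.mode == "lossless" and not loss:
            continue
        records.append(DesignRecord(family, score, sel, loss))
    records.sort(key=lambda r: (-r.score, -r.selectivity, _family_key(r.family)))
    # deduplicate identical families discovered from different starts
    seen: set = set()
    unique = []
    for rec in records:
        key = _family_key(rec.family)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return unique
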