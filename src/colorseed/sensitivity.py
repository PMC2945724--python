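"""Seed sensitivity: probability that a family hits a model-drawn alignment.

The sensitivity of a seed family is the probability that at least one of
its seeds hits a length-m alignment drawn from a probabilistic alignment
model.  It is computed exactly by a forward dynamic program over pairs
(model state, automaton state) — never by enumerating strings.  The same
dynamic program with an i.i.d. uniform background model yields the
selectivity companion statistic (one minus the background hit
probability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models as _models
from .automata import AlignmentDFA, family_to_dfa, indel_extend
from .models import ProbTransducer, batch_probabilities, enumerate_strings
from .seeds import SeedFamily, family_hits

__all__ = [
    "SensitivityResult",
    "compute_sensitivity",
    "family_sensitivity",
    "brute_force_sensitivity",
    "background_hit_probability",
]


@dataclass(frozen=True)
class SensitivityResult:
    value: float
    m: int
    family: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        if not -1e-9 <= self.value <= 1 + 1e-9:
            raise ValueError(f"sensitivity {self.value} outside [0, 1]")


def _harmonize(dfa: AlignmentDFA, model: ProbTransducer):
    if model.n_symbols == 3 and dfa.n_symbols == 2:
        dfa = indel_extend(dfa)
    elif model.n_symbols == 2 and dfa.n_symbols == 3:
        model = _models.lift_to_indel(model)
    return dfa, model


def compute_sensitivity(
    dfa: AlignmentDFA,
    model: ProbTransducer,
    m: int,
    family: str = "",
    model_name: str = "",
) -> SensitivityResult:
    """Probability mass of the length-m strings accepted by ``dfa``.

    Runs in O(m * |model| * |dfa| * |alphabet|); requires the automaton's
    final states to be absorbing (otherwise accepted mass would be
    counted more than once).
    """
    if not dfa.finals_absorbing():
        raise ValueError("final states must be absorbing for the sensitivity DP")
    if model.horizon is not None and m > model.horizon:
        raise ValueError(f"m={m} exceeds the model horizon {model.horizon}")
    dfa, model = _harmonize(dfa, model)
    n_dfa = dfa.n_states
    F = np.zeros((model.n_states, n_dfa))
    F[:, dfa.initial] = model.init
    static_W = None if model.step_dependent else model.symbol_matrices(0)
    for t in range(m):
        W = static_W if static_W is not None else model.symbol_matrices(t)
        F2 = np.zeros_like(F)
        F2_T = F2.T  # view: (n_dfa, n_model)
        for a in range(dfa.n_symbols):
            H = W[a].T @ F  # (n_model, n_dfa)
            np.add.at(F2_T, dfa.delta[:, a], H.T)
        F = F2
    value = float(F[:, dfa.finals].sum())
    return SensitivityResult(min(max(value, 0.0), 1.0), m, family, model_name)


def family_sensitivity(
    family: SeedFamily, model: ProbTransducer, family_name: str = "", model_name: str = ""
) -> SensitivityResult:
    """Sensitivity of a whole family via its OR-union automaton."""
    return compute_sensitivity(
        family_to_dfa(family), model, family.read_length, family_name, model_name
    )


def brute_force_sensitivity(
    family: SeedFamily, model: ProbTransducer, m: int
) -> float:
    """Exhaustive-enumeration oracle for small m.

    Sums the model probability of every length-m symbol string hit by the
    family under the direct scan (position sets honored, windows spanning
    an indel excluded).
    """
    if model.n_symbols == 2 and m > 16:
        raise ValueError("brute force guarded at m <= 16 for the binary alphabet")
    if model.n_symbols == 3 and m > 10:
        raise ValueError("brute force guarded at m <= 10 with indels")
    from .automata import SYMBOL_CHARS

    strings = enumerate_strings(m, model.n_symbols)
    probs = batch_probabilities(model, strings)
    total = 0.0
    for row, p in zip(strings, probs):
        if p == 0.0:
            continue
        s = "".join(SYMBOL_CHARS[a] for a in row)
        if family_hits(family, s):
            total += float(p)
    return total


def background_hit_probability(
    dfa: AlignmentDFA, m: int, p_match: float = 0.25
) -> float:
    """Probability of hitting a random alignment in which each color
    matches independently with probability ``p_match`` (1/4 for a uniform
    background).  Selectivity is one minus this value."""
    model = _models.build_bernoulli_model(p_match, n_symbols=2)
    return compute_sensitivity(dfa, model, m).value
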