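"""colorseed: spaced-seed design and certification for SOLiD color reads.

The package models color-space read alignments with probability
transducers, compiles (position-restricted) seed families to automata
over the match/mismatch/indel alphabet, computes exact seed sensitivity
by dynamic programming, certifies lossless families under mismatch or
cost budgets, and searches for good seed families by sampling plus local
optimization.
"""

from importlib import resources

from .automata import (
    AlignmentDFA,
    family_to_dfa,
    indel_extend,
    position_chain,
    positioned_seed_dfa,
    product,
    seed_to_dfa,
)
from .colorspace import (
    ColorRead,
    decode_from_colors,
    encode_to_colors,
    quality_correlation,
    quality_correlation_profile,
    quality_to_error_prob,
    simulate_reads,
)
from .design import DesignProblem, design_seeds, local_optimize, sample_candidate
from .lossless import (
    CostScheme,
    LosslessVerdict,
    brute_force_lossless,
    build_cost_automaton,
    build_error_combo_automaton,
    build_snp_error_automaton,
    check_lossless,
    check_lossless_combo,
    check_lossless_cost,
    check_lossless_snp_err,
    min_cost_dp,
)
from .models import (
    PositionProfile,
    ProbTransducer,
    alignment_probability,
    apply_position_profile,
    build_reading_error_model,
    build_snp_indel_model,
    default_model,
    linear_profile,
    product_models,
    total_probability,
)
from .params import ModelParams
from .seeds import (
    PositionedSeed,
    SeedFamily,
    SpacedSeed,
    overlap_depth,
    parse_seed,
    read_seed_file,
    seed_hits,
    write_seed_file,
)
from .sensitivity import (
    SensitivityResult,
    background_hit_probability,
    brute_force_sensitivity,
    compute_sensitivity,
    family_sensitivity,
)

__version__ = "0.1.0"

#: Shipped reference seed families (file stem -> human name).
BUILTIN_FAMILIES = {
    "3-lossless-10-24p": "lossless_10_24p",
    "3-lossy-12": "lossy_12",
    "shrimp-default": "shrimp_default",
    "perm-f3-s20": "perm_f3_s20",
}


def builtin_family(name: str, read_length: int = 34) -> SeedFamily:
    """Load one of the shipped seed families by name."""
    if name not in BUILTIN_FAMILIES:
        raise KeyError(
            f"unknown family {name!r}; available: {sorted(BUILTIN_FAMILIES)}"
        )
    ref = resources.files(__name__) / "data" / f"{BUILTIN_FAMILIES[name]}.seeds"
    with resources.as_file(ref) as path:
        return read_seed_file(path, read_length)
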