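# Methods

This note documents the models, algorithms and conventions implemented
in `colorseed`, the reasoning behind the design choices that were
genuinely open, and what the synthetic-data tests do and do not show.

## Alignment alphabet and color-space conventions

Read-to-reference alignments are strings over {`1` match, `0` mismatch,
`I` color indel}, one symbol per alignment column. The dibase code is
the standard two-bit-XOR table (A=0, C=1, G=2, T=3;
`color = code(b1) ^ code(b2)`). Any Latin-square dibase code shares the
properties the package relies on — identical bases give color 0, one
substitution flips exactly two adjacent colors (one at the read's last
base), *n* consecutive substitutions affect at most *n*+1 colors — and
the encoder/decoder are isolated in `colorspace` should a different
table ever be needed.

### Indel bookkeeping (an open convention, fixed here)

Two bookkeeping questions have no single obvious answer when an
alignment contains indel columns:

1. **Does an indel column count toward the alignment horizon m?**
   Yes. Every automaton and dynamic program consumes exactly one symbol
   per column and runs for exactly *m* steps, which keeps all machines
   horizon-synchronous.
2. **Does an indel column consume a read position?** No. Allowed
   positions of a position-restricted seed index the *colors of the
   read*; an indel column carries no read color, so the position
   counter self-loops on `I`. Concretely, a placement at read position
   *p* starts at the column of the *p*-th non-indel symbol, and its
   window must consist of contiguous indel-free columns (seeds sit
   *between* indels).

Convention 2 is forced by the shipped family: under the alternative
(columns-count) reading, `3-Lossless-10-24p` has a cost-7 missed
alignment (indel + its free adjacent mismatch + one SNP, cost 4+0+3),
whereas under the read-color convention it certifies lossless at cost 7
— the property the family was designed for. The direct-scan oracle
(`seeds.family_hits`) implements the same convention independently of
the automata, and the two routes are tested against each other.

## Probabilistic alignment models

Models are finite-state probability transducers: each transition
carries a probability and an emission distribution over alignment
symbols, optionally indexed by step (horizon-dependent). Stochasticity
(outgoing probabilities and every emission row sum to 1) is validated
at construction.

**SNP/indel model** — states Match, SNP, Indel; from every state the
next state is SNP with probability `p_snp`, Indel with `p_indel`, Match
otherwise. Emissions: M→M matches; entering and leaving SNP emit the
two adjacent mismatches of a SNP; the SNP self-loop emits a 0.25/0.75
match/mismatch mixture (color matches can occur inside runs of
consecutive SNPs); transitions entering Indel emit the pre-indel color
mismatch with probability 0.75 (match otherwise); every transition out
of (or looping on) Indel emits one indel color. A transition from SNP
to Indel both leaves SNP and enters Indel; the entering-Indel rule wins
there, i.e. the SNP's second mismatch is subsumed by the pre-indel
mismatch (the ambiguity affects probability mass of order
`p_snp * p_indel` ≈ 10⁻⁵).

**Reading-error model** — states are (marked-phase subset, phase) on a
cycle of 5 read positions: one submodel per arrangement of error-prone
phases, 32 × 5 = 160 states. Transitions at a marked phase ("red")
emit a mismatch with probability `p_err`; unmarked transitions emit no
mismatch at this stage. With probability `p_s` per step the model
switches one level up by marking the *current* phase; the switching
transition is itself red. Switching is one-way, so error phases only
accumulate along the read. A count-based (level, phase) indexing cannot
express *which* phases are marked, which the switching rule requires;
the subset indexing is the minimal state space that can.

**Position profile** — the baseline error probability rising along the
read is a non-decreasing array `p_err'(pos)`, by default linear from
0.01 to 0.1. Applying it multiplies the model by a linear (m+1)-state
position automaton: at step *i* each transition's mismatch emission
becomes `max(own rate, p_err'(i))` (scaled by the transition's
non-indel mass; indel emissions are untouched), with the match share
adjusted to keep the row stochastic.

**Dominance product** — the full model is the product of the SNP/indel
and (profiled) reading-error models: pair states, multiplied transition
probabilities, and for an emitted symbol pair the dominant symbol under
indel ≻ mismatch ≻ match receives the product probability; masses
landing on the same symbol add. With symbol indices match=0 <
mismatch=1 < indel=2 dominance is simply the larger index.

**Default parameters** (the conditions the shipped families were
designed for, also the simulator's defaults):

| parameter | default | meaning |
|---|---|---|
| `p_snp` | 0.0085 | SNP probability per position |
| `p_indel` | 0.0015 | color-indel probability per position |
| `p_err_start` / `p_err_end` | 0.01 / 0.1 | baseline reading-error probability at read start / end |
| `p_err_periodic` | 0.02 | mismatch probability of red (period-5) transitions |
| `p_switch` | 0.05 | per-step probability of marking another phase (free parameter; no published value exists) |
| `p_indel_pre_mismatch` | 0.75 | probability that a color indel is preceded by a color mismatch |
| `quality_lag5_rho` | 0.6 | lag-5 quality correlation injected by the simulator |

## Seed automata

`seed_to_dfa` builds the DFA of strings containing a seed hit by subset
construction over viable seed-prefix lengths followed by Moore
minimization. The minimal automaton is never larger than the compact
bound (w+1)·2^(s−w), which is asserted over seed sweeps; a brute-force
language scan is the independent oracle.

Position restriction multiplies a (non-absorbing) *occurrence*
automaton — final iff a seed occurrence ends at the current symbol —
with the linear position chain λ_P (state `q_i` final iff `i − s ∈ P`),
then makes the AND-finals absorbing. A whole family is compiled
directly as a *placement-thread automaton*: a state is (consumed
symbols, set of still-viable placements), completing any placement
jumps to the absorbing hit state. This economical construction stays
within (w+1)·2^(s−w)·|P| + m states (asserted on sweeps; the naive
synchronous product does not have this property), and its size is
governed in practice by the maximum placement overlap (the chromatic
number of the placement interval graph, `seeds.overlap_depth`).
Backbone states with an empty thread set are always materialized so the
automaton carries a total restart map; `indel_extend` then adds `I`
transitions that jump to the restart image (partial matches die, the
read-position counter stays), leaving finals absorbing.

## Sensitivity

`compute_sensitivity` runs the forward recurrence over
(model state, automaton state) pairs for exactly *m* steps,
O(m·|model|·|DFA|·|alphabet|); absorbing finals are required so
accepted mass is counted once. Family sensitivity always uses the
single OR-union automaton rather than inclusion–exclusion over members.
Selectivity re-uses the identical program with a one-state
Bernoulli(1/4) background model — there is no separate code path.
Exhaustive enumeration (`brute_force_sensitivity`, guarded at m ≤ 16
binary / m ≤ 10 with indels) is the oracle; agreement is asserted to
1e-10 on hundreds of random instances.

## Lossless certification

`min_cost_dp` computes, for every state of a cost-carrying automaton
and every step i ≤ m, the minimal total transition cost to reach it —
two rolling rows, O(|states|·|alphabet|) space; backpointers for
witness reconstruction are opt-in (O(m·|states|)) and break ties toward
the lexicographically smallest string (match < mismatch < indel, then
smallest source state; witnesses are therefore reproducible). A family
is lossless iff after m steps every state that is accepting for the
constraint but not for the family costs more than the threshold.

Constraint automata:

* **k SNPs + h reading errors** (binary alphabet): acceptance means the
  mismatches can be covered by at most k disjoint adjacent pairs plus h
  singletons. The state tracks the capped mismatch count R, the capped
  number of completable pairs P, and the parity of the current mismatch
  run; acceptance is `R − 2·min(P, k) ≤ h`. Transition costs count
  mismatches, so `min_missed_cost` is the mismatch count of a cheapest
  missed in-class alignment and the threshold is 2k + h. This also
  covers consecutive SNPs (k consecutive SNPs yield only k+1
  mismatches), which is property-tested.
* **cost scheme** (three context states: after-match, after-mismatch,
  after-indel): match 0 from anywhere; mismatch 2 after a match, 1
  after a mismatch (so an isolated SNP totals 3), 0 after an indel
  (the indel's own color artifact); indel 4. Two boundary conventions
  are fixed deliberately: a string cannot begin with "the second
  mismatch of a SNP" (the start context is after-match, so a leading
  mismatch costs 2), and a post-indel free mismatch moves to the
  after-mismatch context, keeping the adjacency discount available.
* **bounded event combinations** (at most i indels, k SNPs, h errors)
  for certifying each error combination separately; an indel may be
  followed by one free mismatch, and costs count corrupted colors.

`brute_force_lossless` is the oracle: depth-first generation of every
in-budget constraint-accepted string (cost-pruned, guarded at 10⁶
candidates), each tested with the direct hit scan. DP and oracle are
asserted to agree — verdict and minimal missed cost — on every guarded
instance, including indel budgets.

Certification of the shipped families uses m = 34, the read length the
families were designed for (losslessness at m extends to any longer
read length, which is also property-tested: a missed longer alignment
would have a missed in-budget prefix).

## Read simulator

`colorspace.simulate_reads` draws uniform forward-strand loci and
applies, in order: base-level SNPs (uniform substitute base), color
encoding, color indels (preceded by a color mismatch with probability
0.75; insertion or deletion with equal probability), and reading errors
with per-position probability `max(baseline(pos), p_err_periodic ·
marked(pos))` where marked phases accumulate exactly as in the
reading-error transducer. Qualities follow the Phred trend of the
realized error probability plus a per-read lag-5 correlated Gaussian
component calibrated so that with a flat trend the pooled lag-5 quality
correlation is `quality_lag5_rho` (total extra variance 9; integer
rounding costs ≈ 0.005 of correlation), plus white noise.

What the generator emulates: SNPs as adjacent color-mismatch pairs,
indels with their leading mismatch, the rising error trend, period-5
error phases, and lag-5 quality correlation. What it does not: real
base-composition biases, reverse-strand reads, position-specific
quality distributions of any particular instrument, or correlated
multi-read artifacts. Passing the recovery tests therefore shows the
pipeline is self-consistent under the stated error structure, not that
the model is calibrated to any particular dataset — fitting model
parameters to real reads is out of scope.

## Numerical choices and degenerate inputs

* Stochasticity tolerances: 1e-9 in validators (1e-12 is met in
  practice; exhaustive total-probability checks assert 1 ± 1e-9).
* Sensitivity values are clamped to [0, 1] after the DP (float dust).
* An empty position set is legal data: sensitivity 0, never lossless
  for any budget ≥ 0; the position chain warns when P is empty.
* Constant qualities make the correlation undefined → rejected.
* Strings longer than m are outside every contract; all dynamic
  programs iterate exactly m steps.
* Design-search ties break by (score, selectivity, lexicographic
  pattern/position order); runs are reproducible from the RNG seed.

## Problem sizes

The test suite certifies the shipped family at m = 34 (sub-second),
compares the certification DP with enumeration on 200 random families
(m ≤ 20, budgets k ≤ 1, h ≤ 2) and the sensitivity DP on 200 instances
(m ≤ 12 binary, m ≤ 8 with indels), enumerates all length-10
alignments for the model checks, and simulates 10⁵ length-34 reads for
the structure-recovery statistics; the whole suite runs in well under a
minute. These sizes were chosen so that the enumeration oracles remain
exact; the dynamic programs themselves handle much larger automata.

## Known limitations

* The reading-error topology realizes the documented properties
  (period-5 submodels, one-way switching, red transitions) with the
  newly marked phase being the one at which the switch occurs; other
  layouts with the same properties are conceivable, and the builder is
  pluggable behind the transducer interface.
* `p_switch` has no published value; 0.05 is a package default and
  should be treated as a tunable.
* Lossy and lossless objectives are not combined in the search; the
  design loop's sampling and acceptance schedule is this package's own
  (uniform sampling + strict hill climbing) and makes no claim of
  reproducing any particular published seed set.
* Subset seeds over richer mismatch alphabets and indel seeds (seed
  symbols spanning indels) are out of scope.
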