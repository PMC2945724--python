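# colorseed

Design and certification of spaced seeds for mapping SOLiD color-space
reads.

SOLiD sequencers report reads as *colors* — overlapping-dimer codes —
rather than bases. In color space the error landscape is peculiar: a
genuine SNP appears as **two adjacent color mismatches**, a base indel
appears as an indel of colors usually preceded by one color mismatch,
and reading errors are isolated mismatches that grow more frequent
towards the end of the read and recur with a period of 5 positions (an
artifact of the ligation chemistry). Seed-based mappers filter candidate
alignment loci with spaced seeds, so seeds should be designed *for* this
error structure. `colorseed` is a toolkit for doing that, aimed at
people building or studying short-read mappers:

* **position-restricted seeds** — a spaced seed `π` (a `#`/`-` pattern
  with weight *w* and span *s*) paired with an explicit set *P* of read
  offsets where it may hit, letting a family concentrate placements on
  the reliable early positions of the read;
* **probabilistic alignment models** — finite-state probability
  transducers over the alphabet {match `1`, mismatch `0`, indel `I`}:
  a 3-state Match/SNP/Indel model, a period-5 reading-error model with
  a rising positional error profile, and their dominance product
  (indel ≻ mismatch ≻ match);
* **exact sensitivity** — the probability that at least one seed of a
  family hits a model-drawn alignment of length *m*, computed by a
  forward dynamic program over (model state × seed-automaton state)
  pairs, never by enumeration; the same program under a uniform
  background yields the selectivity companion statistic;
* **lossless certification** — a per-state minimal-cost dynamic program
  over the intersection of the family automaton with a constraint
  automaton proves (or refutes, with a concrete witness alignment) that
  the family hits *every* alignment within an error budget: either
  *k* SNPs + *h* reading errors, or a total cost with the scheme
  match 0, mismatch 2, adjacent second mismatch 1 (a SNP totals 3),
  indel 4, post-indel mismatch 0;
* **seed search** — uniform sampling of patterns and position sets plus
  strict hill climbing, in lossy (maximize sensitivity) or lossless
  (certify, then rank by selectivity) mode;
* **a read simulator** — synthetic csfasta/QUAL data reproducing the
  SNP-pair, indel, rising-error and period-5 structure, for testing
  the whole pipeline end to end.

The shipped family `3-lossless-10-24p` (three weight-10 seeds, 24
allowed positions in total) certifies lossless at cost threshold 7 for
34-color reads, which covers 1 indel + 1 SNP, 1 indel + 1 reading
error, 2 SNPs, and 1 SNP + 2 reading errors.

## Worked example

```python
>>> import colorseed as cs
>>> family = cs.builtin_family("3-lossless-10-24p", read_length=34)
>>> family.weights, family.total_positions
((10, 10, 10), 24)
>>> verdict = cs.check_lossless_cost(family, cs.CostScheme(threshold=7))
>>> verdict.lossless, verdict.min_missed_cost
(True, 8.0)
>>> cs.check_lossless_cost(family, cs.CostScheme(threshold=9)).witness
'11111111111I011111111111I011111111'
>>> sens = cs.family_sensitivity(family, cs.default_model(m=34))
>>> round(sens.value, 4)
0.9903
>>> cs.background_hit_probability(cs.family_to_dfa(family), 34)
2.213897770774209e-05
```

Reading the numbers: every 34-color alignment of total cost ≤ 7 is hit
by at least one seed at an allowed position (the cheapest *missed*
alignment costs 8 — raise the budget to 9 and the certifier hands you
that two-indel witness). Under the full error model the family detects
99.03 % of read alignments while a random background locus passes the
filter with probability 2.2 × 10⁻⁵.

The same checks from the shell:

```sh
colorseed lossless-check --seeds my_family.seeds --length 34 --cost-threshold 7
colorseed evaluate --seeds my_family.seeds --length 34
colorseed simulate --random-reference 3000 --n-reads 1000 --length 34 \
    --seed 0 --out reads.csfasta --qual-out reads.qual
colorseed quality-stats --reads reads.csfasta --quals reads.qual
```

`lossless-check` exits 0 when the family certifies and 1 with a printed
witness when it does not; malformed inputs exit 2.

## Seed files

One family per file, one member per line, tab-separated pattern and
positions (`*` = every valid start offset; `;` starts a comment):

```
####-##-####	0,1,2,3,4,5,6,7,8,18,19,20
#-########-#	2,12,15,16,18,19,20,21
####-#-------#-####	0,1,11,14
```

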