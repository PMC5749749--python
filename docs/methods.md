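# Methods

## Alignment model

The engine computes local (Smith-Waterman) alignments: cell scores are
floored at zero, so an alignment may start and end anywhere in either
sequence. Two gap models are supported, chosen by the gap-extension
penalty:

* **basic** (`g_e = 0`): one score grid H; every gap column costs the
  full open penalty `g_o`.
* **affine** (`g_e > 0`): the Gotoh three-state formulation with grids
  M (match/mismatch), I (gap in the target) and J (gap in the query);
  a gap run of length L costs `g_o + (L-1) g_e`.

Penalties are stored as non-negative magnitudes and subtracted in the
recurrences; `g_o >= g_e >= 0` is enforced. Boundary cells (row 0,
column 0) hold 0 in H/M and a large negative sentinel (-1e30) in I and J.
Only M is floored at zero; I and J may go negative, the standard
treatment for local affine alignment. Scores are float64 throughout;
with integer-valued schemes all arithmetic is exact.

In the affine recurrences a gap state is entered only from M
(`I` from `M` or `I`; `J` from `M` or `J`), so a gap run in one sequence
is never immediately adjacent to a gap run in the other. This is the
canonical alignment convention; it matters only for substitution tables
with entries below `-2 g_e`, where a single-grid ("free") formulation
could place two opposite gaps where this engine places one mismatch
column. The basic model, having one grid, is free by construction —
which is also why the affine model with `g_e = g_o` reproduces basic
scores only when all substitution scores are at least `-2 g_o`; for
every realistic scheme (e.g. match 5 / mismatch -4 / gap 10) the two
coincide exactly, and the test suite exercises the reduction in that
regime.

### Tie-breaking and traceback

The per-cell winner prefers M/diag over I/up over J/left, making
tracebacks deterministic and gap-minimal among equal-scoring paths.
Each interior cell stores its move (stop/diag/up/left) and, in affine
mode, the winning grid; `stop` is recorded exactly when the winning
score is 0. Affine traceback walks the M/I/J state machine, deciding
open-vs-extend inside a gap run by testing which stored predecessor
expression reproduces the stored value — exact float comparisons,
because the fill computed those same expressions. Every traversed cell
is marked visited.

### Multiple hits

All cells scoring at least
`max(minimum_score, lower_limit_score * global_max)` become traceback
starts, processed in score-descending order (ties by row, then column).
A start whose cell was consumed by an earlier traceback is skipped; this
is how contained sub-optimal alignments are deduplicated. The policy is
a package decision — lowering `lower_limit_score` below 1.0 reports
progressively more distinct sub-optimal alignments.

## Metrics and filters

For a hit with raw score S, alignment length L, over query length `n`
and target length `m`:

| metric | definition |
|---|---|
| query_coverage | non-gap query columns / n |
| query_identity | match columns / n |
| relative_score | S / min(n, m) |
| base_score | S / L |
| theoretical_max | min(n, m) x max substitution entry |

`query_identity` divides by the full query length; the module switch
`filtering.IDENTITY_OVER_ALIGNED_SPAN` selects the aligned-span
denominator instead (the phrase "relative to the query" admits both
readings; the full-length reading is the default because it penalises
fragmentary hits).

A hit is reported iff all of: `S >= minimum_score`;
`S > filter_factor * theoretical_max` (strict, because the criterion is
"above" a fraction of the perfect score); and coverage, identity,
relative score and base score each at or above their thresholds
(inclusive, because those are minima). Defaults: 1.0, 30, 0.2, 0.2, 0.2,
2.0, 2.0. The verdict object names every failing criterion, and metrics
are computed before filtering so rejected hits can be logged at debug
level.

## Scoring schemes

The stock DNA/RNA scheme puts the match score (default 5, so a
full-length self-match has relative score 5.0) on the A/C/G/T/U diagonal
and the mismatch score (default -4) elsewhere; N never rewards a match.
Neither the mismatch value nor the default gap-open of 10 is canonical —
both are configurable package defaults. Arbitrary substitution tables up
to 255x255 symbols load from NCBI/EMBOSS-dialect text files; asymmetric
tables are allowed (rows index the query). Symbols outside the scheme's
alphabet score as the worst table entry (the mismatch score for the DNA
scheme) rather than raising, so one stray ambiguity code cannot abort a
batch.

## Parallel backend

The fill grid is decomposed into rectangular blocks (default 64x64
cells) processed in anti-diagonal batches; a block depends only on its
left, upper and upper-left neighbours, so blocks within a batch are
independent. Batches are barrier-synchronised and every cell is written
by exactly one block, which makes the result bit-identical to the
sequential fill for any worker count and block size — there is no
reduction-order-dependent arithmetic, and the global maximum is taken
with a fixed (score desc, row asc, col asc) comparator. Workers are
threads; the numba-compiled kernels release the GIL, so batches scale on
real cores. The kernels are plain Python functions JIT-compiled at
import; without a compiler they still run, only slower. An optional
memory cap (`maximum_memory_usage`, a fraction of system RAM) rejects
pairs whose matrix footprint would exceed the budget before allocation.
The backend interface is a single `align(query, target, scheme)` method,
so an accelerator implementation could be registered without touching
callers; `DPState.cell_updates` exposes cell-update counts for
GCUPS-style throughput reporting.

## Synthetic fixtures

`fixtures.generate_pair` emulates a pair of homologous sequences: a
uniform-random query, a copy of a random 70-90% span of it mutated by
point substitutions (rate `1 - identity`, redrawing uniformly over the
alphabet, so identity 0 leaves the 1/|alphabet| background match rate)
and single-residue indels (rate `indel_rate`, default 0.02), embedded
between random flanks of up to half the query length.
`generate_batch(n, ...)` writes n such pairs plus n i.i.d. uniform decoy
targets and a manifest of true planted coordinates for recall scoring.
All randomness comes from numpy's PCG64 seeded from the spec, so output
is byte-identical across platforms. Defaults (length 150, identity 0.9,
indel rate 0.02) describe a moderately diverged DNA homolog. The
generator does not emulate codon structure, rate heterogeneity across
sites, repeats or compositional bias; recall results on it demonstrate
correct recovery of planted signals against a uniform background, not
performance on real genomes.

## Problem sizes in the test suite

Score equivalence is checked against two independent references: an
exhaustive enumerator of canonical local alignment paths (all pairs with
both lengths <= 4 in the acceptance run; up to 5 in unit tests — path
enumeration grows combinatorially, so these sizes keep it exact and
fast) and Bio.Align.PairwiseAligner on 1,000 pairs per gap model at
lengths 3-8, using schemes in the free-model-safe regime described
above. The reduction property runs on 500 pairs at lengths up to 20;
parallel determinism on a 60x45 pair over worker counts {1,2,4} and
block sizes {8, 64, full}; planted-homology recall on 50 pairs of
length 150 at identity 0.9 against 100 targets (half decoys), requiring
at least 90% of planted regions recovered by a passing hit overlapping
at least half the planted query interval.

## Known limitations

Forward-strand only (no reverse-complement search); no banded or
vectorised fill; no global/semi-global modes; no E-value or bit-score
statistics; SAM output reports alignments (no unmapped records, FLAG 0,
MAPQ 255, soft clips keep the full query in SEQ); BAM/CRAM are out of
scope. Memory for one pair is O(n*m) — three grids in affine mode — so
very long pairs are better served by banded aligners.
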