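# Methods

## The pattern formalism

An interspersed homology is parameterized as **XH-YN_Z** over a region of
length L: homologous units of X bp, spacers of Y bp, first unit starting at
1-based position Z, periodicity P = X + Y.  The homologous position set is

    { Z + kP + j : k >= 0, 0 <= j < X }  ∩  [1, L]

No unit — not even a partial one — is placed before Z; positions 1..Z−1
are always non-homologous.  This makes Z a genuine sequence-position
parameter: sliding Z from 1 to P changes which base-pair combinations end
up inside the units without altering the block structure, and shifting Z
by a full period reproduces the same position set minus the first unit
(asserted as a set identity in the tests).

End handling defaults to truncation at L.  The alternative
`end_policy="extend"` lengthens the final unit by a stated number of
positions (still clipped at L); it exists because synthesized construct
variants sometimes carry an accidentally extended last unit, and analyses
of such constructs must reproduce their masks exactly.

## Test-sequence generation

At every homologous position the test copy keeps the reference base; at
every non-homologous position it receives one of the three alternative
bases, chosen uniformly and independently.  This forces a mismatch at
every masked-out position, so position-wise equality of the two copies
equals the homology mask exactly — the package's central invariant,
checked by `Cassette.validate()` and by property tests over random seeds.
Mismatch-forcing also means a 4H-7N cassette has exactly 4/11 ≈ 36 %
identity per period, not merely in expectation.

Randomness comes from numpy's PCG64 seeded per component: the 500-bp
region, the block's reference bases, the block's substitutions, the
junction insert and the interruption filler each draw from their own
deterministic child stream of the top-level seed.  Consequence: adding or
removing a block never perturbs the region's realized sequence, which
keeps construct families comparable.

A composed cassette concatenates (per `block_side`) block + junction
insert + region, or region + junction insert + block.  The junction insert
models extra DNA present in one copy only; because the in-memory contract
is positional (equal-length copies, mask = equality), the insert occupies
positions in both copies — random reference filler with test bases forced
to differ.  This forcing makes the insert non-homologous by construction
at every position, so no accidental ≥3-bp match can arise at the junction.
A block interruption replaces a stated sub-segment of the block with
forced-mismatch filler; interrupting a 100-bp block at positions 39–60
yields homologous segments of exactly 38 and 40 bp.

## Triplet census and ΔGAC editing

Triplets are counted within **maximal homologous runs** of the mask, not
within nominal pattern units: a run of length ℓ ≥ 3 contributes its ℓ − 2
overlapping 3-windows, read from the reference copy.  For standard
patterns runs and units coincide, but edits and extensions can split or
merge runs, and run-based counting keeps the mask the single source of
truth.  Forward and reverse-complement instances are pooled under the
lexicographically smaller of the pair (a fixed convention chosen for
reproducibility; any fixed one would do).  No 3-mer is its own reverse
complement, so there are exactly 32 canonical classes.

Triplet deletion destroys each targeted occurrence (either orientation,
located exactly as the census counts them) by complementing exactly one
base of the test copy: the base belonging to no other overlapping triplet
of the run.  In a 4-bp unit that is the first base when the triplet
occupies unit positions 1–3 and the last base when it occupies 2–4 —
producing GACT→CACT and TGAC→TGAG while preserving the unit's other
triplet.  For a triplet in the interior of a longer run no exclusive base
exists; the middle base is complemented and a warning logged.  The edited
position is cleared in the mask, so a subsequent census sees the targeted
class reduced by exactly the number of edits.

## Mutation calling

RIP introduces substitutions only, so the default calling mode is
positional: site-by-site comparison of a spore contig against the expected
cassette sequence, classifying expected-C→observed-T as CT,
expected-G→observed-A as GA, and anything else as "other".  Non-RIP
mismatches are reported but excluded from all RIP statistics.  CT and GA
are tallied separately and summed for totals; no molecule-of-origin strand
is inferred.

Gapped mode exists for real Sanger contigs with indel artifacts: a global
pairwise alignment (match +1, mismatch −2, gap open −6, gap extend −1)
precedes classification, gap columns are excluded from counts and tallied,
and an alignment with more than 20 % gap columns is rejected as a likely
wrong construct assignment.  Gap-column exclusion is this package's
choice of artifact handling.

Summaries follow the assay's conventions: the mean number of mutations per
spore with SEM = s/√n (sample standard deviation, n − 1 denominator; SEM
reported as 0 for n = 1), optionally restricted to a 1-based region; and
the per-site profile, the percent of all sequenced spores of a construct
carrying a RIP call at each position (CT and GA pooled at a position).

## Statistics

Mutation-count distributions are compared with the two-sided two-sample
Kolmogorov–Smirnov test.  D is the maximum absolute ECDF difference
evaluated at the pooled unique values.  For n·m ≤ 10,000 the p-value is
permutation-exact, computed by an integer lattice-path recursion over tie
groups; it equals brute-force enumeration over all C(n+m, n) label
assignments, with ties (ubiquitous in integer counts) respected exactly.
Larger samples use the asymptotic Kolmogorov distribution (scipy); the
method used is always reported.  The discreteness of small samples still
makes attainable p-values coarse, so small-n non-significance is weak
evidence.  Replica-cross congruence is the minimum pairwise KS p over all
unordered pairs of crosses of one construct, reported raw (no
multiple-testing correction; p_min < 0.05 is flagged in logs only);
a single cross yields a flagged not-applicable result.  Samples are never
pooled by the congruence routine.  Site profiles are compared by Pearson
correlation over a stated region; zero variance in either profile returns
a distinguished undefined result rather than an error.

## The simulator

The spore simulator is phenomenological.  Per spore, independently: with
probability `escape_prob` the spore emits the unmutated cassette;
otherwise a Poisson(`lambda_mean`) mutation count is drawn, split between
the CT and GA classes by `ct_ga_ratio`, and placed without replacement
among the class's mutable sites (C positions for CT, G for GA) with
probabilities proportional to a spatial weight vector.  Requests exceeding
the available sites are truncated with a log entry.

Defaults, chosen once as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| `lambda_mean` | 12.5 | with the default escape fraction this yields an observed mean of 10 mutations per spore — the level of a strongly mutated 500-bp construct — and a per-spore spread well above Poisson, as real crosses show |
| `escape_prob` | 0.2 | a realistic fraction of progeny spores showing no RIP in a cross |
| `spatial_profile` | symmetric triangle peaking at the cassette center, strictly positive at the edges | mutations in this assay concentrate symmetrically near the repeat center |
| `ct_ga_ratio` | 0.5 | both strands are substrates; no asymmetry is imposed |
| `indel_rate` | 0 | RIP makes no indels; a nonzero rate emulates sequencing artifacts for exercising gapped calling |

`emulate_study` arranges crosses like the real assay — 2 replica crosses
of 30 spores per construct by default — and writes the archive-shaped
files (4-field contig CSV with id `{RepeatID}{cross}_{spore}`,
per-construct expected FASTA, construct table, planted-call TSV).

What the simulator does **not** model: any mapping from homology features
to mutation intensity (intensities are inputs, not predictions),
processivity or clustering of mutations along a molecule, sequence-context
preference (real RIP favors CpA dinucleotides), and the true per-spore
count distribution's possible bimodality beyond the escape-plus-Poisson
mixture.  Passing round-trip tests therefore certifies the calling,
profiling and statistics machinery on data with the right observable
structure; it says nothing about whether a particular real construct will
be mutated.

## Numerical and interface choices

- Coordinates are 1-based inclusive in all interfaces, logs and tables;
  BED exports are 0-based half-open (conversion covered by tests).
- Pattern generation, composition, editing and simulation are
  deterministic functions of their seeds; equal seeds give byte-identical
  outputs, and CLI commands log their full invocation and seed to stderr.
- Recorded mutation totals read from a contig CSV are kept separate from
  recomputed calls; `riplet call --verify` reports disagreements.
- Degenerate inputs: Z > L yields an empty position set with a warning
  (not an error); X = 0 likewise; a single cross yields a not-applicable
  congruence result; zero-variance profiles yield undefined correlation.
- Test problem sizes (hundreds of spores, 500-bp cassettes, 50-seed
  round-trip sweeps) were chosen so the full suite completes in seconds
  while leaving the statistical assertions 3-sigma margins.
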